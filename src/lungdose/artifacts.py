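"""LSFM artifact simulation, training-style augmentation and patch logic.

Light-sheet lung stacks show characteristic acquisition artifacts —
inconsistent per-slice illumination, poorly illuminated (dark) lung
centers, local blur/halo/contrast patches, and stripes of missing data.
This module provides those artifact transforms for augmentation, the
standard intensity/geometry augmentation set, foreground-biased two-patch
sampling, and Gaussian-center-weighted sliding-window aggregation for
patch-based inference.

Contracts shared by all transforms:

* pure functions of ``(input, params, seed)`` — bit-identical reruns;
* null parameters give the identity;
* outputs are clipped to the representable range of integer input dtypes;
* transforms advertised as *local* leave voxels outside the (feathered)
  region of interest bit-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _clip_to_dtype(out: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Clip to the input's representable range; floats pass through ≥0-free."""
    if np.issubdtype(like.dtype, np.integer):
        info = np.iinfo(like.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(like.dtype)
    return out.astype(like.dtype, copy=False)


# ---------------------------------------------------------------------------
# dataset-specific artifact transforms


def slice_illumination(
    volume: np.ndarray, scale_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Multiply every z-slice by an independent scale drawn from the range.

    Emulates inconsistent slice illumination across the light-sheet sweep.
    """
    lo, hi = scale_range
    if not (0 < lo <= hi <= 2):
        raise ValueError("scale range must satisfy 0 < lo <= hi <= 2")
    vol = np.asarray(volume)
    scales = _rng(seed).uniform(lo, hi, size=vol.shape[0])
    out = vol.astype(np.float64) * scales[:, None, None]
    return _clip_to_dtype(out, vol)


def dark_center(
    volume: np.ndarray,
    max_attenuation: float,
    radius_frac: float = 0.9,
    seed: int | None = None,
) -> np.ndarray:
    """Attenuate the in-plane image center with a smooth radial bump.

    Each voxel is scaled by ``1 - a·g(r)`` where ``g`` is a cosine-squared
    bump equal to 1 at the in-plane center and 0 beyond ``radius_frac`` of
    the in-plane half-diagonal, so the center column is scaled by exactly
    ``1 - a``.  Emulates poor illumination of the lung center.
    """
    if not 0 <= max_attenuation < 1:
        raise ValueError("max_attenuation must be in [0, 1)")
    vol = np.asarray(volume)
    nz, ny, nx = vol.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    r = np.hypot(yy, xx)
    r_max = radius_frac * np.hypot(cy, cx)
    g = np.where(r < r_max, np.cos(0.5 * np.pi * np.minimum(r / max(r_max, 1e-12), 1.0)) ** 2, 0.0)
    out = vol.astype(np.float64) * (1.0 - max_attenuation * g)[None]
    return _clip_to_dtype(out, vol)


def _feather_mask(shape, lo, hi, feather) -> np.ndarray:
    """Box ROI alpha mask: 1 in the core, cosine ramp of width ``feather``."""
    alpha = np.ones(tuple(h - l for l, h in zip(lo, hi)), dtype=np.float64)
    for ax, (l, h) in enumerate(zip(lo, hi)):
        n = h - l
        ramp = np.ones(n)
        f = min(feather, n // 2)
        if f > 0:
            t = (np.arange(f) + 1.0) / (f + 1.0)
            edge = 0.5 - 0.5 * np.cos(np.pi * t)
            ramp[:f] = edge
            ramp[n - f:] = edge[::-1]
        alpha *= ramp.reshape([-1 if i == ax else 1 for i in range(len(shape))])
    return alpha


def local_degrade(
    volume: np.ndarray,
    kind: str,
    strength: float,
    seed: int,
    roi_frac: tuple[float, float] = (0.2, 0.5),
    feather: int = 3,
) -> np.ndarray:
    """Apply blur/contrast/brightness/sharpness inside a random feathered box.

    The effect is alpha-blended with a cosine-feathered mask; voxels outside
    the ROI (plus feather) are bit-identical to the input.  ``strength=0``
    is the identity for every kind.  Emulates local halos, blurred areas
    and locally varying signal-to-noise.
    """
    if kind not in {"blur", "contrast", "brightness", "sharpness"}:
        raise ValueError(f"unknown kind {kind!r}")
    vol = np.asarray(volume)
    rng = _rng(seed)
    lo, hi = [], []
    for n in vol.shape:
        size = int(round(n * rng.uniform(*roi_frac)))
        size = max(1, min(size, n))
        start = int(rng.integers(0, n - size + 1))
        lo.append(start)
        hi.append(start + size)
    if strength == 0:
        return vol.copy()
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = vol[box].astype(np.float64)
    if kind == "blur":
        eff = ndimage.gaussian_filter(sub, sigma=strength)
    elif kind == "contrast":
        eff = sub.mean() + (sub - sub.mean()) * (1.0 + strength)
    elif kind == "brightness":
        eff = sub + strength * (np.ptp(sub) if np.ptp(sub) > 0 else 1.0)
    else:  # sharpness: unsharp masking
        eff = sub + strength * (sub - ndimage.gaussian_filter(sub, sigma=1.0))
    alpha = _feather_mask(vol.shape, lo, hi, feather)
    out = vol.astype(np.float64).copy()
    out[box] = sub * (1.0 - alpha) + eff * alpha
    blended = _clip_to_dtype(out, vol)
    result = vol.copy()
    result[box] = blended[box]  # outside the ROI stays bit-identical
    return result


def blank_rectangle(
    volume: np.ndarray,
    n_rects: int,
    size_range: tuple[int, int],
    fill: str = "zero",
    seed: int = 0,
) -> np.ndarray:
    """Overwrite random boxes with a constant fill (missing-data artifact).

    ``fill`` is one of ``zero``, ``image_min``, ``mean``; rectangle voxels
    are set exactly to the fill value, all others are untouched.
    """
    vol = np.asarray(volume)
    lo_s, hi_s = size_range
    if lo_s < 1 or hi_s > min(vol.shape):
        raise ValueError("rectangle sizes must fit the volume")
    fills = {
        "zero": 0,
        "image_min": vol.min() if vol.size else 0,
        "mean": vol.mean() if vol.size else 0,
    }
    if fill not in fills:
        raise ValueError(f"unknown fill {fill!r}")
    value = np.asarray(fills[fill]).astype(vol.dtype)
    rng = _rng(seed)
    out = vol.copy()
    for _ in range(n_rects):
        sizes = rng.integers(lo_s, hi_s + 1, size=3)
        starts = [int(rng.integers(0, n - s + 1)) for n, s in zip(vol.shape, sizes)]
        box = tuple(slice(st, st + int(s)) for st, s in zip(starts, sizes))
        out[box] = value
    return out


# ---------------------------------------------------------------------------
# standard augmentation set


@dataclass
class AugmentOp:
    """One step of an augmentation pipeline.

    ``kind`` ∈ {GAUSS_NOISE, GAUSS_BLUR, BRIGHTNESS, CONTRAST, GAMMA,
    LOWRES, MIRROR, ROTATE, SLICE_ILLUM, DARK_CENTER, LOCAL_BLUR,
    LOCAL_CONTRAST, LOCAL_BRIGHTNESS, LOCAL_SHARPNESS, BLANK_RECT};
    geometric kinds (MIRROR, ROTATE) are applied identically to a paired
    mask.  ``probability`` gates each firing from the pipeline's seeded
    stream.
    """

    kind: str
    probability: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must be in [0, 1]")
        known = {
            "GAUSS_NOISE", "GAUSS_BLUR", "BRIGHTNESS", "CONTRAST", "GAMMA",
            "LOWRES", "MIRROR", "ROTATE", "SLICE_ILLUM", "DARK_CENTER",
            "LOCAL_BLUR", "LOCAL_CONTRAST", "LOCAL_BRIGHTNESS",
            "LOCAL_SHARPNESS", "BLANK_RECT",
        }
        if self.kind not in known:
            raise ValueError(f"unknown augmentation kind {self.kind!r}")


GEOMETRIC_KINDS = {"MIRROR", "ROTATE"}


def _apply_one(vol, op: AugmentOp, rng, is_mask=False):
    p = op.params
    sub = int(rng.integers(0, 2**31 - 1))  # drawn even when unused: stable stream
    if op.kind == "MIRROR":
        return np.flip(vol, axis=p.get("axis", 2)).copy()
    if op.kind == "ROTATE":
        k = p.get("k", 1)
        return np.rot90(vol, k=k, axes=p.get("axes", (1, 2))).copy()
    if is_mask:
        return vol  # intensity ops never touch the paired mask
    if op.kind == "GAUSS_NOISE":
        noisy = vol.astype(np.float64) + _rng(sub).normal(0, p.get("sigma", 1.0), vol.shape)
        return _clip_to_dtype(np.clip(noisy, 0, None), vol)
    if op.kind == "GAUSS_BLUR":
        return _clip_to_dtype(ndimage.gaussian_filter(vol.astype(np.float64), p.get("sigma", 1.0)), vol)
    if op.kind == "BRIGHTNESS":
        return _clip_to_dtype(vol.astype(np.float64) * p.get("factor", 1.0), vol)
    if op.kind == "CONTRAST":
        v = vol.astype(np.float64)
        return _clip_to_dtype(v.mean() + (v - v.mean()) * p.get("factor", 1.0), vol)
    if op.kind == "GAMMA":
        v = vol.astype(np.float64)
        vmax = v.max() if v.max() > 0 else 1.0
        return _clip_to_dtype((v / vmax) ** p.get("gamma", 1.0) * vmax, vol)
    if op.kind == "LOWRES":
        f = p.get("factor", 2)
        small = vol[::f, ::f, ::f]
        return np.kron(small, np.ones((f, f, f), dtype=vol.dtype))[
            : vol.shape[0], : vol.shape[1], : vol.shape[2]
        ].astype(vol.dtype)
    if op.kind == "SLICE_ILLUM":
        return slice_illumination(vol, tuple(p.get("scale_range", (0.7, 1.3))), sub)
    if op.kind == "DARK_CENTER":
        return dark_center(vol, p.get("max_attenuation", 0.5), p.get("radius_frac", 0.9), sub)
    if op.kind in {"LOCAL_BLUR", "LOCAL_CONTRAST", "LOCAL_BRIGHTNESS", "LOCAL_SHARPNESS"}:
        kind = op.kind.split("_", 1)[1].lower()
        return local_degrade(vol, kind, p.get("strength", 1.0), sub,
                             tuple(p.get("roi_frac", (0.2, 0.5))), p.get("feather", 3))
    if op.kind == "BLANK_RECT":
        return blank_rectangle(vol, p.get("n_rects", 1),
                               tuple(p.get("size_range", (2, 8))), p.get("fill", "zero"), sub)
    raise AssertionError(op.kind)


def standard_augment(
    volume: np.ndarray,
    ops: Sequence[AugmentOp],
    seed: int,
    mask: np.ndarray | None = None,
):
    """Run an augmentation pipeline in list order with seeded firing.

    Each op fires with its probability from a single seeded stream;
    geometric ops are applied identically to the paired mask so it stays
    binary and co-registered.  Returns the volume, or ``(volume, mask)``
    when a mask is given.
    """
    rng = _rng(seed)
    vol = np.asarray(volume).copy()
    msk = None if mask is None else np.asarray(mask).copy()
    for op in ops:
        fire = rng.random() < op.probability
        # sub-seed is always drawn so firing of later ops never shifts
        if not fire:
            _ = rng.integers(0, 2**31 - 1)
            continue
        vol = _apply_one(vol, op, rng)
        if msk is not None and op.kind in GEOMETRIC_KINDS:
            msk = _apply_one(msk, op, rng, is_mask=True)
    return vol if mask is None else (vol, msk)


# ---------------------------------------------------------------------------
# patch sampling and sliding-window aggregation


@dataclass
class PatchPair:
    """A training pair: one random patch, one guaranteed-foreground patch."""

    patch_a: np.ndarray
    patch_b: np.ndarray
    offset_a: tuple[int, int, int]
    offset_b: tuple[int, int, int]
    b_contains_foreground: bool


def sample_patch_pair(
    volume: np.ndarray,
    mask: np.ndarray,
    patch_shape: tuple[int, int, int],
    seed: int,
) -> PatchPair:
    """Two-patch sampling: A uniform over valid origins, B covering foreground.

    Patch B's origin is drawn uniformly from the origins whose patch
    contains a uniformly chosen foreground voxel, so B overlaps at least
    one foreground voxel whenever any exists; with an empty mask B falls
    back to uniform and is flagged.
    """
    vol = np.asarray(volume)
    msk = np.asarray(mask).astype(bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    if any(p > n for p, n in zip(patch_shape, vol.shape)):
        raise ValueError(f"patch {patch_shape} larger than volume {vol.shape}")
    rng = _rng(seed)
    valid = [n - p + 1 for n, p in zip(vol.shape, patch_shape)]
    origin_a = tuple(int(rng.integers(0, v)) for v in valid)
    fg = np.argwhere(msk)
    if len(fg) == 0:
        origin_b = tuple(int(rng.integers(0, v)) for v in valid)
        has_fg = False
    else:
        target = fg[int(rng.integers(0, len(fg)))]
        origin_b = tuple(
            int(rng.integers(max(0, t - p + 1), min(v - 1, t) + 1))
            for t, p, v in zip(target, patch_shape, valid)
        )
        has_fg = True
    box_a = tuple(slice(o, o + p) for o, p in zip(origin_a, patch_shape))
    box_b = tuple(slice(o, o + p) for o, p in zip(origin_b, patch_shape))
    return PatchPair(vol[box_a].copy(), vol[box_b].copy(), origin_a, origin_b, has_fg)


def _tile_starts(n: int, p: int) -> list[int]:
    """Tile origins with half-patch stride; the last tile is shifted inward."""
    if p >= n:
        return [0]
    stride = max(1, p // 2)
    starts = list(range(0, n - p, stride))
    starts.append(n - p)
    return sorted(set(starts))


def gaussian_patch_weight(patch_shape: tuple[int, ...], sigma_scale: float = 0.125) -> np.ndarray:
    """Separable Gaussian weight peaked at the patch center (σ = shape/8)."""
    ws = []
    for n in patch_shape:
        x = np.arange(n) - (n - 1) / 2.0
        s = max(n * sigma_scale, 1e-6)
        ws.append(np.exp(-0.5 * (x / s) ** 2))
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return w / w.max()


def sliding_window_apply(
    volume: np.ndarray,
    patch_fn: Callable[[np.ndarray], np.ndarray],
    patch_shape: tuple[int, int, int],
    sigma_scale: float = 0.125,
) -> np.ndarray:
    """Aggregate a patchwise score function over the volume.

    Tiles with half-patch overlap cover the volume (edge tiles shifted
    inward), each patch output is blended with a Gaussian center weight,
    and the accumulated map is normalized by the accumulated weights —
    which are strictly positive everywhere by construction, so an identity
    ``patch_fn`` reproduces the input voxelwise.
    """
    vol = np.asarray(volume)
    patch_shape = tuple(min(p, n) for p, n in zip(patch_shape, vol.shape))
    weight = gaussian_patch_weight(patch_shape, sigma_scale)
    acc = np.zeros(vol.shape, dtype=np.float64)
    norm = np.zeros(vol.shape, dtype=np.float64)
    starts = [_tile_starts(n, p) for n, p in zip(vol.shape, patch_shape)]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                box = (
                    slice(z0, z0 + patch_shape[0]),
                    slice(y0, y0 + patch_shape[1]),
                    slice(x0, x0 + patch_shape[2]),
                )
                out = np.asarray(patch_fn(vol[box]))
                if out.shape != patch_shape:
                    raise ValueError(
                        f"patch_fn returned {out.shape}, expected {patch_shape}"
                    )
                acc[box] += out * weight
                norm[box] += weight
    return acc / norm
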