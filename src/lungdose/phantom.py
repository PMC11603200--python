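"""Synthetic lung phantoms with exact deposition ground truth.

The generator builds, from a single seed, a monopodial airway tree embedded
in an ellipsoidal lung domain, tiles the parenchyma into acini attached to
the terminal branches, deposits nanoparticle (NP) agglomerates according to
a delivery-route preset, and renders NP and autofluorescence (AF) channels.
Every quantity the profiling stage estimates (bronchial/acinar signal split,
per-acinus signal, proximal/distal acinar split) is recorded exactly from
the event bookkeeping *before* rendering, so recovered values can be
compared against uncontaminated truth.

Route presets encode the qualitative contrasts between delivery techniques:
bulk-liquid instillation (INLA, ITLI) deposits a large bronchial share as
big central agglomerates; aerosol delivery (VAAD, NOAI) spreads many small
agglomerates nearly homogeneously, with VAAD favouring the proximal acinar
region.  Preset bronchial-fraction centers (0.32 / 0.19 / 0.11 / 0.08) are
plausible means for these four routes, not reproduction claims.

Rendering model: an agglomerate of Gaussian-equivalent radius ``a`` (µm) is
imaged as a Gaussian blob of width ``sqrt(a² + psf²)`` — below the optical
resolution ``psf`` every dot renders at least psf-sized.  Fluorescence mass
per event is ``packing_density · (2π)^{3/2} a³``, i.e. proportional to the
physical NP mass at constant packing.  This is what makes the apparent
NP-volume per dose (the agglomeration state) large for finely dispersed
aerosols and small for packed instillate clumps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imagio import BinaryMask, ChannelRole, ImageStack, MaskLabel, write_stack
from .tree import AirwayTree, Branch

# region-label codes (uint8 volume)
BACKGROUND = 0
AIRWAY = 1
PAR = 2
DAR = 3
LUNG_OTHER = 4

_GOLDEN_DEG = 137.50776405


class Route(str, Enum):
    """Delivery route preset family."""

    INLA = "INLA"  # intranasal liquid application
    ITLI = "ITLI"  # intratracheal liquid instillation
    VAAD = "VAAD"  # ventilator-assisted aerosol delivery
    NOAI = "NOAI"  # nose-only aerosol inhalation
    UNIFORM = "UNIFORM"  # idealized homogeneous deposition


class PhantomGeometryError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    """All knobs of one synthetic lung; a pure function of this + seed.

    Geometry is a scaled-down mouse lung: ~1.3 mm cube at 10 µm isotropic
    voxels with a 5-generation monopodial tree, so whole phantoms build in
    seconds while every downstream contract stays measurable.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (12.0, 12.0, 12.0)
    # airway tree
    n_generations: int = 5
    root_diameter_um: float = 165.0
    diameter_ratio: float = 0.74
    length_ratio: float = 0.74
    root_length_um: float = 390.0
    branch_angle_deg: float = 40.0
    branch_angle_jitter_sd: float = 5.0
    min_tip_separation_um: float = 45.0
    # how many lateral take-offs are allowed along any root-to-tip path;
    # the main stem always spawns laterals, so 1 gives a bottle-brush tree
    lateral_branching_depth: int = 99
    # reject trees whose non-adjacent branches would fuse when voxelized;
    # needed for exact skeleton-based morphometry, irrelevant for dosimetry
    enforce_branch_clearance: bool = False
    # deposition
    route: Route = Route.UNIFORM
    central_bias: float = 0.0  # λ, exponential inter-acinar weighting
    par_bias: float | None = None  # None → proportional to PAR/DAR volumes
    bronchial_fraction_target: float = 0.15
    bronchial_gen_decay: float = 0.0  # low-generation bias of bronchial events
    n_np_events: int = 10_000
    agglomerate_radius_um: float = 12.0
    psf_sigma_um: float = 10.0
    packing_density: float = 1000.0  # fluorescence a.u. per µm³ of agglomerate
    # lung hull and acini
    lung_smooth_vox: float = 3.0  # Gaussian smoothing of the lung hull (voxels)
    acinus_radius_um: float = 140.0
    par_cut_frac: float = 0.5  # PAR volume fraction of each acinus
    wall_exclusion_um: float = 25.0  # bronchial-wall tissue takes no acinar events
    # autofluorescence channel
    af_base: float = 150.0
    af_wall_gain: float = 1.8
    af_texture_sd: float = 0.15
    af_noise_sd: float = 8.0
    af_background: float = 4.0
    # NP-channel contamination (observed channel only)
    np_af_bleed: float = 0.05
    np_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        if not (0 < self.diameter_ratio < 1 and 0 < self.length_ratio < 1):
            raise ValueError("diameter_ratio and length_ratio must be in (0,1)")
        if not 0 <= self.bronchial_fraction_target <= 1:
            raise ValueError("bronchial_fraction_target must be in [0,1]")
        if self.par_bias is not None and not 0 <= self.par_bias <= 1:
            raise ValueError("par_bias must be in [0,1] or None")
        if self.central_bias < 0:
            raise ValueError("central_bias must be >= 0")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.asarray(self.spacing, float)

    @property
    def render_sigma_um(self) -> float:
        """Imaged blob width: agglomerate size convolved with the PSF."""
        return float(np.hypot(self.agglomerate_radius_um, self.psf_sigma_um))

    @property
    def event_mass(self) -> float:
        """Fluorescence mass of one agglomerate (a.u. · µm³ / voxel volume)."""
        a = self.agglomerate_radius_um
        mass_um3 = self.packing_density * (2 * np.pi) ** 1.5 * a**3
        return float(mass_um3 / np.prod(self.spacing))


#: Route presets.  n_np_events and agglomerate radii follow the physical
#: picture (few large clumps for instilled liquid, many fine dots for
#: aerosol); the uniform preset uses enough small events that the rendered
#: field is statistically homogeneous.
PRESETS: dict[str, dict] = {
    "inla": dict(
        route=Route.INLA, bronchial_fraction_target=0.32, central_bias=3.0,
        agglomerate_radius_um=25.0, n_np_events=1500, bronchial_gen_decay=0.8,
    ),
    "itli": dict(
        route=Route.ITLI, bronchial_fraction_target=0.19, central_bias=1.5,
        agglomerate_radius_um=18.0, n_np_events=3000, bronchial_gen_decay=0.8,
    ),
    "vaad": dict(
        route=Route.VAAD, bronchial_fraction_target=0.11, central_bias=0.0,
        par_bias=0.7, agglomerate_radius_um=10.0, n_np_events=30000,
    ),
    "noai": dict(
        route=Route.NOAI, bronchial_fraction_target=0.08, central_bias=0.0,
        par_bias=0.5, agglomerate_radius_um=5.0, n_np_events=60000,
    ),
    "uniform": dict(
        route=Route.UNIFORM, agglomerate_radius_um=12.0, n_np_events=500000,
    ),
}


#: Phantom configuration for validating morphometry extraction: finer
#: voxels, a slower taper and wider lateral angles than the deposition
#: presets, so that every terminal branch is well resolved by the mask
#: (tips ~6 voxels across, siblings separate well before their caps).
MORPHOMETRY_BENCHMARK: dict = dict(
    grid_shape=(192, 192, 192),
    spacing=(8.0, 8.0, 8.0),
    root_length_um=280.0,
    length_ratio=0.85,
    diameter_ratio=0.78,
    branch_angle_deg=50.0,
    lateral_branching_depth=2,
    enforce_branch_clearance=True,
)


def morphometry_benchmark_spec(seed: int, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` tuned for exact airway-tree recovery checks."""
    kwargs = dict(MORPHOMETRY_BENCHMARK)
    kwargs.update(overrides)
    return PhantomSpec(seed=seed, **kwargs)


def spec_from_preset(preset: str, **overrides) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a named route preset."""
    if preset.lower() not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset.lower()])
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


# ---------------------------------------------------------------------------
# airway tree


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    return u, np.cross(d, u)


def _tilt(d: np.ndarray, theta_deg: float, azimuth_deg: float) -> np.ndarray:
    """Rotate unit vector d by polar angle theta toward azimuth in its ⊥ plane."""
    u, v = _perp_basis(d)
    th, az = np.deg2rad(theta_deg), np.deg2rad(azimuth_deg)
    return _unit(np.cos(th) * d + np.sin(th) * (np.cos(az) * u + np.sin(az) * v))


def generate_airway_tree(spec: PhantomSpec, _rng: np.random.Generator | None = None) -> AirwayTree:
    """Grow a monopodial airway tree, deterministic given ``spec.seed``.

    Every non-terminal branch ends in one junction spawning a continuation
    daughter (near-straight, persistent stem) and one lateral daughter at
    ~``branch_angle_deg``; both are one generation deeper (Weibel-style
    numbering).  Lengths and diameters follow exact geometric schedules
    ``root·length_ratio^g`` and ``root·diameter_ratio^g``; randomness enters
    only through branch directions.
    """
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 0])
    )
    extent = spec.extent_um
    branches: dict[int, Branch] = {}
    next_id = [0]
    step = min(spec.spacing)
    n_try = 25  # candidate directions scored per daughter
    placed_pts: list[np.ndarray] = []
    placed_r: list[np.ndarray] = []
    placed_tips: list[np.ndarray] = []

    def pick_direction(direction, thetas, azimuths, junction, length, radius,
                       terminal):
        """Choose the candidate daughter direction with maximal clearance.

        Clearance of a candidate is the minimal surface-to-surface margin
        between sample points on its distal half and every already-placed
        branch point, ignoring points close to the junction (the sibling
        and parent are legitimately adjacent there).
        """
        dirs = [_tilt(direction, t, a) for t, a in zip(thetas, azimuths)]
        if not placed_pts:
            return dirs[0], float(thetas[0])
        pts = np.concatenate(placed_pts)
        rad = np.concatenate(placed_r)
        keep = np.linalg.norm(pts - junction, axis=1) > 0.6 * length
        if not keep.any():
            return dirs[0], float(thetas[0])
        pts, rad = pts[keep], rad[keep]
        axis_zx = np.array([extent[0] / 2, extent[2] / 2])  # main-stem axis
        r_junc = np.linalg.norm(junction[[0, 2]] - axis_zx)
        # room the subtree hanging off this daughter will still need
        subtree_reach = length * spec.length_ratio / max(1e-9, 1 - spec.length_ratio)
        margin = radius + 2 * step
        best, best_score = None, -np.inf
        fallback, fallback_depth = 0, -np.inf
        for i, d in enumerate(dirs):
            sample = junction[None] + np.outer([0.4, 0.6, 0.8, 1.0], d) * length
            head = sample[-1] + d * min(subtree_reach, 0.6 * length)
            probe_all = np.vstack([sample, head])
            depth = float(np.minimum(probe_all, extent - probe_all).min())
            if depth > fallback_depth:
                fallback, fallback_depth = i, depth
            if depth < margin:
                continue
            probe = np.vstack([sample, head])
            dist = np.linalg.norm(probe[:, None, :] - pts[None], axis=2) - rad[None]
            # clearance plus a mild outward pull so subtrees radiate from the stem
            outward = np.linalg.norm(sample[-1][[0, 2]] - axis_zx) - r_junc
            score = float(dist.min()) - radius + 0.15 * outward
            if terminal and placed_tips:
                tip_d = np.linalg.norm(np.asarray(placed_tips) - sample[-1], axis=1).min()
                # steep penalty for endpoints crowding an existing terminal tip
                score += 3.0 * min(0.0, tip_d - spec.min_tip_separation_um - 15.0)
            if score > best_score:
                best, best_score = i, score
        if best is None:  # no candidate clears the walls: take the most inward
            best = fallback
        return dirs[best], float(thetas[best])

    def grow(start, direction, gen, parent, azimuth, lateral_angle, lat_count=0):
        length = spec.root_length_um * spec.length_ratio**gen
        diam = spec.root_diameter_um * spec.diameter_ratio**gen
        end = start + direction * length
        margin = diam / 2 + step
        for p in (start, end):
            if np.any(p < margin) or np.any(p > extent - margin):
                raise PhantomGeometryError(
                    f"branch at generation {gen} exits grid bounds at {p}"
                )
        npts = max(2, int(np.ceil(length / step)) + 1)
        pts = start[None] + np.linspace(0, 1, npts)[:, None] * (end - start)[None]
        bid = next_id[0]
        next_id[0] += 1
        branches[bid] = Branch(bid, pts, gen, diam, parent, angle_deg=lateral_angle)
        if parent is not None:
            branches[parent].children.append(bid)
        placed_pts.append(pts)
        placed_r.append(np.full(len(pts), diam / 2))
        spawn = gen < spec.n_generations and lat_count < spec.lateral_branching_depth
        if not spawn:
            placed_tips.append(end)
        else:
            # fixed draw order/count per junction keeps the stream stable:
            # continuation tilts+azimuths, then lateral angles+azimuths
            child_len = length * spec.length_ratio
            child_r = diam * spec.diameter_ratio / 2
            cont_t = np.abs(rng.normal(0.0, 3.0, n_try))
            cont_a = rng.uniform(0.0, 360.0, n_try)
            lat_t = np.clip(
                rng.normal(spec.branch_angle_deg, spec.branch_angle_jitter_sd, n_try),
                spec.branch_angle_deg - 10, spec.branch_angle_deg + 10,
            )
            lat_a = azimuth + _GOLDEN_DEG + rng.uniform(-90.0, 90.0, n_try)
            term_cont = gen + 1 == spec.n_generations
            term_lat = term_cont or lat_count + 1 >= spec.lateral_branching_depth
            d_cont, th_c = pick_direction(direction, cont_t, cont_a, end,
                                          child_len, child_r, term_cont)
            grow(end, d_cont, gen + 1, bid, azimuth, th_c, lat_count)
            d_lat, th_l = pick_direction(direction, lat_t, lat_a, end,
                                         child_len, child_r, term_lat)
            grow(end, d_lat, gen + 1, bid, azimuth + _GOLDEN_DEG, th_l,
                 lat_count + 1)

    start_y = spec.root_diameter_um / 2 + 2 * step
    start = np.array([extent[0] / 2, start_y, extent[2] / 2])
    grow(start, np.array([0.0, 1.0, 0.0]), 0, None, 0.0, None)
    tree = AirwayTree(branches, root_id=0)
    tips = tree.tips_um()
    if len(tips) > 1:
        from scipy.spatial.distance import pdist

        if pdist(tips).min() < spec.min_tip_separation_um:
            raise PhantomGeometryError(
                "terminal branch tips closer than min_tip_separation_um"
            )
    if spec.enforce_branch_clearance:
        _check_branch_clearance(tree, spec)
    return tree


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimal distance between two 3D segments (standard clamped form)."""
    d1, d2 = a1 - a0, b1 - b0
    r = a0 - b0
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            den = a * e - b * b
            s = np.clip((b * f - c * e) / den, 0.0, 1.0) if den > 1e-12 else 0.0
            t = np.clip((b * s + f) / e, 0.0, 1.0)
            s = np.clip((b * t - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(a0 + s * d1 - (b0 + t * d2)))


def _check_branch_clearance(tree: AirwayTree, spec: PhantomSpec) -> None:
    """Reject trees whose non-adjacent branches would merge when voxelized.

    Two capsules separated by less than two voxels of tissue fuse in the
    rasterized mask, creating skeleton loops that corrupt morphometry.
    Pairs sharing a junction (parent/child, siblings) are legitimately in
    contact and are skipped.
    """
    gap = 2.2 * max(spec.spacing)
    items = sorted(tree.branches.values(), key=lambda b: b.branch_id)
    for i, bi in enumerate(items):
        near_i = {bi.parent, *bi.children}
        for bj in items[i + 1:]:
            if bj.branch_id in near_i or bj.parent == bi.branch_id:
                continue
            if bj.parent == bi.parent:  # siblings share the junction
                continue
            # skip pairs sharing an endpoint (grandchild chains touch at nodes)
            if np.linalg.norm(bi.points_um[-1] - bj.points_um[0]) < 1e-6 or \
               np.linalg.norm(bj.points_um[-1] - bi.points_um[0]) < 1e-6:
                continue
            d = _segment_distance(
                bi.points_um[0], bi.points_um[-1], bj.points_um[0], bj.points_um[-1]
            )
            if d < bi.diameter_um / 2 + bj.diameter_um / 2 + gap:
                raise PhantomGeometryError(
                    f"branches {bi.branch_id} and {bj.branch_id} too close "
                    f"({d:.0f} um) for clean voxelization"
                )


def rasterize_tree(
    tree: AirwayTree, spec: PhantomSpec, *, return_generations: bool = False
):
    """Voxelize the tree as a union of capsules (anisotropy-aware).

    Each branch becomes a cylinder of its own diameter with hemispherical
    ends; overlapping voxels take the lowest generation (proximal wins).
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, float)
    mask = np.zeros(shape, dtype=np.uint8)
    gen_map = np.full(shape, -1, dtype=np.int16)
    for b in sorted(tree.branches.values(), key=lambda b: (b.generation, b.branch_id)):
        r = b.diameter_um / 2.0
        # branches are straight: a single capsule segment suffices
        a_um, b_um = b.points_um[0], b.points_um[-1]
        lo = np.floor((np.minimum(a_um, b_um) - r) / spacing - 1).astype(int)
        hi = np.ceil((np.maximum(a_um, b_um) + r) / spacing + 1).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(shape))
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(
            *(np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)), indexing="ij"
        )
        pts = np.stack(grids, axis=-1)
        ab = b_um - a_um
        denom = float(ab @ ab)
        t = np.clip(((pts - a_um) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a_um + np.multiply.outer(t, ab)
        inside = ((pts - closest) ** 2).sum(axis=-1) <= r * r
        sl = tuple(slice(lo[i], hi[i]) for i in range(3))
        mask[sl][inside] = 1
        sub = gen_map[sl]
        sub[inside & (sub < 0)] = b.generation
        gen_map[sl] = sub
    airway = BinaryMask(mask, spec.spacing, MaskLabel.AIRWAY)
    if return_generations:
        return airway, gen_map
    return airway


# ---------------------------------------------------------------------------
# lung domain and acini


@dataclass
class RegionLabels:
    """Label volume plus the acinus tessellation of the parenchyma.

    ``labels`` uses the codes BACKGROUND/AIRWAY/PAR/DAR/LUNG_OTHER; with the
    default unbounded (Voronoi-by-tip) acini, LUNG_OTHER is empty and the
    labels partition the lung mask exactly.
    """

    labels: np.ndarray  # uint8 region codes
    acinus_map: np.ndarray  # int32, acinus id (1-based) per voxel, 0 = none
    tip_coords_um: np.ndarray  # (n_acini, 3), acinus id i+1 at row i
    lung_center_um: np.ndarray
    mean_semi_axis_um: float
    dist_to_airway_um: np.ndarray  # Euclidean distance to the airway surface


def build_lung_and_acini(
    tree: AirwayTree,
    airway: BinaryMask,
    spec: PhantomSpec,
    *,
    min_acinus_frac: float = 0.15,
) -> tuple[BinaryMask, RegionLabels]:
    """Smooth lung hull around the tree + acinar tessellation.

    The lung domain is the set of voxels within ``acinus_radius_um`` of the
    airway, Gaussian-smoothed into an organ-like blob; containment of the
    airway is guaranteed by construction.  Each terminal branch tip seeds
    one acinus; every parenchymal voxel joins
    the acinus of its nearest tip, and voxels within ``par_cut_frac ·
    acinus_radius`` of the tip form the proximal acinar region (PAR), the
    rest the distal region (DAR).  An acinus squeezed below
    ``min_acinus_frac`` of the median acinus volume raises
    :class:`PhantomGeometryError` (callers may retry with a jittered seed).
    """
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing, float)
    dist_to_airway = ndimage.distance_transform_edt(
        ~airway.as_bool(), sampling=spacing
    )
    core = dist_to_airway <= spec.acinus_radius_um
    smooth = ndimage.gaussian_filter(
        core.astype(np.float32), sigma=spec.lung_smooth_vox
    )
    lung_vox = core | (smooth >= 0.5)
    if np.any(airway.as_bool() & ~lung_vox):
        raise PhantomGeometryError("airway mask not contained in the lung hull")
    lung = BinaryMask(lung_vox.astype(np.uint8), spec.spacing, MaskLabel.LUNG)
    lung_idx = np.argwhere(lung_vox)
    center = lung_idx.mean(axis=0) * spacing
    mean_semi = float(
        ((lung_vox.sum() * spacing.prod()) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    )

    tips = tree.tips_um()
    labels = np.zeros(tuple(shape), dtype=np.uint8)
    acinus_map = np.zeros(tuple(shape), dtype=np.int32)
    labels[airway.as_bool()] = AIRWAY
    paren = lung_vox & ~airway.as_bool()
    idx = np.argwhere(paren)
    vox_um = idx * spacing
    dist, nearest = cKDTree(tips).query(vox_um)
    acinus_map[tuple(idx.T)] = nearest.astype(np.int32) + 1
    # per-acinus PAR cut at the par_cut_frac distance quantile, so PAR holds
    # that fraction of the acinus volume (default: equal-volume split)
    region = np.full(len(idx), DAR, dtype=np.uint8)
    for a in range(len(tips)):
        sel = nearest == a
        if sel.any():
            cut = np.quantile(dist[sel], spec.par_cut_frac)
            region[sel & (dist <= cut)] = PAR
    labels[tuple(idx.T)] = region

    counts = np.bincount(nearest, minlength=len(tips))
    med = np.median(counts)
    if med > 0 and counts.min() < min_acinus_frac * med:
        raise PhantomGeometryError(
            f"acinus volume collapsed (min {counts.min()} vs median {med:.0f} voxels)"
        )
    reg = RegionLabels(
        labels=labels,
        acinus_map=acinus_map,
        tip_coords_um=tips,
        lung_center_um=center,
        mean_semi_axis_um=mean_semi,
        dist_to_airway_um=dist_to_airway,
    )
    return lung, reg


# ---------------------------------------------------------------------------
# deposition


@dataclass
class PhantomTruth:
    """Exact generator-side accounting of deposited NP signal.

    All sums are event bookkeeping (event count × per-event mass), computed
    before rendering, so they are exact regardless of blob overlap, edge
    clipping or later thresholding.
    """

    bronchial_signal: float
    acinar_signal: float
    par_signal: float
    dar_signal: float
    per_acinus_signal: dict[int, float]
    n_events: int
    event_mass: float
    event_voxels: np.ndarray = field(repr=False)  # (n, 3) int voxel indices
    event_is_bronchial: np.ndarray = field(repr=False)  # (n,) bool

    @property
    def total_signal(self) -> float:
        return self.bronchial_signal + self.acinar_signal

    @property
    def bronchial_fraction(self) -> float:
        return self.bronchial_signal / self.total_signal

    def to_dict(self) -> dict:
        return {
            "bronchial_signal": self.bronchial_signal,
            "acinar_signal": self.acinar_signal,
            "par_signal": self.par_signal,
            "dar_signal": self.dar_signal,
            "bronchial_fraction": self.bronchial_fraction,
            "n_events": self.n_events,
            "event_mass": self.event_mass,
            "per_acinus_signal": {str(k): v for k, v in sorted(self.per_acinus_signal.items())},
        }


def _weighted_choice(rng, n, weights):
    p = np.asarray(weights, float)
    p = p / p.sum()
    return rng.choice(len(p), size=n, p=p)


def simulate_deposition(
    spec: PhantomSpec,
    tree: AirwayTree,
    airway: BinaryMask,
    lung: BinaryMask,
    regions: RegionLabels,
    generation_map: np.ndarray | None = None,
    _rng: np.random.Generator | None = None,
) -> tuple[ImageStack, PhantomTruth]:
    """Place NP deposition events and render the NP channel.

    Non-uniform routes put ``bronchial_fraction_target`` of the events on
    airway-lumen voxels (weighted toward low generations by
    ``bronchial_gen_decay`` and toward the lumen interior) and the rest
    across acini with weight ∝ volume · exp(−λ·d̂), d̂ being the tip's
    distance to the lung centroid over the mean lung semi-axis; within an
    acinus a ``par_bias`` share lands in PAR.  The UNIFORM route samples
    voxels uniformly over the whole lung instead.  Every event renders as a
    Gaussian blob of width ``render_sigma_um`` clipped at 3σ; blobs near
    the grid edge are renormalized so their in-grid mass equals the event
    mass.
    """
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 2])
    )
    spacing = np.asarray(spec.spacing, float)
    labels = regions.labels
    n = int(spec.n_np_events)
    mass = spec.event_mass

    airway_idx = np.argwhere(airway.as_bool())
    if spec.route is Route.UNIFORM:
        lung_idx = np.argwhere(lung.as_bool())
        events = lung_idx[rng.integers(0, len(lung_idx), size=n)]
    else:
        n_bronchial = int(round(spec.bronchial_fraction_target * n))
        if n_bronchial > 0 and len(airway_idx) == 0:
            raise ValueError("bronchial deposition requested but airway mask is empty")
        parts = []
        if n_bronchial > 0:
            edt = ndimage.distance_transform_edt(airway.voxels, sampling=spacing)
            d_wall = edt[tuple(airway_idx.T)]
            # instillate pools in the lumen interior: keep blob centers clear
            # of the wall where the airway caliber allows it
            deep = d_wall >= 1.5 * spec.render_sigma_um
            cand_idx = airway_idx[deep] if deep.sum() >= 100 else airway_idx
            cand_d = d_wall[deep] if deep.sum() >= 100 else d_wall
            w = cand_d**2 + 1e-9
            if generation_map is not None and spec.bronchial_gen_decay > 0:
                g = generation_map[tuple(cand_idx.T)].astype(float)
                w = w * np.exp(-spec.bronchial_gen_decay * np.maximum(g, 0))
            parts.append(cand_idx[_weighted_choice(rng, n_bronchial, w)])
        n_acinar = n - n_bronchial
        if n_acinar > 0:
            # alveolar airspace only: the peribronchial wall shell is tissue
            open_paren = ((labels == PAR) | (labels == DAR)) & (
                regions.dist_to_airway_um > spec.wall_exclusion_um
            )
            paren = np.argwhere(open_paren)
            aci = regions.acinus_map[tuple(paren.T)]
            is_par = labels[tuple(paren.T)] == PAR
            n_aci = len(regions.tip_coords_um)
            vol = np.bincount(aci - 1, minlength=n_aci).astype(float)
            d_hat = np.linalg.norm(
                regions.tip_coords_um - regions.lung_center_um, axis=1
            ) / regions.mean_semi_axis_um
            w_aci = vol * np.exp(-spec.central_bias * d_hat)
            chosen = _weighted_choice(rng, n_acinar, w_aci)
            # per-acinus voxel pools, split PAR/DAR
            order = np.argsort(aci, kind="stable")
            acinar_events = np.empty((n_acinar, 3), dtype=np.int64)
            for a in np.unique(chosen):
                take = np.where(chosen == a)[0]
                pool = order[np.searchsorted(aci[order], a + 1, side="left"):
                             np.searchsorted(aci[order], a + 1, side="right")]
                par_pool = pool[is_par[pool]]
                dar_pool = pool[~is_par[pool]]
                if spec.par_bias is None or len(par_pool) == 0 or len(dar_pool) == 0:
                    pick = pool[rng.integers(0, len(pool), size=len(take))]
                else:
                    to_par = rng.random(len(take)) < spec.par_bias
                    pick = np.empty(len(take), dtype=np.int64)
                    pick[to_par] = par_pool[rng.integers(0, len(par_pool), size=int(to_par.sum()))]
                    pick[~to_par] = dar_pool[rng.integers(0, len(dar_pool), size=int((~to_par).sum()))]
                acinar_events[take] = paren[pick]
            parts.append(acinar_events)
        events = np.concatenate(parts) if parts else np.empty((0, 3), dtype=np.int64)

    ev_labels = labels[tuple(events.T)]
    is_bronchial = ev_labels == AIRWAY
    is_par = ev_labels == PAR
    aci_of_event = regions.acinus_map[tuple(events.T)]
    per_acinus = {
        int(a): float(c * mass)
        for a, c in zip(*np.unique(aci_of_event[aci_of_event > 0], return_counts=True))
    }
    truth = PhantomTruth(
        bronchial_signal=float(is_bronchial.sum() * mass),
        acinar_signal=float((~is_bronchial).sum() * mass),
        par_signal=float(is_par.sum() * mass),
        dar_signal=float((~is_bronchial & ~is_par).sum() * mass),
        per_acinus_signal=per_acinus,
        n_events=n,
        event_mass=mass,
        event_voxels=events,
        event_is_bronchial=is_bronchial,
    )

    np_vox = _render_events(events, mass, spec, lung.as_bool())
    stack = ImageStack(np_vox, spec.spacing, ChannelRole.NP)
    return stack, truth


def _render_events(
    events: np.ndarray, mass: float, spec: PhantomSpec, lung_vox: np.ndarray
) -> np.ndarray:
    """Render events as truncated Gaussian blobs, mass-conserving inside the lung.

    Each event's kernel is renormalized by its local lung coverage (the
    fraction of the kernel that falls on lung tissue), so the rendered
    in-lung mass of every event equals the event mass exactly: deposited
    particles sit in tissue, and without this correction blobs near the
    pleural border would bleed part of their fluorescence into the void.
    """
    shape = tuple(spec.grid_shape)
    sigma_vox = spec.render_sigma_um / np.asarray(spec.spacing, float)
    img = np.zeros(shape, dtype=np.float64)
    if len(events) == 0:
        return img
    coverage = ndimage.gaussian_filter(
        lung_vox.astype(np.float64), sigma=sigma_vox, truncate=3.0, mode="constant"
    )
    amp = mass / np.maximum(coverage[tuple(events.T)], 1e-6)
    np.add.at(img, tuple(events.T), amp)
    return ndimage.gaussian_filter(img, sigma=sigma_vox, truncate=3.0, mode="constant")


# ---------------------------------------------------------------------------
# autofluorescence and observed NP channel


def render_autofluorescence(
    lung: BinaryMask,
    airway: BinaryMask,
    spec: PhantomSpec,
    _rng: np.random.Generator | None = None,
) -> ImageStack:
    """Tissue AF channel: lung parenchyma + bright airway walls + texture.

    Base level inside the lung, an elevated shell on airway walls (the wall
    tissue is AF-bright while the lumen is dark), a smooth multiplicative
    texture field, and additive Gaussian noise; near-dark background.
    """
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 3])
    )
    lung_b = lung.as_bool()
    airway_b = airway.as_bool()
    wall = ndimage.binary_dilation(airway_b, iterations=2) & ~airway_b
    af = np.full(lung.shape, spec.af_background, dtype=np.float64)
    af[lung_b] = spec.af_base
    af[wall & lung_b] = spec.af_base * spec.af_wall_gain
    af[airway_b] = spec.af_background  # lumen is air: dark
    texture = ndimage.gaussian_filter(rng.standard_normal(lung.shape), sigma=8.0)
    texture = 1.0 + spec.af_texture_sd * texture / max(texture.std(), 1e-12)
    af *= np.clip(texture, 0.1, None)
    af += rng.normal(0.0, spec.af_noise_sd, size=lung.shape)
    return ImageStack(np.clip(af, 0, None), spec.spacing, ChannelRole.AF)


def compose_observed_np(
    np_stack: ImageStack,
    af_stack: ImageStack,
    spec: PhantomSpec,
    _rng: np.random.Generator | None = None,
) -> ImageStack:
    """Realistic NP channel: rendered NP + AF spectral bleed-through + noise."""
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 4])
    )
    vox = (
        np_stack.voxels
        + spec.np_af_bleed * af_stack.voxels
        + rng.normal(0.0, spec.np_noise_sd, size=np_stack.shape)
    )
    return ImageStack(np.clip(vox, 0, None), np_stack.spacing, ChannelRole.NP)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class Phantom:
    """One fully generated synthetic lung with ground truth."""

    spec: PhantomSpec
    tree: AirwayTree
    airway: BinaryMask
    lung: BinaryMask
    regions: RegionLabels
    generation_map: np.ndarray
    np_stack: ImageStack
    af_stack: ImageStack
    truth: PhantomTruth

    def observed_np(self) -> ImageStack:
        """NP channel with AF bleed-through and sensor noise added."""
        return compose_observed_np(self.np_stack, self.af_stack, self.spec)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(out / "np.tif", ImageStack(
            self.np_stack.voxels.astype(np.float32), self.spec.spacing, ChannelRole.NP))
        write_stack(out / "af.tif", ImageStack(
            self.af_stack.voxels.astype(np.float32), self.spec.spacing, ChannelRole.AF))
        write_stack(out / "airway.tif", self.airway)
        write_stack(out / "lung.tif", self.lung)
        import tifffile

        tifffile.imwrite(out / "labels.tif", self.regions.labels)
        (out / "truth.json").write_text(
            json.dumps(self.truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.tree.to_swc(out / "tree.swc")


def generate_phantom(spec: PhantomSpec, *, max_attempts: int = 8) -> Phantom:
    """Run the full generator pipeline; pure function of (spec, seed).

    Sub-stages draw from independent child streams of ``spec.seed`` in a
    fixed order (tree, deposition, AF), so adding options to one stage never
    shifts the draws of another.  If the acinar tessellation degenerates the
    tree is regrown with a jittered sub-seed, up to ``max_attempts`` times.
    """
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        seed = (int(spec.seed) + attempt * 1_000_003) & 0x7FFFFFFF
        eff = replace(spec, seed=seed) if attempt else spec
        try:
            tree = generate_airway_tree(eff)
            airway, gen_map = rasterize_tree(tree, eff, return_generations=True)
            lung, regions = build_lung_and_acini(tree, airway, eff)
            break
        except PhantomGeometryError as err:  # retry with jittered seed
            last_err = err
    else:
        raise PhantomGeometryError(
            f"phantom geometry failed after {max_attempts} attempts: {last_err}"
        )
    np_stack, truth = simulate_deposition(eff, tree, airway, lung, regions, gen_map)
    af_stack = render_autofluorescence(lung, airway, eff)
    return Phantom(eff, tree, airway, lung, regions, gen_map, np_stack, af_stack, truth)
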