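"""Segmentation evaluation: volumetric Dice and centerline Dice (clDice).

clDice measures topological completeness of tubular segmentations: the
skeleton of the prediction should lie inside the reference mask (topology
precision) and the skeleton of the reference inside the prediction
(topology sensitivity); clDice is their harmonic mean.  For airway trees it
penalizes missed or hallucinated branches that voxel Dice barely notices.

Empty-mask conventions (the literature varies, so they are pinned here):
both masks empty → 1.0; exactly one empty → 0.0; an empty skeleton of a
nonempty mask contributes 0 to its ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize as _sk_skeletonize

from .imagio import BinaryMask, MaskLabel

SkeletonFn = Callable[[np.ndarray], np.ndarray]


def dice(pred: BinaryMask | np.ndarray, ref: BinaryMask | np.ndarray) -> float:
    """Volumetric Dice overlap 2|P∩G|/(|P|+|G|); 1.0 when both masks are empty."""
    p = _as_bool(pred)
    g = _as_bool(ref)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def skeletonize3d(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Thin medial-axis skeleton (Lee 3D thinning); empty in → empty out."""
    m = _as_bool(mask)
    if not m.any():
        return np.zeros_like(m)
    return _sk_skeletonize(m).astype(bool)


@dataclass
class SegScore:
    dice: float
    cldice: float
    topo_precision: float
    topo_sensitivity: float


def cldice(
    pred: BinaryMask | np.ndarray,
    ref: BinaryMask | np.ndarray,
    skeleton_fn: SkeletonFn = skeletonize3d,
) -> SegScore:
    """Centerline Dice with its topology precision/sensitivity components.

    topo_precision = |skel(P) ∩ G| / |skel(P)|,
    topo_sensitivity = |skel(G) ∩ P| / |skel(G)|,
    cldice = their harmonic mean.  The skeletonizer is pluggable so metric
    sensitivity to the thinning algorithm can be measured.
    """
    p = _as_bool(pred)
    g = _as_bool(ref)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    d = dice(p, g)
    if not p.any() and not g.any():
        return SegScore(d, 1.0, 1.0, 1.0)
    if not p.any() or not g.any():
        return SegScore(d, 0.0, 0.0, 0.0)
    skel_p = skeleton_fn(p)
    skel_g = skeleton_fn(g)
    tp = float((skel_p & g).sum() / skel_p.sum()) if skel_p.any() else 0.0
    ts = float((skel_g & p).sum() / skel_g.sum()) if skel_g.any() else 0.0
    cl = 2.0 * tp * ts / (tp + ts) if tp + ts > 0 else 0.0
    return SegScore(d, cl, tp, ts)


@dataclass
class SetScore:
    """Per-image scores and their unweighted mean over an evaluation set."""

    per_image: pd.DataFrame
    mean_dice: float
    mean_cldice: float

    def to_dict(self) -> dict:
        return {
            "mean_dice": self.mean_dice,
            "mean_cldice": self.mean_cldice,
            "per_image": self.per_image.to_dict(orient="records"),
        }


def evaluate_set(
    pairs: Sequence[tuple[BinaryMask | np.ndarray, BinaryMask | np.ndarray]],
    ids: Sequence[str] | None = None,
    skeleton_fn: SkeletonFn = skeletonize3d,
) -> SetScore:
    """Score every (pred, ref) pair and report the unweighted per-image mean."""
    if len(pairs) == 0:
        raise ValueError("need at least one (pred, ref) pair")
    if ids is None:
        ids = [str(i) for i in range(len(pairs))]
    rows = []
    for img_id, (p, g) in zip(ids, pairs):
        s = cldice(p, g, skeleton_fn)
        rows.append(
            {
                "id": img_id,
                "dice": s.dice,
                "cldice": s.cldice,
                "topo_precision": s.topo_precision,
                "topo_sensitivity": s.topo_sensitivity,
            }
        )
    table = pd.DataFrame(rows)
    return SetScore(table, float(table["dice"].mean()), float(table["cldice"].mean()))


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def mask_pair(p: np.ndarray, g: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """Convenience: wrap two arrays as airway-labelled masks."""
    return (
        BinaryMask(np.asarray(p, dtype=np.uint8), spacing, MaskLabel.AIRWAY),
        BinaryMask(np.asarray(g, dtype=np.uint8), spacing, MaskLabel.AIRWAY),
    )
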