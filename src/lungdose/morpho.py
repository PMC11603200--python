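"""Airway-tree morphometry from a binary mask.

The pipeline is: 3D thinning → skeleton-voxel graph (26-connectivity) →
spur pruning → root selection → maximal junction-free paths as branches →
per-branch generation (Weibel numbering: +1 at every junction), length,
diameter and branching angle, summarized per generation.

Diameter estimation uses the anisotropy-aware Euclidean distance transform
sampled along the branch centerline, away from junctions (carina bulges
inflate the local radius); each sample takes the local EDT ridge maximum
because the thinned skeleton zigzags off the true medial axis.

Root selection defaults to the skeleton endpoint with the largest inscribed
radius — the trachea end is the widest airway — and can be overridden with
an explicit hint.
"""

from __future__ import annotations

import warnings
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .imagio import BinaryMask
from .segmetrics import skeletonize3d
from .tree import AirwayTree, Branch

_NEIGHBORS = [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]


def extract_tree(
    airway_mask: BinaryMask,
    root_hint: tuple[int, int, int] | str = "auto",
    *,
    prune_surface_vox: float = 1.4,
    prune_length_factor: float = 0.5,
    prune_extra_vox: float = 1.0,
    fit_span_k: int = 5,
) -> AirwayTree:
    """Centerline tree of an airway mask.

    Parameters
    ----------
    airway_mask : BinaryMask
        Binary airway segmentation; if it has several 26-connected
        components the largest is used (with a warning).
    root_hint : (z, y, x) voxel index or "auto"
        Trachea-end location.  "auto" picks the skeleton endpoint with the
        largest inscribed radius.
    prune_surface_vox, prune_length_factor, prune_extra_vox
        Spur criteria: a terminal twig is removed when its endpoint's
        inscribed radius is below ``prune_surface_vox`` voxels (surface
        ridge) or its length is below ``prune_length_factor · local_radius
        + prune_extra_vox · voxel`` (in-tube stub).
    """
    spacing = np.asarray(airway_mask.spacing, float)
    mask = airway_mask.as_bool()
    if not mask.any():
        raise ValueError("airway mask is empty")
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        warnings.warn(f"airway mask has {n_comp} components; using the largest")
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))

    skel = skeletonize3d(mask)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    G = _skeleton_graph(skel, spacing)
    _collapse_cycles(G, edt, spacing)

    root = _pick_root(G, edt, mask, root_hint)
    _prune_spurs(G, root, edt, spacing, prune_surface_vox, prune_length_factor,
                 prune_extra_vox)
    return _graph_to_tree(G, root, edt, spacing, fit_span_k)


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    voxels = set(map(tuple, np.argwhere(skel)))
    G = nx.Graph()
    G.add_nodes_from(voxels)
    for v in voxels:
        for off in _NEIGHBORS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxels and not G.has_edge(v, w):
                G.add_edge(v, w, length=float(np.linalg.norm(np.array(off) * spacing)))
    return G


def _collapse_cycles(G: nx.Graph, edt: np.ndarray, spacing: np.ndarray) -> None:
    """Contract every 2-edge-connected component to its widest voxel.

    A thinned airway tree should be a topological tree; residual cycles are
    26-neighbourhood triangle chords and 'collar' loops that thinning
    leaves around thick junctions.  Each cyclic cluster is replaced by its
    maximum-inscribed-radius member (the junction centre), with all
    outside edges reattached there.
    """
    if G.number_of_edges() < G.number_of_nodes():
        return
    bridges = set(frozenset(e) for e in nx.bridges(G))
    cyc_edges = [e for e in G.edges if frozenset(e) not in bridges]
    sub = G.edge_subgraph(cyc_edges)
    large = False
    for comp in [c for c in nx.connected_components(sub)]:
        comp = set(comp)
        rep = max(comp, key=lambda n: edt[n])
        pts = np.array(list(comp), float) * spacing
        extent = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        if extent > 5.0 * max(float(edt[rep]), float(spacing.mean())):
            # a large cyclic core means genuinely fused branches: keep its
            # paths and let a spanning tree cut the loop chords instead
            large = True
            continue
        external = set()
        for n in comp:
            external.update(m for m in G.neighbors(n) if m not in comp)
        G.remove_nodes_from(comp - {rep})
        for m in external:
            if m in G and not G.has_edge(rep, m):
                G.add_edge(rep, m, length=float(
                    np.linalg.norm((np.array(rep) - np.array(m)))
                ))
    if large:
        mst = nx.minimum_spanning_tree(G, weight="length")
        G.remove_edges_from([e for e in list(G.edges) if not mst.has_edge(*e)])


def _pick_root(G: nx.Graph, edt, mask, root_hint):
    if isinstance(root_hint, str):
        if root_hint != "auto":
            raise ValueError("root_hint must be a voxel index or 'auto'")
        ends = [n for n in G.nodes if G.degree(n) <= 1] or list(G.nodes)
        return max(ends, key=lambda n: edt[n])
    hint = tuple(int(c) for c in root_hint)
    if not mask[hint]:
        raise ValueError(f"root hint {hint} is outside the airway mask")
    return min(G.nodes, key=lambda n: sum((a - b) ** 2 for a, b in zip(n, hint)))


def _leaf_path(G: nx.Graph, leaf):
    """Walk from a leaf to the first junction (or the far end of a chain)."""
    path = [leaf]
    prev = None
    cur = leaf
    while True:
        nbrs = [n for n in G.neighbors(cur) if n != prev]
        if G.degree(cur) >= 3 and cur != leaf:
            return path
        if not nbrs:
            return path
        prev, cur = cur, nbrs[0]
        path.append(cur)


def _prune_spurs(G, root, edt, spacing, surface_vox, length_factor, extra_vox):
    """Iteratively delete thinning spurs while keeping genuine (eroded) tips.

    A terminal twig is deleted when it looks like a thinning artifact
    rather than an airway ending: either its endpoint hugs the mask
    surface (endpoint radius below ``surface_vox`` voxels — a surface-bump
    ridge), or it is shorter than ``length_factor`` of the local tube
    radius (a stub that never leaves the parent airway).  Real terminal
    branches — even when thinning has eroded most of their length — end in
    a cap whose inscribed radius matches the branch caliber, which
    distinguishes them from both spur classes.
    """
    mean_vox = float(spacing.mean())
    changed = True
    while changed:
        changed = False
        candidates = {}
        for leaf in [n for n in G.nodes if G.degree(n) == 1 and n != root]:
            path = _leaf_path(G, leaf)
            end = path[-1]
            if G.degree(end) < 3:  # whole component is a chain: keep it
                continue
            length = sum(
                G.edges[a, b]["length"] for a, b in zip(path[:-1], path[1:])
            )
            # local scale one step into the twig: junction nodes produced by
            # collar contraction carry inflated radii
            local_r = float(edt[path[-2]]) if len(path) >= 2 else float(edt[end])
            is_surface_spur = float(edt[leaf]) < surface_vox * mean_vox
            is_stub = length < length_factor * local_r + extra_vox * mean_vox
            if is_surface_spur or is_stub:
                candidates[leaf] = (path, length, end)
        # a junction whose distal side consists only of prune candidates is a
        # genuine tube ending (e.g. a forked cap): keep its longest twig
        by_junction: dict = {}
        for leaf, (path, length, end) in candidates.items():
            by_junction.setdefault(end, []).append((length, leaf))
        exempt = set()
        for end, twigs in by_junction.items():
            if G.degree(end) - len(twigs) <= 1:
                exempt.add(max(twigs)[1])
        for leaf, (path, length, end) in candidates.items():
            if leaf in exempt or leaf not in G:
                continue
            G.remove_nodes_from(path[:-1])
            changed = True


def _graph_to_tree(G, root, edt, spacing, k) -> AirwayTree:
    if G.degree(root) == 0:
        raise ValueError("root is isolated after pruning")
    branches: dict[int, Branch] = {}
    next_id = [0]
    mean_vox = float(spacing.mean())

    def walk(start, first, parent_id, generation):
        """Trace one branch from ``start`` through ``first`` to the next node
        of degree != 2, then recurse into its children."""
        path = [start, first]
        prev, cur = start, first
        while G.degree(cur) == 2:
            nxt = [n for n in G.neighbors(cur) if n != prev][0]
            prev, cur = cur, nxt
            path.append(cur)
        pts_um = np.asarray(path, float) * spacing
        bid = next_id[0]
        next_id[0] += 1
        diam = branch_diameter(path, edt, spacing)
        branches[bid] = Branch(bid, pts_um, generation, diam, parent_id)
        if parent_id is not None:
            branches[parent_id].children.append(bid)
            branches[bid].angle_deg = branching_angle(
                branches[bid], branches[parent_id], fit_span_k=k
            )
        end = path[-1]
        for nbr in G.neighbors(end):
            if nbr != prev:
                walk(end, nbr, bid, generation + 1)

    first = next(iter(G.neighbors(root)))
    walk(root, first, None, 0)
    # guard against pathological recursion output
    if not branches:
        raise ValueError("no branches extracted")
    tree = AirwayTree(branches, root_id=0)
    _ = mean_vox
    return tree


def branch_diameter(
    path_vox, edt: np.ndarray, spacing: np.ndarray | tuple[float, float, float]
) -> float:
    """Mean airway diameter along a centerline path (µm).

    Samples the distance transform along the path, excluding a junction
    zone of one local radius at each end; the ridge-corrected inscribed
    radius is doubled to a diameter.
    """
    spacing = np.asarray(spacing, float)
    if len(path_vox) == 0:
        raise ValueError("empty branch path")
    # ridge-corrected sampling: the thinned skeleton zigzags off the true
    # medial axis by up to a voxel, so take the local EDT maximum instead
    # of the (systematically low) on-skeleton value
    shape = edt.shape
    vals = np.empty(len(path_vox))
    for i, p in enumerate(path_vox):
        sl = tuple(
            slice(max(0, c - 1), min(n, c + 2)) for c, n in zip(p, shape)
        )
        vals[i] = edt[sl].max()
    pts = np.asarray(path_vox, float) * spacing
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1] if len(arc) > 1 else 0.0
    lo, hi = vals[0], vals[-1]
    keep = (arc >= lo) & (arc <= total - hi)
    if not keep.any():  # branch fully inside the junction-exclusion zones
        keep = np.ones_like(vals, bool)
    # the nearest background center of a digitized radius-R tube sits at
    # distance ~R from the axis, so 2·EDT is already on the diameter scale
    return float(2.0 * vals[keep].mean())


def _window_direction(points: np.ndarray, from_start: bool, skip_um: float, k: int):
    """Direction over a k-point window after skipping ``skip_um`` of arc.

    Skipping matters at junctions: the thinned centerline of a daughter
    first crosses from the parent's axis to its own, so the very first
    points overstate the branching angle.
    """
    pts = points if from_start else points[::-1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    start = int(np.searchsorted(arc, min(skip_um, arc[-1] * 0.5)))
    stop = min(len(pts) - 1, start + max(1, k - 1))
    if stop <= start:
        start, stop = 0, len(pts) - 1
    d = pts[stop] - pts[start]
    return d if from_start else -d


def branching_angle(branch: Branch, parent: Branch, fit_span_k: int = 5) -> float:
    """Angle (degrees) between a branch and its parent's direction.

    The parent direction is fit over a window at its distal end and the
    child direction over a window just beyond the junction collar (one
    parent radius of arc is skipped on each side); 0° is a collinear
    continuation.
    """
    k = max(2, fit_span_k)
    p = parent.points_um
    c = branch.points_um
    if len(p) < 2 or len(c) < 2:
        raise ValueError("both branches need >= 2 points")
    r_junc = parent.diameter_um / 2.0
    u = _window_direction(p, from_start=False, skip_um=r_junc, k=k)
    v = _window_direction(c, from_start=True, skip_um=r_junc, k=k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate (coincident) points")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def morphometry_table(tree: AirwayTree) -> pd.DataFrame:
    """Per-generation branch count and mean±sd of length/diameter/angle.

    The table carries ``max_generation`` and ``min_tip_diameter_um`` as
    attributes (``df.attrs``) for the whole-tree summary figures.
    """
    per = tree.to_table()
    rows = []
    for gen, grp in per.groupby("generation"):
        rows.append(
            {
                "generation": gen,
                "n_branches": len(grp),
                "length_um_mean": grp["length_um"].mean(),
                "length_um_sd": grp["length_um"].std(ddof=0),
                "diameter_um_mean": grp["diameter_um"].mean(),
                "diameter_um_sd": grp["diameter_um"].std(ddof=0),
                "angle_deg_mean": grp["angle_deg"].mean(),
                "angle_deg_sd": grp["angle_deg"].std(ddof=0),
            }
        )
    table = pd.DataFrame(rows)
    tips = per[per["terminal"]]
    table.attrs["max_generation"] = int(per["generation"].max())
    table.attrs["min_tip_diameter_um"] = float(tips["diameter_um"].min())
    return table
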