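"""Airway-tree container shared by the phantom generator and morphometry.

A tree is a rooted collection of branches.  A *branch* is a maximal
junction-free centerline path; its points are (z, y, x) coordinates in µm.
Generation numbering is Weibel-style: the root (trachea end) is generation 0
and every junction increments the generation of *both* daughters, so in a
monopodial (rodent-like) lung the main stem accumulates one generation per
lateral take-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Branch:
    """One junction-free airway segment."""

    branch_id: int
    points_um: np.ndarray  # (n, 3) float, (z,y,x) µm, ordered root→tip
    generation: int
    diameter_um: float
    parent: int | None = None  # branch_id of parent, None for root
    children: list[int] = field(default_factory=list)
    angle_deg: float | None = None  # branching angle vs parent direction

    @property
    def length_um(self) -> float:
        d = np.diff(self.points_um, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    @property
    def is_terminal(self) -> bool:
        return not self.children


@dataclass
class AirwayTree:
    """Rooted airway tree: acyclic, single root, child generation = parent + 1."""

    branches: dict[int, Branch]
    root_id: int

    def __post_init__(self) -> None:
        if self.root_id not in self.branches:
            raise ValueError("root_id not among branches")
        for b in self.branches.values():
            if b.branch_id == self.root_id:
                if b.parent is not None:
                    raise ValueError("root branch must have no parent")
            elif b.parent is None or b.parent not in self.branches:
                raise ValueError(f"branch {b.branch_id} lacks a valid parent")
            elif self.branches[b.parent].generation + 1 != b.generation:
                raise ValueError(
                    f"branch {b.branch_id}: generation must be parent's + 1"
                )
            if len(b.points_um) < 2:
                raise ValueError(f"branch {b.branch_id} needs >=2 points")

    @property
    def root(self) -> Branch:
        return self.branches[self.root_id]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def max_generation(self) -> int:
        return max(b.generation for b in self.branches.values())

    def terminal_branches(self) -> list[Branch]:
        return [b for b in self.branches.values() if b.is_terminal]

    def tips_um(self) -> np.ndarray:
        """(n_tips, 3) µm coordinates of terminal-branch endpoints."""
        return np.array([b.points_um[-1] for b in self.terminal_branches()])

    def to_table(self) -> pd.DataFrame:
        """Per-branch table (id, parent, generation, length, diameter, angle)."""
        rows = [
            {
                "branch_id": b.branch_id,
                "parent": -1 if b.parent is None else b.parent,
                "generation": b.generation,
                "length_um": b.length_um,
                "diameter_um": b.diameter_um,
                "angle_deg": np.nan if b.angle_deg is None else b.angle_deg,
                "terminal": b.is_terminal,
            }
            for b in sorted(self.branches.values(), key=lambda b: b.branch_id)
        ]
        return pd.DataFrame(rows)

    def to_swc(self, path: str | Path) -> None:
        """Write the centerline as a standard 7-column SWC file.

        SWC coordinates are written (x, y, z) in µm; radius is half the branch
        diameter.  Sample ids are 1-based; the root sample has parent -1.
        """
        lines = ["# id type x y z radius parent  (µm; type 0 = undefined)"]
        next_id = 1
        # branch_id -> swc id of its last point (for children to attach)
        tail_ids: dict[int, int] = {}
        order = self._preorder()
        for bid in order:
            b = self.branches[bid]
            parent_swc = -1 if b.parent is None else tail_ids[b.parent]
            pts = b.points_um
            start = 0 if b.parent is None else 1  # first point repeats the junction
            for i in range(start, len(pts)):
                z, y, x = pts[i]
                lines.append(
                    f"{next_id} 0 {x:.3f} {y:.3f} {z:.3f} {b.diameter_um / 2:.3f} {parent_swc}"
                )
                parent_swc = next_id
                next_id += 1
            tail_ids[bid] = parent_swc
        Path(path).write_text("\n".join(lines) + "\n")

    def _preorder(self) -> list[int]:
        order, stack = [], [self.root_id]
        while stack:
            bid = stack.pop()
            order.append(bid)
            stack.extend(sorted(self.branches[bid].children, reverse=True))
        return order
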