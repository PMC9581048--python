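"""Lineage trees from time-lapse microscopy: validation, filtering, collapse.

A clone is the family tree grown from one founder cell. Cells are labelled
by their lineage path: the founder has the empty label, its daughters are
``(1,)`` and ``(2,)``, and in general ``(x1, ..., xj)`` with ``xj in {1, 2}``
is a generation-``j`` cell. Each cell carries exactly one terminal fate —
``divided``, ``died`` or ``lost`` (left the field of view / outlived the
experiment) — and the time of that event in hours from stimulation.

Because division, destiny and death times are strongly shared within a
family, a tree can be summarised ("collapsed") by per-generation average
event times, which is what downstream correlation and distribution-fitting
analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cell",
    "FamilyTree",
    "CollapsedClone",
    "TreeStructureError",
    "filter_clones",
    "collapse_clone",
    "within_clone_cv",
    "clone_fate_table",
]

FATES = ("divided", "died", "lost")


class TreeStructureError(ValueError):
    """Raised when a family tree violates its structural invariants."""


@dataclass(frozen=True)
class Cell:
    """One cell: lineage label, terminal fate, and event time (hours)."""

    label: tuple[int, ...]
    fate: str
    fate_time: float

    def __post_init__(self):
        if any(x not in (1, 2) for x in self.label):
            raise TreeStructureError(f"label entries must be 1/2: {self.label}")
        if self.fate not in FATES:
            raise TreeStructureError(f"unknown fate {self.fate!r}")
        if not np.isfinite(self.fate_time) or self.fate_time < 0:
            raise TreeStructureError(
                f"fate_time must be finite and >= 0, got {self.fate_time}")

    @property
    def generation(self) -> int:
        return len(self.label)

    @property
    def parent_label(self) -> Optional[tuple[int, ...]]:
        return self.label[:-1] if self.label else None


@dataclass
class FamilyTree:
    """A validated clonal family tree."""

    clone_id: str
    cells: dict[tuple[int, ...], Cell] = field(default_factory=dict)

    @classmethod
    def from_cells(cls, clone_id, cells: Iterable[Cell],
                   validate: bool = True) -> "FamilyTree":
        tree = cls(clone_id=str(clone_id),
                   cells={c.label: c for c in cells})
        if validate:
            tree.validate()
        return tree

    @property
    def founder(self) -> Cell:
        return self.cells[()]

    def validate(self) -> None:
        if () not in self.cells:
            raise TreeStructureError(f"clone {self.clone_id}: no founder cell")
        for label, cell in self.cells.items():
            if label:
                parent = self.cells.get(cell.parent_label)
                if parent is None:
                    raise TreeStructureError(
                        f"clone {self.clone_id}: cell {label} has no parent")
                if parent.fate != "divided":
                    raise TreeStructureError(
                        f"clone {self.clone_id}: parent of {label} did not "
                        "divide")
                if cell.fate_time <= parent.fate_time:
                    raise TreeStructureError(
                        f"clone {self.clone_id}: cell {label} event at "
                        f"{cell.fate_time} not after parent at "
                        f"{parent.fate_time}")
            n_children = sum(
                1 for d in (1, 2) if label + (d,) in self.cells)
            if cell.fate == "divided" and n_children != 2:
                raise TreeStructureError(
                    f"clone {self.clone_id}: divided cell {label} has "
                    f"{n_children} recorded daughters (needs 2)")
            if cell.fate != "divided" and n_children:
                raise TreeStructureError(
                    f"clone {self.clone_id}: {cell.fate} cell {label} has "
                    "daughters")

    # convenience selections -------------------------------------------
    def divided(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.fate == "divided"]

    def died(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.fate == "died"]

    def max_event_time(self) -> float:
        return max(c.fate_time for c in self.cells.values())

    def birth_time(self, cell: Cell) -> float:
        """Time the cell appeared: its parent's division time (0 for founder)."""
        if not cell.label:
            return 0.0
        return self.cells[cell.parent_label].fate_time


@dataclass
class CollapsedClone:
    """Per-generation average event times for one concordant clone.

    ``div_time_means[g]`` is the mean division time of generation-``g``
    cells; ``t_die`` the mean death time; ``t_ld`` the mean, over died
    cells, of each cell's birth time (its parent's division time), i.e. the
    average time of the clone's last divisions; ``t_div_sub`` the average
    subsequent (inter-)division time, defined only for clones that divided
    at least twice.
    """

    clone_id: str
    div_time_means: tuple[float, ...]
    t_die: float
    t_ld: float
    t_div_sub: Optional[float]

    @property
    def t_div0(self) -> float:
        return self.div_time_means[0]


def filter_clones(trees: Sequence[FamilyTree]
                  ) -> tuple[list[FamilyTree], pd.DataFrame]:
    """Retain clones that divided at least once and ended with a death.

    A clone is retained when its founder divided and the latest recorded
    event time in the tree belongs to a death event (a loss or division
    tied exactly with the latest death still retains the clone). Returns
    the retained trees and an exclusion report with one row per excluded
    clone and its reason.
    """
    retained, report = [], []
    for tree in trees:
        tree.validate()
        if tree.founder.fate != "divided":
            report.append((tree.clone_id, "no division"))
            continue
        t_max = tree.max_event_time()
        deaths = tree.died()
        if not deaths:
            report.append((tree.clone_id, "no death event"))
            continue
        if max(c.fate_time for c in deaths) < t_max:
            report.append((tree.clone_id, "latest event is not a death"))
            continue
        retained.append(tree)
    return retained, pd.DataFrame(report, columns=["clone_id", "reason"])


def collapse_clone(tree: FamilyTree) -> CollapsedClone:
    """Collapse a retained tree to per-generation average event times."""
    deaths = tree.died()
    if not deaths:
        raise TreeStructureError(
            f"clone {tree.clone_id}: cannot collapse without death events")
    by_gen: dict[int, list[float]] = {}
    for c in tree.divided():
        by_gen.setdefault(c.generation, []).append(c.fate_time)
    gens = sorted(by_gen)
    div_means = tuple(float(np.mean(by_gen[g])) for g in gens)
    t_die = float(np.mean([c.fate_time for c in deaths]))
    t_ld = float(np.mean([tree.birth_time(c) for c in deaths]))
    if len(div_means) >= 2:
        t_div_sub = float(np.mean(np.diff(div_means)))
    else:
        t_div_sub = None
    return CollapsedClone(clone_id=tree.clone_id, div_time_means=div_means,
                          t_die=t_die, t_ld=t_ld, t_div_sub=t_div_sub)


_CV_VARIABLES = ("subsequent_division", "last_division", "death")


def _raw_times(tree: FamilyTree, variable: str) -> list[float]:
    if variable == "subsequent_division":
        return [c.fate_time - tree.birth_time(c)
                for c in tree.divided() if c.generation >= 1]
    if variable == "last_division":
        return [tree.birth_time(c) for c in tree.died()]
    if variable == "death":
        return [c.fate_time for c in tree.died()]
    raise ValueError(f"variable must be one of {_CV_VARIABLES}")


def within_clone_cv(trees: Sequence[FamilyTree], variable: str
                    ) -> tuple[pd.DataFrame, float]:
    """Per-clone coefficient of variation (%) of raw per-cell times.

    The CV uses the n-1 sample standard deviation over the clone's raw
    per-cell observations of ``variable``; clones with fewer than two
    observations are skipped and flagged in the returned table. Returns
    the per-clone table and the average CV over scored clones.
    """
    if not trees:
        raise ValueError("empty retained set")
    rows = []
    for tree in trees:
        vals = _raw_times(tree, variable)
        if len(vals) < 2:
            rows.append((tree.clone_id, len(vals), np.nan, True))
            continue
        arr = np.asarray(vals)
        cv = 100.0 * arr.std(ddof=1) / arr.mean()
        rows.append((tree.clone_id, len(vals), cv, False))
    table = pd.DataFrame(rows, columns=["clone_id", "n_obs", "cv_percent",
                                        "skipped"])
    avg = float(table.loc[~table.skipped, "cv_percent"].mean())
    return table, avg


def clone_fate_table(collapsed: Sequence[CollapsedClone]) -> pd.DataFrame:
    """Four key variables per clone: T_div0, subsequent division time,
    time to last division, and time to death. Undefined subsequent times
    (single-division clones) appear as NaN, so pairwise analyses see the
    differing N per variable pair."""
    if not collapsed:
        raise ValueError("empty collapsed set")
    return pd.DataFrame({
        "clone_id": [c.clone_id for c in collapsed],
        "t_div0": [c.t_div0 for c in collapsed],
        "t_div_sub": [np.nan if c.t_div_sub is None else c.t_div_sub
                      for c in collapsed],
        "t_ld": [c.t_ld for c in collapsed],
        "t_die": [c.t_die for c in collapsed],
    })
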