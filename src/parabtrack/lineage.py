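"""Lineage trees and per-cell growth statistics.

Builds parent/daughter trees from the per-frame cell table and computes the
standard single-cell statistics: birth and division length, exponential
growth rate (OLS slope of log length against time), doubling time (birth to
division), pole identity, and the short-cell ("minicell") classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MINICELL_MAX_UM = 2.25  # cells at or below this length are minicells


@dataclass
class CellHistory:
    """All frames of one cell, ordered by frame index."""

    cell_id: int
    frames: np.ndarray      # frame indices
    times: np.ndarray       # h
    lengths: np.ndarray     # um
    parent_id: int | None
    new_pole_end: str = "unknown"

    @property
    def birth_length(self) -> float:
        return float(self.lengths[0])

    @property
    def last_length(self) -> float:
        return float(self.lengths[-1])


@dataclass
class LineageTree:
    """Cell histories plus parent -> (daughter, daughter) links."""

    cells: dict[int, CellHistory]
    children: dict[int, tuple[int, int]] = field(default_factory=dict)
    roots: list[int] = field(default_factory=list)

    def parent_of(self, cell_id: int) -> int | None:
        return self.cells[cell_id].parent_id

    def is_root(self, cell_id: int) -> bool:
        return cell_id in self.roots


def build_lineage(cell_table: pd.DataFrame) -> LineageTree:
    """Assemble a :class:`LineageTree` from the long-format cell table.

    Expected columns: frame, time_h, cell_id, parent_id, length_um and
    optionally new_pole_end.  Cells whose parent is absent from the table
    become roots (with a warning); a parent with a number of daughters
    other than two is flagged as an inconsistency.
    """
    df = cell_table.sort_values(["cell_id", "frame"])
    cells: dict[int, CellHistory] = {}
    for cid, g in df.groupby("cell_id", sort=True):
        pid = g["parent_id"].iloc[0]
        pid = None if pd.isna(pid) else int(pid)
        pole = str(g["new_pole_end"].iloc[0]) if "new_pole_end" in g else "unknown"
        cells[int(cid)] = CellHistory(
            cell_id=int(cid),
            frames=g["frame"].to_numpy(dtype=int),
            times=g["time_h"].to_numpy(dtype=float),
            lengths=g["length_um"].to_numpy(dtype=float),
            parent_id=pid,
            new_pole_end=pole,
        )
    kids: dict[int, list[int]] = {}
    roots: list[int] = []
    for cid, hist in cells.items():
        pid = hist.parent_id
        if pid is None:
            roots.append(cid)
        elif pid not in cells:
            logger.warning("cell %d references absent parent %d; treated as root",
                           cid, pid)
            hist.parent_id = None
            roots.append(cid)
        else:
            kids.setdefault(pid, []).append(cid)
    children: dict[int, tuple[int, int]] = {}
    for pid, ds in kids.items():
        if len(ds) != 2:
            logger.warning("parent %d has %d daughters (expected 2)", pid, len(ds))
            continue
        children[pid] = (ds[0], ds[1])
    return LineageTree(cells=cells, children=children, roots=sorted(roots))


def growth_rate(times: np.ndarray, lengths: np.ndarray) -> tuple[float, float]:
    """Exponential growth rate: OLS slope of ln(length) on time.

    Returns ``(rate_per_h, standard_error)``; ``(nan, nan)`` with fewer
    than 3 frames.
    """
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if times.size < 3:
        return math.nan, math.nan
    fit = stats.linregress(times, np.log(lengths))
    return float(fit.slope), float(fit.stderr)


def doubling_time(tree: LineageTree, cell_id: int) -> float:
    """Birth-to-division time in hours; NaN if birth or division unobserved."""
    hist = tree.cells[cell_id]
    if tree.is_root(cell_id) or cell_id not in tree.children:
        return math.nan
    return float(hist.times[-1] - hist.times[0])


def assign_polarity(tree: LineageTree, cell_table: pd.DataFrame) -> LineageTree:
    """Set each daughter's new pole to the end created at the division plane.

    The daughter occupying the left portion of its parent has its new pole
    on the right, and vice versa; the side is inferred by comparing the two
    daughters' recorded segment order when a ``segment_start_um`` column is
    present, else the table's own ``new_pole_end`` labels are kept.  Roots
    are always ``unknown``.
    """
    if "segment_start_um" in cell_table.columns:
        starts = (cell_table.drop_duplicates("cell_id")
                  .set_index("cell_id")["segment_start_um"])
        for pid, (d1, d2) in tree.children.items():
            left, right = (d1, d2) if starts[d1] <= starts[d2] else (d2, d1)
            tree.cells[left].new_pole_end = "right"
            tree.cells[right].new_pole_end = "left"
    for rid in tree.roots:
        tree.cells[rid].new_pole_end = "unknown"
    return tree


def classify_minicell(length_um: float, threshold_um: float = MINICELL_MAX_UM) -> bool:
    """True iff the cell length is at or below the minicell threshold."""
    if length_um <= 0:
        raise ValueError("length must be positive")
    return bool(length_um <= threshold_um)


def cell_statistics(
    tree: LineageTree, minicell_threshold_um: float = MINICELL_MAX_UM
) -> pd.DataFrame:
    """Per-cell summary table.

    Columns: cell_id, parent_id, birth_length_um, division_length_um (NaN
    if the cell never divides), growth_rate, growth_rate_se,
    doubling_time_h, new_pole_end, is_minicell (at birth length).
    """
    rows = []
    for cid, hist in sorted(tree.cells.items()):
        rate, se = growth_rate(hist.times, hist.lengths)
        divides = cid in tree.children
        rows.append({
            "cell_id": cid,
            "parent_id": hist.parent_id,
            "birth_length_um": hist.birth_length,
            "division_length_um": hist.last_length if divides else math.nan,
            "growth_rate": rate,
            "growth_rate_se": se,
            "doubling_time_h": doubling_time(tree, cid),
            "new_pole_end": hist.new_pole_end,
            "is_minicell": classify_minicell(hist.birth_length, minicell_threshold_um),
        })
    return pd.DataFrame(rows)
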