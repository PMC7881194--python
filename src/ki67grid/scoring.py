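"""Whole-slide Ki67 scores over a grid table.

Three scores are computed per slide after QC filtering:

* ``average`` — pooled (cell-weighted) score: 100 * sum(positive) / sum(tumor)
  over all valid grids;
* ``hotspot`` — unweighted mean labeling index of the top-k grids (default 5);
* ``hottest_spot`` — the single maximum grid labeling index.

QC excludes grids with fewer than ``min_cells`` tumor cells (default 100;
strictly less-than, so a grid with exactly 100 cells is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import EmptySlideError, UndefinedStatisticError
from .grid_io import ExclusionReason, GridRecord, SlideGridTable

__all__ = [
    "SlideScores",
    "grid_li",
    "apply_qc",
    "average_score",
    "hottest_spot_score",
    "hotspot_score",
    "score_slide",
]


@dataclass(frozen=True)
class SlideScores:
    """The three whole-slide scores plus QC bookkeeping, percents in [0, 100]."""

    case_id: str
    grid_size_um: float
    n_grids_total: int
    n_grids_valid: int
    average: float
    hotspot: float
    hottest_spot: float
    k_used: int


def grid_li(grid: GridRecord) -> float:
    """Labeling index of one grid as a percent: 100 * positive / tumor."""
    if grid.tumor_cells == 0:
        raise UndefinedStatisticError(
            f"grid {grid.grid_id!r}: labeling index undefined with zero tumor cells"
        )
    return 100.0 * grid.positive_cells / grid.tumor_cells


def apply_qc(table: SlideGridTable, min_cells: int = 100) -> SlideGridTable:
    """Exclude grids with fewer than ``min_cells`` tumor cells.

    Manual exclusions already present are preserved.  Returns a new table;
    the input is never mutated.
    """
    out = []
    for g in table.grids:
        if not g.excluded and g.tumor_cells < min_cells:
            g = replace(g, excluded=True, exclusion_reason=ExclusionReason.TOO_FEW_CELLS)
        out.append(g)
    return table.with_grids(out)


def _require_valid(table: SlideGridTable) -> tuple[GridRecord, ...]:
    grids = table.valid_grids
    if not grids:
        raise EmptySlideError(f"slide {table.case_id!r}: no valid grids after QC")
    return grids


def average_score(table: SlideGridTable) -> float:
    """Pooled score: 100 * sum(positive) / sum(tumor) over valid grids."""
    grids = _require_valid(table)
    total = sum(g.tumor_cells for g in grids)
    if total == 0:
        raise UndefinedStatisticError(f"slide {table.case_id!r}: zero tumor cells in valid grids")
    return 100.0 * sum(g.positive_cells for g in grids) / total


def hottest_spot_score(table: SlideGridTable) -> float:
    """Maximum labeling index over valid grids."""
    return max(grid_li(g) for g in _require_valid(table))


def hotspot_score(table: SlideGridTable, k: int = 5, pooled: bool = False) -> tuple[float, int]:
    """Mean labeling index of the ``k`` highest-LI valid grids.

    With fewer than ``k`` valid grids, averages all of them; the second
    return value is the number of grids actually averaged.  Ties at the k-th
    labeling index are broken by larger tumor-cell count, then by grid id —
    this affects only which grids are selected, never the score when the
    tied indices are equal.  With ``pooled=True`` the top-k grids' counts
    are pooled instead of averaging their indices.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grids = _require_valid(table)
    ranked = sorted(grids, key=lambda g: (-grid_li(g), -g.tumor_cells, g.grid_id))
    top = ranked[: min(k, len(ranked))]
    if pooled:
        score = 100.0 * sum(g.positive_cells for g in top) / sum(g.tumor_cells for g in top)
    else:
        score = sum(grid_li(g) for g in top) / len(top)
    return score, len(top)


def score_slide(table: SlideGridTable, min_cells: int = 100, k: int = 5) -> SlideScores:
    """Apply QC, then compute all three scores with bookkeeping."""
    filtered = apply_qc(table, min_cells=min_cells)
    hotspot, k_used = hotspot_score(filtered, k=k)
    return SlideScores(
        case_id=table.case_id,
        grid_size_um=table.grid_size_um,
        n_grids_total=len(filtered.grids),
        n_grids_valid=len(filtered.valid_grids),
        average=average_score(filtered),
        hotspot=hotspot,
        hottest_spot=hottest_spot_score(filtered),
        k_used=k_used,
    )
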