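"""Monte-Carlo simulation of the IKWG manual scoring protocol.

The protocol partitions a slide's grids into four staining levels (zero,
low, medium, high) using case-specific cutoffs at thirds of the observed
labeling-index range, samples a small number of fields (default 4) across
the non-empty levels, and reports two manual-style scores per draw:

* ``global_average`` — pooled positive/tumor ratio over the selected grids;
* ``weighted_average`` — per-level mean index weighted by each level's
  share of all valid grids.

Repeating the draw (default 1000 replicates) yields per-slide medians and
percentile confidence intervals for both scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptySlideError, ValidationError
from .grid_io import GridRecord, SlideGridTable
from .scoring import grid_li

__all__ = [
    "Level",
    "LevelPartition",
    "IKWGReplicate",
    "IKWGSummary",
    "partition_levels",
    "select_fields",
    "global_average",
    "weighted_average",
    "run_ikwg_simulation",
]


class Level(str, enum.Enum):
    ZERO = "zero"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


#: Fixed iteration order used for deterministic tie-breaking and rng draws.
LEVEL_ORDER: tuple[Level, ...] = (Level.ZERO, Level.LOW, Level.MEDIUM, Level.HIGH)


@dataclass(frozen=True)
class LevelPartition:
    """Assignment of every valid grid to one of four staining levels."""

    li_min: float
    li_max: float
    range_r: float
    cutoff_c1: float
    cutoff_c2: float
    assignment: Mapping[str, Level]
    proportions: Mapping[Level, float]
    grids_by_level: Mapping[Level, tuple[GridRecord, ...]]


@dataclass(frozen=True)
class IKWGReplicate:
    selected_grid_ids: tuple[str, ...]
    global_average: float
    weighted_average: float


@dataclass(frozen=True)
class IKWGSummary:
    n_replicates: int
    seed: int | None
    medians: Mapping[str, float]
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]
    replicates: tuple[IKWGReplicate, ...] = field(default=())


def partition_levels(table: SlideGridTable, include_zero_in_range: bool = True) -> LevelPartition:
    """Assign valid grids to the four staining levels.

    The zero level holds grids with labeling index exactly 0.  The remaining
    grids are split at thirds of the observed index range with
    upper-inclusive intervals: low if 0 < LI <= c1, medium if c1 < LI <= c2,
    high if LI > c2.  A degenerate range (all non-zero indices equal) puts
    all non-zero grids into a single level, labelled high.

    ``include_zero_in_range=False`` computes the range over non-zero grids
    only (alternative convention; default includes every valid grid).
    """
    grids = table.valid_grids
    if not grids:
        raise EmptySlideError(f"slide {table.case_id!r}: no valid grids to partition")
    lis = {g.grid_id: grid_li(g) for g in grids}

    range_pool = [v for v in lis.values() if v > 0.0] if not include_zero_in_range else list(lis.values())
    if not range_pool:
        range_pool = [0.0]
    li_min, li_max = min(range_pool), max(range_pool)
    range_r = li_max - li_min
    c1 = li_min + range_r / 3.0
    c2 = li_min + 2.0 * range_r / 3.0

    assignment: dict[str, Level] = {}
    for g in grids:
        v = lis[g.grid_id]
        if v == 0.0:
            assignment[g.grid_id] = Level.ZERO
        elif range_r == 0.0:
            assignment[g.grid_id] = Level.HIGH
        elif v <= c1:
            assignment[g.grid_id] = Level.LOW
        elif v <= c2:
            assignment[g.grid_id] = Level.MEDIUM
        else:
            assignment[g.grid_id] = Level.HIGH

    by_level = {
        lvl: tuple(g for g in grids if assignment[g.grid_id] is lvl) for lvl in LEVEL_ORDER
    }
    n = len(grids)
    proportions = {lvl: len(by_level[lvl]) / n for lvl in LEVEL_ORDER}
    return LevelPartition(
        li_min=li_min,
        li_max=li_max,
        range_r=range_r,
        cutoff_c1=c1,
        cutoff_c2=c2,
        assignment=assignment,
        proportions=proportions,
        grids_by_level=by_level,
    )


def allocate_fields(partition: LevelPartition, n_fields: int = 4) -> dict[Level, int]:
    """Largest-remainder apportionment of ``n_fields`` picks across levels.

    Quotas are n_fields * proportion per level; floors are assigned first,
    then remaining picks go to the largest fractional remainders (ties broken
    by level order).  No level is allocated more picks than it has grids;
    picks that cannot be placed move to the largest levels with spare
    capacity.  Deterministic: depends only on the partition.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    sizes = {lvl: len(partition.grids_by_level[lvl]) for lvl in LEVEL_ORDER}
    quotas = {lvl: n_fields * partition.proportions[lvl] for lvl in LEVEL_ORDER}
    alloc = {lvl: min(int(quotas[lvl]), sizes[lvl]) for lvl in LEVEL_ORDER}
    remaining = n_fields - sum(alloc.values())
    # remainder pass: largest fractional part first, level order breaks ties
    order = sorted(
        LEVEL_ORDER,
        key=lambda l: (-(quotas[l] - int(quotas[l])), LEVEL_ORDER.index(l)),
    )
    for lvl in order:
        if remaining == 0:
            break
        if alloc[lvl] < sizes[lvl]:
            alloc[lvl] += 1
            remaining -= 1
    # overflow (some level hit capacity): push leftovers into the levels with
    # the most spare room; stop if the slide has fewer grids than fields
    while remaining > 0:
        candidates = [l for l in LEVEL_ORDER if alloc[l] < sizes[l]]
        if not candidates:
            break
        lvl = max(candidates, key=lambda l: (sizes[l] - alloc[l], -LEVEL_ORDER.index(l)))
        alloc[lvl] += 1
        remaining -= 1
    return alloc


def select_fields(
    partition: LevelPartition,
    rng: np.random.Generator,
    n_fields: int = 4,
    strategy: str = "proportional",
) -> tuple[str, ...]:
    """Randomly select grids to score across staining levels.

    ``strategy='proportional'`` apportions the picks by level proportion
    (largest remainder); ``'one_per_level'`` takes one grid from each
    non-empty level.  Sampling within a level is without replacement.
    """
    if strategy == "proportional":
        alloc = allocate_fields(partition, n_fields)
    elif strategy == "one_per_level":
        alloc = {lvl: (1 if partition.grids_by_level[lvl] else 0) for lvl in LEVEL_ORDER}
    else:
        raise ValidationError(f"unknown selection strategy {strategy!r}")
    if sum(alloc.values()) == 0:
        raise EmptySlideError("no grids available for field selection")
    selected: list[str] = []
    for lvl in LEVEL_ORDER:
        k = alloc[lvl]
        if k == 0:
            continue
        ids = [g.grid_id for g in partition.grids_by_level[lvl]]
        picks = rng.choice(len(ids), size=k, replace=False)
        selected.extend(ids[i] for i in sorted(picks))
    return tuple(selected)


def global_average(selected: Sequence[GridRecord]) -> float:
    """Pooled score over the selected grids: 100 * sum(positive)/sum(tumor)."""
    if not selected:
        raise ValidationError("empty field selection")
    return 100.0 * sum(g.positive_cells for g in selected) / sum(g.tumor_cells for g in selected)


def weighted_average(selected: Sequence[GridRecord], partition: LevelPartition) -> float:
    """Level-proportion-weighted mean of per-level sampled scores.

    Each sampled level contributes its selected grids' mean labeling index
    times the level's proportion of all valid grids.  An unsampled zero
    level still contributes proportion x 0; unsampled non-zero levels have
    their mass redistributed by renormalizing over the contributing levels.
    """
    if not selected:
        raise ValidationError("empty field selection")
    level_lis: dict[Level, list[float]] = {}
    for g in selected:
        lvl = partition.assignment[g.grid_id]
        level_lis.setdefault(lvl, []).append(grid_li(g))
    mass = sum(partition.proportions[lvl] for lvl in level_lis)
    if Level.ZERO not in level_lis:
        mass += partition.proportions[Level.ZERO]  # zero level contributes 0 regardless
    total = sum(
        partition.proportions[lvl] * (sum(v) / len(v)) for lvl, v in level_lis.items()
    )
    return total / mass


def run_ikwg_simulation(
    table: SlideGridTable,
    n_replicates: int = 1000,
    seed: int | None = None,
    n_fields: int = 4,
    strategy: str = "proportional",
    keep_replicates: bool = False,
    rng: np.random.Generator | None = None,
) -> IKWGSummary:
    """Simulate the field-sampling protocol ``n_replicates`` times.

    One seeded generator drives the whole simulation; replicates consume the
    stream sequentially, so output is bit-identical for identical seeds.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    partition = partition_levels(table)
    by_id = {g.grid_id: g for g in table.valid_grids}

    globals_: list[float] = []
    weighteds: list[float] = []
    reps: list[IKWGReplicate] = []
    for _ in range(n_replicates):
        ids = select_fields(partition, rng, n_fields=n_fields, strategy=strategy)
        grids = [by_id[i] for i in ids]
        g = global_average(grids)
        w = weighted_average(grids, partition)
        globals_.append(g)
        weighteds.append(w)
        if keep_replicates:
            reps.append(IKWGReplicate(ids, g, w))

    ga = np.asarray(globals_)
    wa = np.asarray(weighteds)
    q = [2.5, 50.0, 97.5]
    g_lo, g_med, g_hi = np.percentile(ga, q)
    w_lo, w_med, w_hi = np.percentile(wa, q)
    return IKWGSummary(
        n_replicates=n_replicates,
        seed=seed,
        medians={"global_average": float(g_med), "weighted_average": float(w_med)},
        ci_low={"global_average": float(g_lo), "weighted_average": float(w_lo)},
        ci_high={"global_average": float(g_hi), "weighted_average": float(w_hi)},
        replicates=tuple(reps),
    )
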