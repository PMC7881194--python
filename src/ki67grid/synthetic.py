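"""Synthetic slide and cohort generation.

Slides are lattices of square grids.  Per-grid tumor-cell counts follow a
gamma-Poisson (negative binomial) law around a configurable mean; the
Ki67-positive fraction is a baseline plus Gaussian bumps ("hotspots")
placed uniformly at random, and positive counts are binomial draws.  The
construction gives a right-skewed per-grid labeling-index field whose
top-grid scores exceed the pooled average, which is the spatial structure
the scoring pipeline is designed to summarize.

Cohorts draw a per-case baseline from a lognormal so that case-level
average scores are right skewed, and link a 0-100 recurrence score to the
average score through a saturating square-root transform plus grade effect
and Gaussian noise — producing the modest, non-linear score/RS correlation
the concordance analysis expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CaseRecord
from .errors import ValidationError
from .grid_io import CaseMetadata, ExclusionReason, GridRecord, SlideGridTable
from .scoring import score_slide

__all__ = [
    "SlideSimParams",
    "CohortSimParams",
    "simulate_slide",
    "simulate_cohort",
    "regrid",
]


@dataclass(frozen=True)
class SlideSimParams:
    """Parameters for one synthetic slide."""

    n_rows: int = 20
    n_cols: int = 20
    grid_size_um: float = 300.0
    cells_mean: float = 268.4
    cells_dispersion: float = 0.3  # var = mean + dispersion * mean^2
    baseline_li: float = 0.06
    n_hotspots: int = 2
    hotspot_amplitude: float = 0.35
    hotspot_sigma_grids: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("lattice dimensions must be positive")
        if self.cells_mean <= 0 or self.cells_dispersion < 0:
            raise ValidationError("cells_mean must be positive, cells_dispersion non-negative")
        if not 0.0 <= self.baseline_li <= 1.0:
            raise ValidationError("baseline_li must be a fraction in [0, 1]")
        if self.n_hotspots < 0 or self.hotspot_amplitude < 0 or self.hotspot_sigma_grids <= 0:
            raise ValidationError("invalid hotspot parameters")


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters for a synthetic case cohort with one slide per case."""

    n_cases: int = 100
    prob_age_lt50: float = 0.64
    age_range_lt50: tuple[float, float] = (35.0, 49.0)
    age_range_ge50: tuple[float, float] = (50.0, 75.0)
    grade_probs: tuple[float, float, float] = (0.2125, 0.6458, 0.1417)
    # per-case baseline labeling fraction: lognormal(median, log-sd), clipped
    li_median: float = 0.09
    li_log_sd: float = 0.6
    li_clip: tuple[float, float] = (0.005, 0.55)
    # hotspot amplitude scales with the case baseline so hotspot ~ 2x average
    amplitude_scale: float = 1.5
    slide: SlideSimParams = field(default_factory=lambda: SlideSimParams(n_rows=16, n_cols=16))
    # RS = round(clip(beta0 + beta1*sqrt(avg) + beta2*(grade-2) + N(0, sigma)))
    rs_beta0: float = -9.0
    rs_beta1: float = 7.0
    rs_beta2: float = 5.0
    rs_sigma: float = 11.0
    min_cells: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValidationError("n_cases must be non-negative")
        if not 0.0 <= self.prob_age_lt50 <= 1.0:
            raise ValidationError("prob_age_lt50 must be in [0, 1]")
        if abs(sum(self.grade_probs) - 1.0) > 1e-6 or any(p < 0 for p in self.grade_probs):
            raise ValidationError("grade_probs must be non-negative and sum to 1")
        if self.rs_sigma < 0:
            raise ValidationError("rs_sigma must be non-negative")
        if not 0 < self.li_median < 1 or self.li_log_sd < 0:
            raise ValidationError("invalid baseline labeling-index distribution")


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean / shape, size=size))


def simulate_slide(
    params: SlideSimParams,
    rng: np.random.Generator | None = None,
    case_id: str = "synthetic",
) -> SlideGridTable:
    """Draw one slide: counts, hotspot field, and binomial positives."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    nr, nc = params.n_rows, params.n_cols
    n_grids = nr * nc

    centers = rng.uniform(low=(0.0, 0.0), high=(nr, nc), size=(params.n_hotspots, 2))
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    p = np.full((nr, nc), params.baseline_li)
    sig2 = 2.0 * params.hotspot_sigma_grids**2
    for cr, cc in centers:
        d2 = (rows + 0.5 - cr) ** 2 + (cols + 0.5 - cc) ** 2
        p = p + params.hotspot_amplitude * np.exp(-d2 / sig2)
    p = np.clip(p, 0.0, 1.0)

    tumor = _draw_counts(rng, params.cells_mean, params.cells_dispersion, n_grids).reshape(nr, nc)
    positive = rng.binomial(tumor, p)

    grids = tuple(
        GridRecord(
            grid_id=f"r{i}c{j}",
            row_index=i,
            col_index=j,
            tumor_cells=int(tumor[i, j]),
            positive_cells=int(positive[i, j]),
        )
        for i in range(nr)
        for j in range(nc)
    )
    return SlideGridTable(case_id=case_id, grid_size_um=params.grid_size_um, grids=grids)


def simulate_cohort(
    params: CohortSimParams,
    rng: np.random.Generator | None = None,
) -> list[tuple[CaseMetadata, SlideGridTable]]:
    """Draw a cohort of cases, each with clinical metadata and one slide."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out: list[tuple[CaseMetadata, SlideGridTable]] = []
    for i in range(params.n_cases):
        case_id = f"case{i:04d}"
        if rng.random() < params.prob_age_lt50:
            age = float(rng.uniform(*params.age_range_lt50))
        else:
            age = float(rng.uniform(*params.age_range_ge50))
        grade = int(rng.choice((1, 2, 3), p=params.grade_probs))

        p0 = float(
            np.clip(
                math.exp(rng.normal(math.log(params.li_median), params.li_log_sd)),
                *params.li_clip,
            )
        )
        amplitude = min(params.amplitude_scale * p0, 0.95 - p0)
        slide_params = replace(params.slide, baseline_li=p0, hotspot_amplitude=amplitude)
        table = simulate_slide(slide_params, rng=rng, case_id=case_id)

        avg = score_slide(table, min_cells=params.min_cells).average
        rs_raw = (
            params.rs_beta0
            + params.rs_beta1 * math.sqrt(avg)
            + params.rs_beta2 * (grade - 2)
            + rng.normal(0.0, params.rs_sigma)
        )
        rs = int(round(float(np.clip(rs_raw, 0.0, 100.0))))
        out.append((CaseMetadata(case_id=case_id, age_years=age, grade=grade, rs=rs), table))
    return out


def regrid(table: SlideGridTable, factor: int) -> SlideGridTable:
    """Merge factor x factor blocks by summing counts; partial edge blocks kept.

    Exclusion flags are reset — QC is meant to be re-applied at the new grid
    size.  With factor 1 the table is returned with flags cleared but counts
    untouched; pooled sums (hence the pooled average score) are conserved for
    any factor.
    """
    if factor < 1:
        raise ValidationError("regrid factor must be >= 1")
    blocks: dict[tuple[int, int], list[GridRecord]] = {}
    for g in table.grids:
        blocks.setdefault((g.row_index // factor, g.col_index // factor), []).append(g)
    grids = tuple(
        GridRecord(
            grid_id=f"r{bi}c{bj}",
            row_index=bi,
            col_index=bj,
            tumor_cells=sum(g.tumor_cells for g in members),
            positive_cells=sum(g.positive_cells for g in members),
            excluded=False,
            exclusion_reason=ExclusionReason.NONE,
        )
        for (bi, bj), members in sorted(blocks.items())
    )
    return SlideGridTable(
        case_id=table.case_id,
        grid_size_um=table.grid_size_um * factor,
        grids=grids,
    )


def cohort_case_records(
    cohort: list[tuple[CaseMetadata, SlideGridTable]],
    min_cells: int = 100,
    k: int = 5,
) -> list[CaseRecord]:
    """Score every slide and join with its metadata."""
    return [
        CaseRecord.from_parts(meta, score_slide(table, min_cells=min_cells, k=k))
        for meta, table in cohort
    ]
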