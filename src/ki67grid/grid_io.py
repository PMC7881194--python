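"""Reading, validation, and writing of per-grid measurement tables.

The on-disk unit is a delimited text export with one row per square grid
(tile) of an annotated tumor region: a tumor-cell count and a count of
Ki67-positive tumor cells per grid.  Column names vary between image-analysis
exports, so every reader takes an overridable ``column_map``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ExclusionReason",
    "GridRecord",
    "SlideGridTable",
    "CaseMetadata",
    "DEFAULT_COLUMN_MAP",
    "read_grid_table",
    "read_case_metadata",
    "write_score_table",
]


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    TOO_FEW_CELLS = "too_few_cells"
    MANUAL = "manual"


@dataclass(frozen=True)
class GridRecord:
    """One grid's counts plus its lattice position and QC status."""

    grid_id: str
    row_index: int
    col_index: int
    tumor_cells: int
    positive_cells: int
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if self.tumor_cells < 0 or self.positive_cells < 0:
            raise ValidationError(
                f"grid {self.grid_id!r}: counts must be non-negative "
                f"(tumor_cells={self.tumor_cells}, positive_cells={self.positive_cells})"
            )
        if self.positive_cells > self.tumor_cells:
            raise ValidationError(
                f"grid {self.grid_id!r}: positive_cells ({self.positive_cells}) "
                f"exceeds tumor_cells ({self.tumor_cells})"
            )
        if self.row_index < 0 or self.col_index < 0:
            raise ValidationError(f"grid {self.grid_id!r}: negative lattice index")
        if self.excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValidationError(
                f"grid {self.grid_id!r}: excluded flag inconsistent with reason "
                f"{self.exclusion_reason.value!r}"
            )


@dataclass(frozen=True)
class SlideGridTable:
    """All grids of one slide at one grid size; the unit of scoring."""

    case_id: str
    grid_size_um: float
    grids: tuple[GridRecord, ...]

    def __post_init__(self) -> None:
        if self.grid_size_um <= 0:
            raise ValidationError(f"slide {self.case_id!r}: grid_size_um must be positive")
        if not self.grids:
            raise ValidationError(f"slide {self.case_id!r}: no grids")
        positions = [(g.row_index, g.col_index) for g in self.grids]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"slide {self.case_id!r}: duplicate lattice positions")

    @property
    def valid_grids(self) -> tuple[GridRecord, ...]:
        return tuple(g for g in self.grids if not g.excluded)

    def with_grids(self, grids: Iterable[GridRecord]) -> "SlideGridTable":
        return replace(self, grids=tuple(grids))


@dataclass(frozen=True)
class CaseMetadata:
    """Clinical annotations attached to one case."""

    case_id: str
    age_years: float
    grade: int
    rs: int

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValidationError(f"case {self.case_id!r}: age_years must be positive")
        if self.grade not in (1, 2, 3):
            raise ValidationError(f"case {self.case_id!r}: grade {self.grade} not in {{1,2,3}}")
        if not 0 <= self.rs <= 100:
            raise ValidationError(f"case {self.case_id!r}: rs {self.rs} outside [0, 100]")


#: Conventional column names for tile-annotation exports; always overridable.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "tumor_cells": "Num Tumor",
    "positive_cells": "Num Tumor Positive",
}

_OPTIONAL_FIELDS = ("grid_id", "row_index", "col_index", "excluded")
_REQUIRED_FIELDS = ("tumor_cells", "positive_cells")


def _sniff_delimiter(path: Path) -> str:
    """Choose tab vs comma by inspecting the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    return ","


def _as_count(value, column: str, row_label: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"{row_label}: missing value in column {column!r}")
    f = float(value)
    if not f.is_integer():
        raise ValidationError(f"{row_label}: non-integer count {value!r} in column {column!r}")
    n = int(f)
    if n < 0:
        raise ValidationError(f"{row_label}: negative count {n} in column {column!r}")
    return n


def read_grid_table(
    path: str | Path,
    case_id: str | None = None,
    grid_size_um: float = 300.0,
    column_map: Mapping[str, str] | None = None,
) -> SlideGridTable:
    """Parse one slide's grid export into a validated :class:`SlideGridTable`.

    Parameters
    ----------
    path
        Delimited text file (tab or comma; auto-detected from the header).
    case_id
        Identifier for the slide; defaults to the file stem.
    grid_size_um
        Edge length of the square grids in this export.
    column_map
        Maps internal field names (``tumor_cells``, ``positive_cells``, and
        optionally ``grid_id``, ``row_index``, ``col_index``, ``excluded``) to
        file column names.  Unmapped optional fields are synthesized: grid ids
        from the row number, lattice indices sequentially.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    for fld in _REQUIRED_FIELDS:
        col = cmap.get(fld)
        if col is None:
            raise ConfigurationError(f"column_map is missing required field {fld!r}")
        if col not in frame.columns:
            raise ConfigurationError(
                f"{path.name}: mapped column {col!r} (for {fld!r}) not found; "
                f"available: {list(frame.columns)}"
            )
    for fld in _OPTIONAL_FIELDS:
        col = cmap.get(fld)
        if col is not None and col not in frame.columns and fld in (column_map or {}):
            raise ConfigurationError(f"{path.name}: mapped column {col!r} (for {fld!r}) not found")

    if len(frame) == 0:
        raise ValidationError(f"{path.name}: no grids")

    have = {fld: cmap.get(fld) in frame.columns for fld in _OPTIONAL_FIELDS}
    grids = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rec = dict(zip(frame.columns, row))
        gid = str(rec[cmap["grid_id"]]) if have["grid_id"] else f"g{i}"
        label = f"{path.name} grid {gid!r}"
        if have["row_index"] and have["col_index"]:
            ri = _as_count(rec[cmap["row_index"]], cmap["row_index"], label)
            ci = _as_count(rec[cmap["col_index"]], cmap["col_index"], label)
        else:
            ri, ci = 0, i
        excluded = bool(rec[cmap["excluded"]]) if have["excluded"] else False
        grids.append(
            GridRecord(
                grid_id=gid,
                row_index=ri,
                col_index=ci,
                tumor_cells=_as_count(rec[cmap["tumor_cells"]], cmap["tumor_cells"], label),
                positive_cells=_as_count(rec[cmap["positive_cells"]], cmap["positive_cells"], label),
                excluded=excluded,
                exclusion_reason=ExclusionReason.MANUAL if excluded else ExclusionReason.NONE,
            )
        )
    return SlideGridTable(
        case_id=case_id if case_id is not None else path.stem,
        grid_size_um=grid_size_um,
        grids=tuple(grids),
    )


def read_case_metadata(path: str | Path) -> dict[str, CaseMetadata]:
    """Read case-level annotations (case_id, age_years, grade, rs)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = ("case_id", "age_years", "grade", "rs")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: missing metadata columns {missing}")
    out: dict[str, CaseMetadata] = {}
    for row in frame.itertuples(index=False):
        rec = dict(zip(frame.columns, row))
        cid = str(rec["case_id"])
        if cid in out:
            raise ValidationError(f"{path.name}: duplicate case_id {cid!r}")
        out[cid] = CaseMetadata(
            case_id=cid,
            age_years=float(rec["age_years"]),
            grade=_as_count(rec["grade"], "grade", f"case {cid!r}"),
            rs=_as_count(rec["rs"], "rs", f"case {cid!r}"),
        )
    return out


def write_score_table(
    scores: Sequence,
    path: str | Path,
    metadata: Mapping[str, CaseMetadata] | None = None,
    decimals: int = 2,
) -> None:
    """Write per-case slide scores (and metadata when available) as TSV.

    ``scores`` is any sequence of objects with the :class:`~ki67grid.scoring.SlideScores`
    fields.  Cases without metadata get ``NA`` in the metadata columns.
    """
    metadata = metadata or {}
    rows = []
    for s in scores:
        meta = metadata.get(s.case_id)
        rows.append(
            {
                "case_id": s.case_id,
                "grid_size_um": s.grid_size_um,
                "n_grids_total": s.n_grids_total,
                "n_grids_valid": s.n_grids_valid,
                "average": f"{s.average:.{decimals}f}",
                "hotspot": f"{s.hotspot:.{decimals}f}",
                "hottest_spot": f"{s.hottest_spot:.{decimals}f}",
                "k_used": s.k_used,
                "age_years": meta.age_years if meta else "NA",
                "grade": meta.grade if meta else "NA",
                "rs": meta.rs if meta else "NA",
            }
        )
    columns = [
        "case_id", "grid_size_um", "n_grids_total", "n_grids_valid",
        "average", "hotspot", "hottest_spot", "k_used",
        "age_years", "grade", "rs",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
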