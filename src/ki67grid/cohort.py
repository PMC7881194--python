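"""Categorical risk bookkeeping: RS categories, Ki67 decade bins, the
grade+hotspot combined risk rule, chemotherapy decision rules, contingency
tables, and misclassification accounting.

A bundled reference tabulation (published cross-tabulated counts of Ki67
score bins, grade, and combined risk against RS category for a 240-case
cohort, split at age 50) lets the classifiers be exercised without any
external data: each counted cell is expanded into per-case records carrying
representative within-bin values, and re-tabulation must return the
original counts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .grid_io import CaseMetadata
from .scoring import SlideScores

__all__ = [
    "RS_CATEGORIES",
    "KI67_BINS",
    "CaseRecord",
    "RiskCall",
    "rs_category",
    "ki67_bin",
    "combined_risk",
    "chemo_by_rs",
    "classify",
    "misclassification_summary",
    "build_contingency",
    "load_reference_tabulations",
    "expand_tabulation",
]

RS_CATEGORIES = ("0-15", "16-19", "20-25", ">25")
KI67_BINS = ("<10", "<20", "<30", "<40", ">=40")

#: Representative within-bin values used when expanding counted cells into
#: per-case records; chosen so the classifiers (not table bookkeeping)
#: reproduce the counts.
_RS_REPRESENTATIVE = {"0-15": 8, "16-19": 17, "20-25": 22, ">25": 30}
_BIN_REPRESENTATIVE = {"<10": 5.0, "<20": 15.0, "<30": 25.0, "<40": 35.0, ">=40": 70.0}
_AGE_REPRESENTATIVE = {"age_lt50": 45.0, "age_ge50": 60.0}


@dataclass(frozen=True)
class CaseRecord:
    """One case's clinical annotations plus its three slide scores."""

    case_id: str
    age_years: float
    grade: int
    rs: int
    average: float | None = None
    hotspot: float | None = None
    hottest_spot: float | None = None

    @classmethod
    def from_parts(cls, meta: CaseMetadata, scores: SlideScores) -> "CaseRecord":
        if meta.case_id != scores.case_id:
            raise ValidationError(
                f"metadata case {meta.case_id!r} does not match scores case {scores.case_id!r}"
            )
        return cls(
            case_id=meta.case_id,
            age_years=meta.age_years,
            grade=meta.grade,
            rs=meta.rs,
            average=scores.average,
            hotspot=scores.hotspot,
            hottest_spot=scores.hottest_spot,
        )

    def score(self, which: str) -> float:
        value = getattr(self, which, None)
        if value is None:
            raise ValidationError(f"case {self.case_id!r}: score {which!r} not available")
        return value


@dataclass(frozen=True)
class RiskCall:
    rs_category: str
    ki67_bin: str
    combined_risk: str
    chemo_by_rs: bool
    low_by_ki67_rule: bool


def rs_category(rs: int) -> str:
    """Map an RS value onto the four TAILORx-derived categories."""
    if not 0 <= rs <= 100:
        raise ValidationError(f"rs {rs} outside [0, 100]")
    if rs <= 15:
        return "0-15"
    if rs <= 19:
        return "16-19"
    if rs <= 25:
        return "20-25"
    return ">25"


def ki67_bin(score: float) -> str:
    """Decade bins [0,10), [10,20), [20,30), [30,40), [40,100]."""
    if not 0 <= score <= 100:
        raise ValidationError(f"score {score} outside [0, 100]")
    for upper, label in ((10, "<10"), (20, "<20"), (30, "<30"), (40, "<40")):
        if score < upper:
            return label
    return ">=40"


def combined_risk(grade: int, hotspot: float) -> str:
    """Low risk iff grade 1 OR hotspot score strictly below 20."""
    if grade not in (1, 2, 3):
        raise ValidationError(f"grade {grade} not in {{1,2,3}}")
    return "low" if (grade == 1 or hotspot < 20.0) else "high"


def chemo_by_rs(age_years: float, rs: int) -> bool:
    """Chemotherapy indicated by RS alone: rs > 20 under age 50, rs > 25 at 50+."""
    if age_years < 50:
        return rs > 20
    return rs > 25


def classify(case: CaseRecord, score: str = "hotspot") -> RiskCall:
    """Run every categorical rule on one case; ``score`` picks the Ki67 score binned."""
    value = case.score(score)
    return RiskCall(
        rs_category=rs_category(case.rs),
        ki67_bin=ki67_bin(value),
        combined_risk=combined_risk(case.grade, case.score("hotspot")),
        chemo_by_rs=chemo_by_rs(case.age_years, case.rs),
        low_by_ki67_rule=case.score("hotspot") < 20.0,
    )


def _rule_counts(cases: Sequence[CaseRecord], low: Callable[[CaseRecord], bool]) -> dict:
    selected = [c for c in cases if low(c)]
    cats = [rs_category(c.rs) for c in selected]
    return {
        "n_low": len(selected),
        "n_chemo_by_rs": sum(chemo_by_rs(c.age_years, c.rs) for c in selected),
        "n_rs_above_20": sum(cat in ("20-25", ">25") for cat in cats),
        "n_rs_above_25": sum(cat == ">25" for cat in cats),
    }


def misclassification_summary(cases: Sequence[CaseRecord]) -> dict:
    """Count low-risk calls and their disagreements with RS, overall and by age.

    For both the combined rule (grade 1 OR hotspot < 20) and the pure
    hotspot < 20 rule, reports: cases called low risk; among them, cases
    where RS alone would indicate chemotherapy; cases in an RS category
    above 20; and cases in the category above 25.
    """
    strata = {
        "overall": list(cases),
        "age_lt50": [c for c in cases if c.age_years < 50],
        "age_ge50": [c for c in cases if c.age_years >= 50],
    }
    out: dict = {}
    for name, group in strata.items():
        out[name] = {
            "n_cases": len(group),
            "combined_rule": _rule_counts(
                group, lambda c: combined_risk(c.grade, c.score("hotspot")) == "low"
            ),
            "hotspot_rule": _rule_counts(group, lambda c: c.score("hotspot") < 20.0),
        }
    return out


_ROW_FACTORS: dict[str, tuple[Callable[[CaseRecord], str], tuple[str, ...]]] = {
    "hotspot": (lambda c: ki67_bin(c.score("hotspot")), KI67_BINS),
    "average": (lambda c: ki67_bin(c.score("average")), KI67_BINS),
    "hottest_spot": (lambda c: ki67_bin(c.score("hottest_spot")), KI67_BINS),
    "grade": (lambda c: str(c.grade), ("1", "2", "3")),
    "combined": (lambda c: combined_risk(c.grade, c.score("hotspot")), ("low", "high")),
}


def build_contingency(
    cases: Iterable[CaseRecord],
    row_factor: str = "hotspot",
    age_filter: str | None = None,
    drop_empty_rows: bool = True,
) -> pd.DataFrame:
    """Cross-tabulate a row factor against RS category, with marginals.

    ``row_factor`` is one of hotspot / average / hottest_spot (decade bins),
    grade, or combined (risk rule).  ``age_filter`` restricts to
    ``'age_lt50'`` or ``'age_ge50'``.  Rows with zero counts are dropped by
    default (a chi-square cannot use them); columns are always the four RS
    categories.  The returned frame carries a ``Total`` row and column.
    """
    if row_factor not in _ROW_FACTORS:
        raise ValidationError(f"unknown row factor {row_factor!r}")
    label_of, row_labels = _ROW_FACTORS[row_factor]
    cases = list(cases)
    if age_filter == "age_lt50":
        cases = [c for c in cases if c.age_years < 50]
    elif age_filter == "age_ge50":
        cases = [c for c in cases if c.age_years >= 50]
    elif age_filter is not None:
        raise ValidationError(f"unknown age filter {age_filter!r}")
    if not cases:
        raise ValidationError("no cases after filtering")

    table = pd.DataFrame(0, index=list(row_labels), columns=list(RS_CATEGORIES))
    for c in cases:
        table.loc[label_of(c), rs_category(c.rs)] += 1
    if drop_empty_rows:
        table = table.loc[table.sum(axis=1) > 0]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def load_reference_tabulations() -> pd.DataFrame:
    """Load the bundled reference cross-tabulation (counts per cell)."""
    ref = importlib.resources.files("ki67grid.data") / "reference_tabulations.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def expand_tabulation(
    tabulation: pd.DataFrame,
    variable: str,
    stratum: str | None = None,
) -> list[CaseRecord]:
    """Expand counted cells of one tabulated variable into per-case records.

    Each cell becomes that many :class:`CaseRecord` objects carrying
    representative values: Ki67 bins map to in-bin midpoints (70 for the
    open >=40 bin), RS categories to 8 / 17 / 22 / 30, age strata to 45 / 60.
    Auxiliary fields are filled so only the expanded variable drives the
    classifier of interest (e.g. grade 2 for score rows, hotspot 50 for
    grade rows).
    """
    rows = tabulation[tabulation["variable"] == variable]
    if stratum is not None:
        rows = rows[rows["stratum"] == stratum]
    if rows.empty:
        raise ValidationError(f"no tabulated rows for variable {variable!r}")
    records: list[CaseRecord] = []
    for _, row in rows.iterrows():
        age = _AGE_REPRESENTATIVE[row["stratum"]]
        level = str(row["level"])
        for cat in RS_CATEGORIES:
            col = {"0-15": "rs_0_15", "16-19": "rs_16_19", "20-25": "rs_20_25", ">25": "rs_gt25"}[cat]
            rs = _RS_REPRESENTATIVE[cat]
            for _ in range(int(row[col])):
                idx = len(records)
                if variable in ("hotspot", "average", "hottest_spot"):
                    value = _BIN_REPRESENTATIVE[level]
                    scores = {"average": 10.0, "hotspot": 50.0, "hottest_spot": 60.0}
                    scores[variable] = value
                    records.append(
                        CaseRecord(
                            case_id=f"{row['stratum']}-{variable}-{idx}",
                            age_years=age, grade=2, rs=rs, **scores,
                        )
                    )
                elif variable == "grade":
                    records.append(
                        CaseRecord(
                            case_id=f"{row['stratum']}-grade-{idx}",
                            age_years=age, grade=int(level), rs=rs,
                            average=10.0, hotspot=50.0, hottest_spot=60.0,
                        )
                    )
                elif variable == "combined":
                    grade = 1 if level == "low" else 2
                    records.append(
                        CaseRecord(
                            case_id=f"{row['stratum']}-combined-{idx}",
                            age_years=age, grade=grade, rs=rs,
                            average=10.0, hotspot=50.0, hottest_spot=60.0,
                        )
                    )
                else:
                    raise ValidationError(f"unknown tabulated variable {variable!r}")
    return records
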