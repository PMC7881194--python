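"""Statistical primitives: Pearson chi-square, Pearson correlation, quartiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = ["ContingencyResult", "pearson_chi2", "pearson_r", "quartile_summary"]


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def pearson_chi2(observed) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts are the usual outer product of margins over the grand
    total; the p-value is the upper tail of the chi-square distribution at
    (r-1)(c-1) degrees of freedom.  Rows or columns summing to zero are
    rejected — the caller must drop degenerate margins first.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValidationError("contingency table entries must be non-negative")
    if obs.sum() <= 0:
        raise ValidationError("contingency table grand total must be positive")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("degenerate margin: a row or column sums to zero")
    chi2, p, df, expected = scipy.stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        observed=obs.astype(int),
        expected=expected,
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r requires two equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a zero-variance vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def quartile_summary(values) -> dict[str, float]:
    """Median, first and third quartile via linear interpolation of order stats."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("quartile_summary requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}
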