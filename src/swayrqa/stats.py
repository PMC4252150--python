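"""Inferential layer: Pearson correlations and paired t-tests.

Correlations between sway features and vection outcomes are reported as raw
(unadjusted) two-sided p-values; the table writer records how many tests
were run so readers can apply their own multiplicity control. Missing values
are deleted pairwise, so each feature/outcome pair uses every subject with
both values present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateDataError, PairSpecError

__all__ = [
    "CorrelationResult",
    "PairedTestResult",
    "pearson",
    "paired_t",
    "correlation_table",
    "TABLE_RQA_PAIRS",
    "TABLE_LINEAR_PAIRS",
]


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    outcome: str
    r: float
    p: float
    n: int
    note: str | None = None


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    t: float
    df: int
    p: float


#: Feature/outcome pairs mirroring the recurrence-rate correlation table:
#: rr difference, eyes-open and eyes-closed rr against the four vection
#: outcomes (verbal and throttle max, expanding and contracting).
TABLE_RQA_PAIRS: list[tuple[str, str]] = [
    (feature, outcome)
    for outcome in (
        "verbal_expanding",
        "throttle_max_expanding",
        "verbal_contracting",
        "throttle_max_contracting",
    )
    for feature in ("rr_diff", "rr_eo", "rr_ec")
]

#: Linear-measure pairs: VEPRs and the log sway-area ratio against the same
#: outcomes plus latency.
TABLE_LINEAR_PAIRS: list[tuple[str, str]] = [
    (feature, outcome)
    for outcome in (
        "verbal_expanding",
        "throttle_max_expanding",
        "latency_expanding",
        "verbal_contracting",
        "throttle_max_contracting",
        "latency_contracting",
    )
    for feature in ("vepr_expanding", "vepr_contracting", "log_area_ratio", "romberg")
]


def _pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y, feature: str = "x", outcome: str = "y") -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df).

    Missing values are deleted pairwise; fewer than 3 complete pairs or zero
    variance in either argument is an error.
    """
    xv, yv = _pairwise(x, y)
    n = len(xv)
    if n < 3:
        raise DataError(f"pearson needs >= 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(
        feature=feature,
        outcome=outcome,
        r=float(res.statistic),
        p=float(res.pvalue),
        n=n,
    )


def paired_t(a, b) -> PairedTestResult:
    """Paired-samples t-test: t = mean(a-b) / (sd(a-b)/sqrt(n)), df = n-1."""
    av, bv = _pairwise(a, b)
    n = len(av)
    if n < 2:
        raise DataError(f"paired t needs >= 2 complete pairs, got {n}")
    d = av - bv
    if np.ptp(d) == 0:
        raise DegenerateDataError("paired t undefined: zero-variance differences")
    res = sps.ttest_rel(av, bv)
    return PairedTestResult(
        mean_diff=float(np.mean(d)),
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
    )


def correlation_table(
    features: pd.DataFrame,
    pairs: list[tuple[str, str]],
    magnitude: bool = False,
) -> list[CorrelationResult]:
    """One Pearson correlation per (feature, outcome) pair, in given order.

    Pairs whose correlation is undefined (zero variance, too few complete
    pairs) yield a NaN result flagged in ``note`` rather than aborting the
    table. ``magnitude=True`` correlates |feature| instead of the signed
    value — relevant for VEPRs whose expanding means sit near zero.
    No multiple-comparison adjustment is applied.
    """
    results: list[CorrelationResult] = []
    for feature, outcome in pairs:
        for col in (feature, outcome):
            if col not in features.columns:
                raise PairSpecError(f"unknown column {col!r} in pair spec")
        x = features[feature].to_numpy(dtype=float)
        if magnitude:
            x = np.abs(x)
        y = features[outcome].to_numpy(dtype=float)
        try:
            results.append(pearson(x, y, feature=feature, outcome=outcome))
        except (DataError, DegenerateDataError) as exc:
            xv, yv = _pairwise(x, y)
            results.append(
                CorrelationResult(
                    feature=feature,
                    outcome=outcome,
                    r=math.nan,
                    p=math.nan,
                    n=len(xv),
                    note=str(exc),
                )
            )
    return results
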