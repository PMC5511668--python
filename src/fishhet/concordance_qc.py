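"""Method-agreement statistics and segmentation/signal QC summaries.

Two comparisons drive the quality assessment of automated FISH counting:
automated data (AD) versus the observer-corrected reference (CD), and AD
versus the conventional manual procedure (MP). Agreement is quantified per
case-level variable (mean HER2, mean CEP17, ratio-of-sums) with a paired
t-test for bias and an ordinary least-squares regression of AD on the
reference. QC tallies of nucleus segmentation and per-channel signal
detection are converted to percentages: nucleus rows over the total nucleus
count, signal rows over the channel's detected total.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import PairingError, SingularFitError


@dataclass(frozen=True)
class QCCounts:
    """Raw QC tallies from review of automated segmentation and spot detection."""

    nuclei_total: int
    nuclei_correct: int
    nuclei_under_over: int
    nuclei_missed: int
    her2_detected: int
    her2_correct: int
    her2_false: int
    her2_undetected: int
    cep17_detected: int
    cep17_correct: int
    cep17_false: int
    cep17_undetected: int

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"QC count {f} must be non-negative, got {v}")
        if self.nuclei_correct + self.nuclei_under_over > self.nuclei_total:
            raise ValueError("nucleus QC counts exceed the total")


@dataclass(frozen=True)
class ConcordanceResult:
    variable: str  # mean_her2 | mean_cep17 | ratio
    mean_diff: float
    ci_low: float
    ci_high: float
    p_paired: float
    r2: float
    slope: float
    intercept: float
    slope_p: float
    intercept_p: float


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used for display percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def qc_percentages(c: QCCounts) -> dict[str, dict[str, float | None]]:
    """Exact and display (one-decimal, half-up) percentages for each QC row.

    Nucleus rows use ``nuclei_total`` as denominator; signal rows use the
    channel's detected total. A zero denominator yields None rather than an
    error.
    """

    def pct(num: int, den: int):
        if den == 0:
            return {"exact": None, "display": None}
        exact = 100.0 * num / den
        return {"exact": exact, "display": round_half_up(exact, 1)}

    return {
        "nuclei_correct": pct(c.nuclei_correct, c.nuclei_total),
        "nuclei_under_over": pct(c.nuclei_under_over, c.nuclei_total),
        "nuclei_missed": pct(c.nuclei_missed, c.nuclei_total),
        "her2_correct": pct(c.her2_correct, c.her2_detected),
        "her2_false": pct(c.her2_false, c.her2_detected),
        "her2_undetected": pct(c.her2_undetected, c.her2_detected),
        "cep17_correct": pct(c.cep17_correct, c.cep17_detected),
        "cep17_false": pct(c.cep17_false, c.cep17_detected),
        "cep17_undetected": pct(c.cep17_undetected, c.cep17_detected),
    }


def paired_bias(x, y, ids=None) -> tuple[float, tuple[float, float], float]:
    """Mean paired difference x − y with 95% t-interval and two-sided p.

    Positive mean_diff means x exceeds y. A zero-variance difference vector
    is handled exactly: CI collapses to the point, p is 1 for zero
    difference and 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise PairingError(
            f"paired comparison needs matched vectors, got {x.size} vs {y.size}"
        )
    if x.size < 3:
        raise PairingError("paired comparison needs at least 3 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return mean, (mean, mean), (1.0 if mean == 0.0 else 0.0)
    se = sd / np.sqrt(d.size)
    tcrit = stats.t.ppf(0.975, d.size - 1)
    res = stats.ttest_rel(x, y)
    return mean, (mean - tcrit * se, mean + tcrit * se), float(res.pvalue)


def match_by_case(a: dict[str, float], b: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Align two per-case value mappings on shared ids; error on mismatch."""
    unmatched = sorted(set(a) ^ set(b))
    if unmatched:
        raise PairingError(
            f"case sets do not match; unmatched ids: {unmatched}", unmatched
        )
    ids = sorted(a)
    return (
        np.array([a[i] for i in ids], dtype=float),
        np.array([b[i] for i in ids], dtype=float),
    )


def regression_agreement(dependent, explanatory, variable: str = "") -> ConcordanceResult:
    """OLS of the dependent method on the explanatory reference, with paired bias."""
    import statsmodels.api as sm

    y = np.asarray(dependent, dtype=float)
    x = np.asarray(explanatory, dtype=float)
    if y.size != x.size or y.size < 3:
        raise PairingError("regression needs matched vectors of length ≥ 3")
    if x.std() == 0.0:
        raise SingularFitError("explanatory variable has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    mean_diff, (lo, hi), p = paired_bias(y, x)
    return ConcordanceResult(
        variable=variable,
        mean_diff=mean_diff,
        ci_low=lo,
        ci_high=hi,
        p_paired=p,
        r2=float(fit.rsquared),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
    )


def concordance_to_frame(results, pair: str):
    import pandas as pd

    cols = ["variable", "r2", "intercept", "intercept_p", "slope", "slope_p"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])
    df.insert(0, "pair", pair)
    return df
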