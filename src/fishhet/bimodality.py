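"""Two-component Gaussian mixture fits and bimodality indicators.

Intratumor heterogeneity of HER2 copy number is quantified by fitting a
two-component univariate Gaussian mixture (unequal variances) to the
per-cell distributions of HER2, CEP17 and the HER2/CEP17 ratio, then
deriving two separation statistics:

* Ashman's D = √2 |μ1 − μ2| / √(σ1² + σ2²); D > 2 indicates a clearly
  bimodal population.
* Bimodality index BI = √(p(1−p)) · |μ1 − μ2| / σ_pooled with
  σ_pooled = √((σ1² + σ2²)/2), weighting the mode separation by the mixing
  proportion.

Both indicators are computed from a single unequal-variance EM fit.
Initialization is deterministic (component means at the 25th/75th sample
percentiles, equal weights, pooled standard deviation) so that case-level
results reproduce exactly; optional multi-start is available via
:class:`FitSettings`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core_io import CaseCellSet, require_filtered
from .errors import DegenerateSampleError, InsufficientDataError

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitSettings:
    """EM configuration. ``var_floor`` is the minimal component variance."""

    max_iter: int = 500
    tol: float = 1e-6
    var_floor: float = 1e-3
    n_starts: int = 1  # >1 adds seeded random restarts on top of quantile init
    restart_seed: int = 0
    degenerate_as_unimodal: bool = True  # profile-level handling only
    min_n: int = 10


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-Gaussian mixture with components ordered so mu1 ≤ mu2."""

    p: float  # mixing proportion of component 1
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    converged: bool
    n: int


@dataclass(frozen=True)
class VariableBimodality:
    ashman_d: float
    bindex: float
    bimodal: bool
    fit: MixtureFit | None = None


@dataclass(frozen=True)
class BimodalityResult:
    """Per-case indicators for HER2, CEP17 and the per-cell ratio."""

    case_id: str
    source: str
    her2: VariableBimodality
    cep17: VariableBimodality
    ratio: VariableBimodality

    def as_row(self) -> dict:
        row = {"case_id": self.case_id, "source": self.source}
        for stat in ("ashd", "bindex", "bim"):
            for name in ("her2", "cep17", "ratio"):
                v: VariableBimodality = getattr(self, name)
                value = {"ashd": v.ashman_d, "bindex": v.bindex, "bim": v.bimodal}[stat]
                row[f"{stat}_{name}"] = value
        return row


def _loglik(x: np.ndarray, p, mu1, mu2, v1, v2) -> tuple[float, np.ndarray]:
    # log f(x) via logsumexp over the two components; returns total and the
    # per-point log joint matrix for the E step.
    lj = np.empty((x.size, 2))
    lj[:, 0] = math.log(p) - 0.5 * (_LOG_2PI + math.log(v1) + (x - mu1) ** 2 / v1)
    lj[:, 1] = math.log1p(-p) - 0.5 * (_LOG_2PI + math.log(v2) + (x - mu2) ** 2 / v2)
    lmarg = logsumexp(lj, axis=1)
    return float(lmarg.sum()), lj - lmarg[:, None]


def _em(x: np.ndarray, p, mu1, mu2, v1, v2, cfg: FitSettings) -> MixtureFit:
    n = x.size
    prev = -np.inf
    converged = False
    ll = prev
    for _ in range(cfg.max_iter):
        ll, lresp = _loglik(x, p, mu1, mu2, v1, v2)
        r1 = np.exp(lresp[:, 0])
        w1 = r1.sum()
        w2 = n - w1
        # guard against a component losing all mass
        w1 = max(w1, 1e-10)
        w2 = max(w2, 1e-10)
        mu1 = float((r1 * x).sum() / w1)
        mu2 = float(((1.0 - r1) * x).sum() / w2)
        v1 = max(float((r1 * (x - mu1) ** 2).sum() / w1), cfg.var_floor)
        v2 = max(float(((1.0 - r1) * (x - mu2) ** 2).sum() / w2), cfg.var_floor)
        p = float(np.clip(w1 / n, 1e-9, 1.0 - 1e-9))
        if abs(ll - prev) < cfg.tol:
            converged = True
            break
        prev = ll
    ll, _ = _loglik(x, p, mu1, mu2, v1, v2)
    if mu1 > mu2:  # canonical ordering
        p, mu1, mu2, v1, v2 = 1.0 - p, mu2, mu1, v2, v1
    return MixtureFit(
        p=p,
        mu1=mu1,
        mu2=mu2,
        sigma1=math.sqrt(v1),
        sigma2=math.sqrt(v2),
        loglik=ll,
        converged=converged,
        n=n,
    )


def fit_two_component_mixture(
    values, cfg: FitSettings = FitSettings()
) -> MixtureFit:
    """EM maximum-likelihood fit of a two-Gaussian mixture (unequal variances).

    Deterministic quantile initialization; when the 25th and 75th percentiles
    coincide (common on integer counts) the 10th/90th percentiles are used,
    then mean ± sd/2 as a last resort. With ``cfg.n_starts > 1`` additional
    seeded random initializations are tried and the best log-likelihood kept.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < cfg.min_n:
        raise InsufficientDataError(
            f"mixture fit needs at least {cfg.min_n} values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("mixture fit requires finite values")
    sd = float(x.std())
    if sd == 0.0:
        raise DegenerateSampleError("zero-variance sample: mixture fit undefined")

    mu1, mu2 = np.percentile(x, [25.0, 75.0])
    if mu1 == mu2:
        mu1, mu2 = np.percentile(x, [10.0, 90.0])
    if mu1 == mu2:
        m = x.mean()
        mu1, mu2 = m - sd / 2.0, m + sd / 2.0
    v0 = max(sd * sd, cfg.var_floor)

    best = _em(x, 0.5, float(mu1), float(mu2), v0, v0, cfg)
    if cfg.n_starts > 1:
        rng = np.random.default_rng(cfg.restart_seed)
        lo, hi = x.min(), x.max()
        for _ in range(cfg.n_starts - 1):
            a, b = np.sort(rng.uniform(lo, hi, size=2))
            cand = _em(x, rng.uniform(0.2, 0.8), float(a), float(b), v0, v0, cfg)
            if cand.loglik > best.loglik:
                best = cand
    return best


def ashman_d(fit: MixtureFit) -> float:
    """Ashman–Bird–Zepf separation: √2 |μ1−μ2| / √(σ1²+σ2²)."""
    return math.sqrt(2.0) * abs(fit.mu1 - fit.mu2) / math.hypot(fit.sigma1, fit.sigma2)


def bimodality_index(fit: MixtureFit) -> float:
    """Wang-style bimodality index: √(p(1−p)) |μ1−μ2| / σ_pooled."""
    sigma_pooled = math.sqrt((fit.sigma1**2 + fit.sigma2**2) / 2.0)
    return math.sqrt(fit.p * (1.0 - fit.p)) * abs(fit.mu1 - fit.mu2) / sigma_pooled


def _variable_result(
    values, threshold: float, cfg: FitSettings, label: str
) -> VariableBimodality:
    try:
        fit = fit_two_component_mixture(values, cfg)
    except DegenerateSampleError:
        if cfg.degenerate_as_unimodal:
            return VariableBimodality(ashman_d=0.0, bindex=0.0, bimodal=False, fit=None)
        raise DegenerateSampleError(f"variable {label!r}: zero-variance sample")
    d = ashman_d(fit)
    return VariableBimodality(
        ashman_d=d, bindex=bimodality_index(fit), bimodal=d > threshold, fit=fit
    )


def bimodality_profile(
    cells: CaseCellSet,
    threshold: float = 2.0,
    cfg: FitSettings = FitSettings(),
) -> BimodalityResult:
    """Fit mixtures to per-cell HER2, CEP17 and ratio; flag bimodality by D > threshold."""
    require_filtered(cells, n_min=cfg.min_n)
    return BimodalityResult(
        case_id=cells.case_id,
        source=cells.source,
        her2=_variable_result(cells.her2_counts(), threshold, cfg, "her2"),
        cep17=_variable_result(cells.cep17_counts(), threshold, cfg, "cep17"),
        ratio=_variable_result(cells.ratios(), threshold, cfg, "ratio"),
    )
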