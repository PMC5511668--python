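"""Subsampling simulation: how many cells are needed to detect bimodality.

Mirrors the manual-versus-automated sampling question: the manual procedure
counts 40–60 nuclei, while automated image analysis yields hundreds to
thousands. For a given per-cell distribution, cells are repeatedly
subsampled without replacement at increasing sample sizes, a two-Gaussian
mixture is fitted to each subsample, and the fraction of iterations with
Ashman's D above the bimodality threshold gives a detection-rate curve over
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bimodality import FitSettings, ashman_d, fit_two_component_mixture
from .errors import DegenerateSampleError, InsufficientDataError

#: Default sample-size grid spanning the manual (40) to automated (1000) range.
DEFAULT_SIZES = (40, 60, 100, 200, 400, 600, 800, 1000)


@dataclass(frozen=True)
class SubsampleCurve:
    sizes: tuple[int, ...]
    mean_d: tuple[float, ...]  # mean Ashman's D over successful fits
    detection_rate: tuple[float, ...]  # fraction of iterations with D > threshold
    n_failures: tuple[int, ...]  # degenerate subsamples, counted as non-detections
    iterations: int
    threshold: float
    seed: int | None

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")


def subsample_curve(
    values,
    sizes=DEFAULT_SIZES,
    iterations: int = 1000,
    threshold: float = 2.0,
    seed: int | None = None,
    fit_cfg: FitSettings = FitSettings(),
) -> SubsampleCurve:
    """Monte-Carlo detection-rate curve of bimodality over subsample size.

    For each size s, draws ``iterations`` subsamples of size s without
    replacement, fits the mixture and records Ashman's D. Degenerate
    subsamples (zero variance) count as non-detections and are tallied in
    ``n_failures``. Fully reproducible from ``seed``.
    """
    x = np.asarray(values, dtype=float).ravel()
    sizes = tuple(int(s) for s in sizes)
    for s in sizes:
        if s > x.size:
            raise InsufficientDataError(
                f"subsample size {s} exceeds available sample of {x.size} values"
            )
    rng = np.random.default_rng(seed)
    mean_d, rates, fails = [], [], []
    for s in sizes:
        ds = []
        detected = 0
        failed = 0
        for _ in range(iterations):
            sub = rng.choice(x, size=s, replace=False)
            try:
                fit = fit_two_component_mixture(sub, fit_cfg)
            except DegenerateSampleError:
                failed += 1
                continue
            d = ashman_d(fit)
            ds.append(d)
            if d > threshold:
                detected += 1
        mean_d.append(float(np.mean(ds)) if ds else float("nan"))
        rates.append(detected / iterations)
        fails.append(failed)
    return SubsampleCurve(
        sizes=sizes,
        mean_d=tuple(mean_d),
        detection_rate=tuple(rates),
        n_failures=tuple(fails),
        iterations=iterations,
        threshold=threshold,
        seed=seed,
    )


def rare_detection_sizes(curve: SubsampleCurve) -> list[int]:
    """Sizes at which bimodality is detected in fewer than half the iterations."""
    return [s for s, r in zip(curve.sizes, curve.detection_rate) if r < 0.5]


def robust_sample_size(
    curve: SubsampleCurve, rate_required: float = 0.95
) -> int | None:
    """Smallest size whose detection rate reaches ``rate_required``; None if none does.

    No smoothing is applied: a non-monotone curve still yields the smallest
    qualifying size.
    """
    for s, r in zip(curve.sizes, curve.detection_rate):
        if r >= rate_required:
            return s
    return None


def curve_to_frame(curve: SubsampleCurve, case_id: str = "", variable: str = ""):
    import pandas as pd

    return pd.DataFrame(
        {
            "case_id": case_id,
            "variable": variable,
            "size": curve.sizes,
            "mean_d": curve.mean_d,
            "detection_rate": curve.detection_rate,
            "n_failures": curve.n_failures,
        }
    )
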