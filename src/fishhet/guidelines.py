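"""Case-level summaries and the clinical classification rulebook.

Implements the dual-probe amplification categories (ASCO/CAP 2013 encoding:
positive when the HER2/CEP17 ratio-of-sums is ≥ 2.0 or mean HER2 ≥ 6.0;
equivocal when the ratio is < 2.0 and mean HER2 lies in [4.0, 6.0)),
CEP17 polysomy (mean CEP17 ≥ 3), amplified-cell fractions (per-cell ratio
> 2.2, or > 6 HER2 signals for the single-probe variant, both strict), and
the CAP 2009 genetic-heterogeneity (GH) flag: strictly more than 5% and
strictly less than 50% of cells individually amplified.

The per-tumor ratio is the ratio of sums — total HER2 signals divided by
total CEP17 signals — not the mean of per-cell ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import CaseCellSet, require_filtered
from .errors import InsufficientDataError


@dataclass(frozen=True)
class GuidelineThresholds:
    """All clinical cut-offs in one configurable place.

    ``ad_heterogeneous_band`` is the separate, inclusive-lower-bound interval
    used to call automated data "potentially heterogeneous"
    (5 ≤ amplified-cell % < 25 by default); it is distinct from the strict GH
    bounds.
    """

    ratio_positive: float = 2.0
    her2_positive: float = 6.0
    her2_equivocal_low: float = 4.0
    polysomy_cep17: float = 3.0
    cell_amp_ratio_cutoff: float = 2.2
    her2only_cutoff: float = 6.0
    gh_lower_pct: float = 5.0
    gh_upper_pct: float = 50.0
    ad_heterogeneous_band: tuple[float, float] = (5.0, 25.0)

    def __post_init__(self):
        if not self.gh_lower_pct < self.gh_upper_pct:
            raise ValueError("gh_lower_pct must be below gh_upper_pct")


@dataclass
class CaseSummary:
    """Per-case indicators feeding classification, plots and factor analysis."""

    case_id: str
    source: str
    n_cells: int
    mean_her2: float
    mean_cep17: float
    ratio: float  # ratio of sums, Σher2 / Σcep17
    amp_cell_pct: float
    amp_cell_pct_her2only: float
    amplification: str  # amplified | equivocal | negative
    polysomy: bool
    gh_ratio: bool
    gh_her2only: bool


def classify_amplification(
    mean_her2: float, ratio: float, thr: GuidelineThresholds = GuidelineThresholds()
) -> str:
    if ratio >= thr.ratio_positive or mean_her2 >= thr.her2_positive:
        return "amplified"
    if thr.her2_equivocal_low <= mean_her2 < thr.her2_positive:
        return "equivocal"
    return "negative"


def classify_polysomy(
    mean_cep17: float, thr: GuidelineThresholds = GuidelineThresholds()
) -> bool:
    return bool(mean_cep17 >= thr.polysomy_cep17)


def amplified_cell_fraction(
    cells: CaseCellSet,
    mode: str = "ratio",
    thr: GuidelineThresholds = GuidelineThresholds(),
) -> float:
    """Percentage of cells individually amplified (strict comparisons).

    ``mode="ratio"``: per-cell HER2/CEP17 ratio > ``cell_amp_ratio_cutoff``.
    ``mode="her2only"``: HER2 count > ``her2only_cutoff``.
    """
    require_filtered(cells, n_min=1)
    if mode == "ratio":
        hits = np.count_nonzero(cells.ratios() > thr.cell_amp_ratio_cutoff)
    elif mode == "her2only":
        hits = np.count_nonzero(cells.her2_counts() > thr.her2only_cutoff)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(100.0 * hits / len(cells))


def classify_gh(
    amp_pct: float, thr: GuidelineThresholds = GuidelineThresholds()
) -> bool:
    """Genetic heterogeneity: strictly between the lower and upper bounds."""
    return bool(thr.gh_lower_pct < amp_pct < thr.gh_upper_pct)


def in_ad_heterogeneous_band(
    amp_pct: float, thr: GuidelineThresholds = GuidelineThresholds()
) -> bool:
    """"Potentially heterogeneous" band for automated data: lo ≤ pct < hi."""
    lo, hi = thr.ad_heterogeneous_band
    return bool(lo <= amp_pct < hi)


def summarize_case(
    cells: CaseCellSet, thr: GuidelineThresholds = GuidelineThresholds()
) -> CaseSummary:
    """Compute every case-level indicator from a filtered cell set."""
    require_filtered(cells, n_min=1)
    her2 = cells.her2_counts()
    cep17 = cells.cep17_counts()
    if cep17.sum() == 0:
        raise InsufficientDataError(
            f"case {cells.case_id!r}: total CEP17 signal count is zero"
        )
    ratio = her2.sum() / cep17.sum()
    mean_her2 = float(her2.mean())
    mean_cep17 = float(cep17.mean())
    amp_pct = amplified_cell_fraction(cells, "ratio", thr)
    amp_pct_h = amplified_cell_fraction(cells, "her2only", thr)
    return CaseSummary(
        case_id=cells.case_id,
        source=cells.source,
        n_cells=len(cells),
        mean_her2=mean_her2,
        mean_cep17=mean_cep17,
        ratio=float(ratio),
        amp_cell_pct=amp_pct,
        amp_cell_pct_her2only=amp_pct_h,
        amplification=classify_amplification(mean_her2, ratio, thr),
        polysomy=classify_polysomy(mean_cep17, thr),
        gh_ratio=classify_gh(amp_pct, thr),
        gh_her2only=classify_gh(amp_pct_h, thr),
    )


def summaries_to_frame(summaries) -> "pd.DataFrame":
    import pandas as pd

    cols = [
        "case_id",
        "source",
        "n_cells",
        "mean_her2",
        "mean_cep17",
        "ratio",
        "amp_cell_pct",
        "amp_cell_pct_her2only",
        "amplification",
        "polysomy",
        "gh_ratio",
        "gh_her2only",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])
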