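"""Synthetic borderline-breast-carcinoma cohorts for end-to-end testing.

No per-nucleus FISH dataset is publicly deposited for this kind of study,
so the generator plants the biology the pipeline must recover: mixtures of
nonamplified (HER2 ≈ 2), amplified-subclone (elevated HER2) and polysomic
(mean CEP17 ≥ 3) cell populations, with amplified cells either scattered
uniformly through the field or grouped around a few cluster centers, and an
observation model producing the three data sources:

* CD — the generated counts themselves (ground truth),
* AD — per-signal binomial thinning plus whole-nucleus dropout, emulating
  automated under-detection,
* MP — a small observer-style sample (40 nuclei, +20 for equivocal cases)
  drawn without replacement, optionally biased toward signal-rich nuclei,
  with no thinning.

Per-nucleus counts are truncated-at-zero negative binomial: a population
with mean m and dispersion k has variance m + m²/k, so large k approaches
Poisson and small k yields the overdispersion typical of amplified clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CaseCellSet, NucleusRecord, cells_to_frame
from .errors import ConfigError

#: Default field of view: ≈ 4 fields of 1392×1024 px at 0.16 µm/px.
DEFAULT_FIELD_W = 880.0
DEFAULT_FIELD_H = 650.0


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population within a case."""

    weight: float
    her2_mean: float
    cep17_mean: float
    her2_dispersion: float = 20.0
    cep17_dispersion: float = 20.0
    spatial_mode: str = "scattered"  # scattered | clustered
    n_cluster_centers: int = 3
    cluster_sd_um: float = 40.0

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigError(f"population weight {self.weight} outside [0, 1]")
        if self.her2_mean <= 0 or self.cep17_mean <= 0:
            raise ConfigError("population means must be positive")
        if self.spatial_mode not in ("scattered", "clustered"):
            raise ConfigError(f"unknown spatial_mode {self.spatial_mode!r}")


@dataclass(frozen=True)
class CaseSimConfig:
    case_id: str
    n_cells: int
    populations: tuple[PopulationSpec, ...]
    field_width: float = DEFAULT_FIELD_W
    field_height: float = DEFAULT_FIELD_H
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigError("n_cells must be ≥ 1")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ConfigError("field dimensions must be positive")
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"population weights sum to {total}, expected 1")


@dataclass(frozen=True)
class DetectionConfig:
    """Observation model turning ground-truth counts into AD and MP sources."""

    signal_detect_prob: float = 0.97
    nucleus_miss_prob: float = 0.09
    mp_sample_size: int = 40
    mp_equivocal_extra: int = 20
    mp_selection_bias: float = 0.0  # weight ∝ (her2+cep17)^bias

    def __post_init__(self):
        if not 0.0 < self.signal_detect_prob <= 1.0:
            raise ConfigError("signal_detect_prob must be in (0, 1]")
        if not 0.0 <= self.nucleus_miss_prob < 1.0:
            raise ConfigError("nucleus_miss_prob must be in [0, 1)")
        if self.mp_sample_size < 1:
            raise ConfigError("mp_sample_size must be ≥ 1")


@dataclass(frozen=True)
class SimulatedCase:
    """Ground-truth cell set plus the per-nucleus population labels."""

    cells: CaseCellSet
    population_labels: np.ndarray  # index into cfg.populations, length n_cells


def _nb_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    # numpy parameterization: n = dispersion, p = n / (n + mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_case(cfg: CaseSimConfig, rng=None) -> SimulatedCase:
    """Generate one ground-truth (CD) case; reproducible from cfg.seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = np.array([p.weight for p in cfg.populations])
    labels = rng.choice(len(cfg.populations), size=cfg.n_cells, p=weights)

    her2 = np.zeros(cfg.n_cells, dtype=int)
    cep17 = np.zeros(cfg.n_cells, dtype=int)
    x = np.zeros(cfg.n_cells)
    y = np.zeros(cfg.n_cells)
    for k, pop in enumerate(cfg.populations):
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            continue
        her2[idx] = _nb_counts(rng, pop.her2_mean, pop.her2_dispersion, idx.size)
        cep17[idx] = _nb_counts(rng, pop.cep17_mean, pop.cep17_dispersion, idx.size)
        if pop.spatial_mode == "scattered":
            x[idx] = rng.uniform(0.0, cfg.field_width, idx.size)
            y[idx] = rng.uniform(0.0, cfg.field_height, idx.size)
        else:
            centers = np.column_stack(
                [
                    rng.uniform(0.0, cfg.field_width, pop.n_cluster_centers),
                    rng.uniform(0.0, cfg.field_height, pop.n_cluster_centers),
                ]
            )
            which = rng.integers(0, pop.n_cluster_centers, idx.size)
            pts = centers[which] + rng.normal(0.0, pop.cluster_sd_um, (idx.size, 2))
            x[idx] = np.clip(pts[:, 0], 0.0, cfg.field_width)
            y[idx] = np.clip(pts[:, 1], 0.0, cfg.field_height)

    nuclei = [
        NucleusRecord(
            case_id=cfg.case_id,
            nucleus_id=f"{cfg.case_id}-{i}",
            source="CD",
            x=float(x[i]),
            y=float(y[i]),
            her2=int(her2[i]),
            cep17=int(cep17[i]),
        )
        for i in range(cfg.n_cells)
    ]
    cells = CaseCellSet(case_id=cfg.case_id, source="CD", nuclei=nuclei)
    return SimulatedCase(cells=cells, population_labels=labels)


def apply_detection_model(
    truth: CaseCellSet,
    det: DetectionConfig = DetectionConfig(),
    case_status_hint: str = "nonequivocal",
    rng=None,
    seed: int | None = None,
) -> tuple[CaseCellSet, CaseCellSet]:
    """Derive AD (thinned) and MP (small observer sample) sets from the truth.

    AD keeps each signal independently with ``signal_detect_prob`` and drops
    each nucleus with ``nucleus_miss_prob``; channel-wise AD counts never
    exceed the truth. MP draws ``mp_sample_size`` nuclei (plus
    ``mp_equivocal_extra`` when the hint is "equivocal") without replacement,
    weighted by (her2+cep17)^mp_selection_bias, without thinning; positions
    are not recorded, as in manual reading.
    """
    if truth.source != "CD":
        raise ConfigError("detection model applies to a ground-truth CD set")
    if rng is None:
        rng = np.random.default_rng(seed)

    her2 = truth.her2_counts().astype(int)
    cep17 = truth.cep17_counts().astype(int)
    n = len(truth)

    keep = rng.random(n) >= det.nucleus_miss_prob
    ad_her2 = rng.binomial(her2, det.signal_detect_prob)
    ad_cep17 = rng.binomial(cep17, det.signal_detect_prob)
    ad_nuclei = [
        replace(truth.nuclei[i], source="AD", her2=int(ad_her2[i]), cep17=int(ad_cep17[i]))
        for i in np.flatnonzero(keep)
    ]
    ad = CaseCellSet(case_id=truth.case_id, source="AD", nuclei=ad_nuclei)

    want = det.mp_sample_size
    if case_status_hint == "equivocal":
        want += det.mp_equivocal_extra
    if want > n:
        warnings.warn(
            f"case {truth.case_id!r}: MP sample of {want} requested but only "
            f"{n} nuclei available; taking all",
            stacklevel=2,
        )
        chosen = np.arange(n)
    else:
        w = (her2 + cep17).astype(float) ** det.mp_selection_bias
        chosen = rng.choice(n, size=want, replace=False, p=w / w.sum())
    mp_nuclei = [
        replace(truth.nuclei[i], source="MP", x=None, y=None) for i in sorted(chosen)
    ]
    mp = CaseCellSet(case_id=truth.case_id, source="MP", nuclei=mp_nuclei)
    return ad, mp


# --------------------------------------------------------------------------
# Archetype presets
# --------------------------------------------------------------------------

# Disomic background. cep17_mean 1.8 keeps the post-filter mean CEP17 of
# disomic cells below the polysomy cut-off: conditioning on cep17 >= 2
# shifts a near-Poisson mean-2 channel up to ~2.9, a hair from the 3.0 rule.
_BACKGROUND = dict(her2_mean=2.0, cep17_mean=1.8)

#: Named case archetypes with planted truth labels. Weights/means are chosen
#: so the guideline classifier recovers the intended category on ground truth.
ARCHETYPES = {
    "negative": dict(
        populations=(PopulationSpec(weight=1.0, **_BACKGROUND),),
        amp_weight=0.0,
        polysomy=False,
        bimodal_her2=False,
        status_hint="nonequivocal",
    ),
    "amplified": dict(
        populations=(
            PopulationSpec(weight=0.9, her2_mean=12.0, cep17_mean=1.9,
                           her2_dispersion=100.0),
            PopulationSpec(weight=0.1, **_BACKGROUND),
        ),
        amp_weight=0.9,
        polysomy=False,
        bimodal_her2=False,
        status_hint="nonequivocal",
    ),
    "equivocal_polysomy": dict(
        populations=(
            PopulationSpec(weight=1.0, her2_mean=4.6, cep17_mean=3.8),
        ),
        amp_weight=0.0,
        polysomy=True,
        bimodal_her2=False,
        status_hint="equivocal",
    ),
    "gh": dict(
        populations=(
            PopulationSpec(weight=0.85, **_BACKGROUND),
            PopulationSpec(weight=0.15, her2_mean=14.0, cep17_mean=2.0,
                           her2_dispersion=100.0, spatial_mode="clustered"),
        ),
        amp_weight=0.15,
        polysomy=False,
        bimodal_her2=True,
        status_hint="nonequivocal",
    ),
    "bimodal_negative": dict(
        populations=(
            PopulationSpec(weight=0.75, her2_mean=1.5, cep17_mean=1.8),
            PopulationSpec(weight=0.25, her2_mean=8.0, cep17_mean=2.5,
                           her2_dispersion=50.0),
        ),
        amp_weight=0.0,
        polysomy=False,
        bimodal_her2=True,
        status_hint="nonequivocal",
    ),
}


def archetype_config(
    name: str,
    case_id: str,
    n_cells: int = 800,
    seed: int = 0,
    scattered: bool = False,
) -> CaseSimConfig:
    """Build a case config from a named archetype.

    ``scattered=True`` forces every population to the scattered spatial mode
    (used to contrast dispersion against the default clustered subclones).
    """
    if name not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}")
    pops = ARCHETYPES[name]["populations"]
    if scattered:
        pops = tuple(replace(p, spatial_mode="scattered") for p in pops)
    return CaseSimConfig(case_id=case_id, n_cells=n_cells, populations=pops, seed=seed)


#: Four-group archetype mix used for factor/cluster recovery experiments.
FOUR_GROUP_MIX = (
    ("amplified", 12),
    ("negative", 14),
    ("equivocal_polysomy", 12),
    ("gh", 12),
)

#: Archetype mix of the default 50-case cohort (borderline-carcinoma style:
#: mostly negative/equivocal with a minority of amplified and heterogeneous cases).
DEFAULT_COHORT_MIX = (
    ("amplified", 10),
    ("negative", 12),
    ("equivocal_polysomy", 16),
    ("gh", 8),
    ("bimodal_negative", 4),
)


@dataclass(frozen=True)
class Cohort:
    cells: pd.DataFrame  # canonical per-cell columns, all sources
    truth_labels: pd.DataFrame  # case_id, archetype, amp_weight, polysomy, bimodal_her2
    case_sets: dict  # (case_id, source) -> CaseCellSet


def generate_cohort(
    configs: Sequence[tuple[CaseSimConfig, str]],
    det: DetectionConfig = DetectionConfig(),
    seed: int = 0,
) -> Cohort:
    """Generate CD/AD/MP sources for each (config, archetype-name) pair.

    All randomness derives from the single cohort ``seed`` via per-case
    SeedSequence spawn keys (the case index), so cases are independent and
    the cohort is reproducible regardless of any per-case cfg.seed.
    """
    ids = [cfg.case_id for cfg, _ in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigError(f"duplicate case_id(s): {dupes}")

    case_sets: dict = {}
    truth_rows = []
    all_sets = []
    for idx, (cfg, archetype) in enumerate(configs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))
        sim = generate_case(cfg, rng=rng)
        arch = ARCHETYPES.get(archetype, {})
        hint = arch.get("status_hint", "nonequivocal")
        ad, mp = apply_detection_model(sim.cells, det, case_status_hint=hint, rng=rng)
        for cs in (sim.cells, ad, mp):
            case_sets[(cfg.case_id, cs.source)] = cs
            all_sets.append(cs)
        truth_rows.append(
            {
                "case_id": cfg.case_id,
                "archetype": archetype,
                "amp_weight": arch.get("amp_weight", float("nan")),
                "polysomy": arch.get("polysomy", False),
                "bimodal_her2": arch.get("bimodal_her2", False),
            }
        )
    return Cohort(
        cells=cells_to_frame(all_sets),
        truth_labels=pd.DataFrame(
            truth_rows,
            columns=["case_id", "archetype", "amp_weight", "polysomy", "bimodal_her2"],
        ),
        case_sets=case_sets,
    )


def preset_cohort_configs(
    n_cells: int = 800,
    mix=DEFAULT_COHORT_MIX,
) -> list[tuple[CaseSimConfig, str]]:
    """Expand the archetype mix into per-case configs (case ids C01, C02, ...)."""
    configs = []
    i = 0
    for name, count in mix:
        for _ in range(count):
            i += 1
            configs.append((archetype_config(name, f"C{i:02d}", n_cells=n_cells), name))
    return configs
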