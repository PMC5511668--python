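"""End-to-end pipeline: filter → summaries → bimodality → spatial →
concordance → factors/clusters, with a JSON manifest of every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bimodality import BimodalityResult, FitSettings, bimodality_profile
from .concordance_qc import concordance_to_frame, match_by_case, regression_agreement
from .core_io import CaseCellSet, FilterRule, filter_evaluable, read_cell_table
from .errors import ConfigError, FishhetError, InsufficientDataError
from .guidelines import GuidelineThresholds, summaries_to_frame, summarize_case
from .multivariate import (
    build_feature_matrix,
    cluster_cases,
    fit_factors,
    summarize_clusters,
)
from .spatial import spatial_result, spatial_to_frame
from .synthetic_cohort import DetectionConfig, generate_cohort, preset_cohort_configs

log = logging.getLogger("fishhet")


@dataclass
class PipelineConfig:
    input_path: str | None = None
    simulate: bool = False
    n_cells: int = 800
    filter_rule: FilterRule = field(default_factory=FilterRule)
    thresholds: GuidelineThresholds = field(default_factory=GuidelineThresholds)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    ashman_threshold: float = 2.0
    n_factors: int = 3
    k_clusters: int = 4
    out_dir: str = "fishhet_out"
    seed: int = 0

    def __post_init__(self):
        if bool(self.input_path) == bool(self.simulate):
            raise ConfigError("exactly one of input_path / simulate must be set")


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            out = fn(*a, **kw)
            log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def cohort_indicators(
    case_sets: dict,
    filter_rule: FilterRule = FilterRule(),
    thresholds: GuidelineThresholds = GuidelineThresholds(),
    fit_cfg: FitSettings = FitSettings(),
    ashman_threshold: float = 2.0,
) -> tuple[dict, dict]:
    """Filter every case set and compute summaries plus AD bimodality profiles.

    Returns (summaries, bimod) keyed like the factor-analysis inputs:
    summaries by (case_id, source), bimodality by case_id (AD source only).
    """
    summaries: dict = {}
    bimod: dict[str, BimodalityResult] = {}
    for key, cs in case_sets.items():
        fcs, _ = filter_evaluable(cs, filter_rule)
        if len(fcs) == 0:
            continue
        summaries[key] = summarize_case(fcs, thresholds)
        if cs.source == "AD" and len(fcs) >= fit_cfg.min_n:
            bimod[cs.case_id] = bimodality_profile(fcs, ashman_threshold, fit_cfg)
    return summaries, bimod


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write CSV outputs plus manifest.json.

    Returns the manifest dictionary. Cases or sources that lack the data a
    stage needs (e.g. too few amplified nuclei for spatial statistics) are
    skipped with a log line, never a crash.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if cfg.simulate:
        cohort = generate_cohort(
            preset_cohort_configs(n_cells=cfg.n_cells), DetectionConfig(), seed=cfg.seed
        )
        cohort.cells.to_csv(out / "cells.csv", index=False)
        cohort.truth_labels.to_csv(out / "truth_labels.csv", index=False)
        outputs["cells"] = "cells.csv"
        outputs["truth_labels"] = "truth_labels.csv"
        case_sets = cohort.case_sets
    else:
        case_sets = {
            (cs.case_id, cs.source): cs for cs in read_cell_table(cfg.input_path)
        }

    # evaluability filter (kept for the spatial stage), summaries, bimodality
    filtered = {}
    for key, cs in case_sets.items():
        fcs, _ = filter_evaluable(cs, cfg.filter_rule)
        if len(fcs) > 0:
            filtered[key] = fcs
    summaries, bimod = cohort_indicators(
        case_sets, cfg.filter_rule, cfg.thresholds, cfg.fit_settings, cfg.ashman_threshold
    )
    summaries_to_frame(summaries.values()).to_csv(out / "case_summaries.csv", index=False)
    outputs["case_summaries"] = "case_summaries.csv"
    if bimod:
        pd.DataFrame([b.as_row() for b in bimod.values()]).to_csv(
            out / "bimodality.csv", index=False
        )
        outputs["bimodality"] = "bimodality.csv"

    # spatial dispersion on automated data
    spatial_rows = []
    for (cid, src), cs in filtered.items():
        if src != "AD":
            continue
        try:
            r = spatial_result(cs, cfg.thresholds.cell_amp_ratio_cutoff)
        except FishhetError:
            r = None
        if r is not None:
            spatial_rows.append(r)
    if spatial_rows:
        spatial_to_frame(spatial_rows).to_csv(out / "spatial.csv", index=False)
        outputs["spatial"] = "spatial.csv"

    # concordance: AD vs CD and AD vs MP on shared cases
    conc_frames = []
    for ref in ("CD", "MP"):
        for var, attr in (
            ("HER2 copy number", "mean_her2"),
            ("CEP17 copy number", "mean_cep17"),
            ("HER2/CEP17 ratio", "ratio"),
        ):
            dep = {
                cid: getattr(s, attr)
                for (cid, src), s in summaries.items()
                if src == "AD" and (cid, ref) in summaries
            }
            exp = {cid: getattr(summaries[(cid, ref)], attr) for cid in dep}
            if len(dep) < 3:
                continue
            y, x = match_by_case(dep, exp)
            conc_frames.append(
                concordance_to_frame([regression_agreement(y, x, var)], f"AD~{ref}")
            )
    if conc_frames:
        pd.concat(conc_frames, ignore_index=True).to_csv(
            out / "concordance.csv", index=False
        )
        outputs["concordance"] = "concordance.csv"

    # factors and clusters, when every case has AD + MP + bimodality
    try:
        fm = build_feature_matrix(
            {k: v for k, v in summaries.items() if k[1] in ("AD", "MP")}, bimod
        )
        model = fit_factors(fm, cfg.n_factors)
        cr = cluster_cases(model.scores, cfg.k_clusters, seed=cfg.seed)
        model.loadings.to_csv(out / "factor_loadings.csv")
        model.scores.to_csv(out / "factor_scores.csv")
        cr.assignments.to_frame().to_csv(out / "cluster_assignments.csv")
        summarize_clusters(
            cr, summaries, bimod, cfg.thresholds, cfg.ashman_threshold
        ).to_csv(out / "cluster_summary.csv")
        outputs.update(
            factor_loadings="factor_loadings.csv",
            factor_scores="factor_scores.csv",
            cluster_assignments="cluster_assignments.csv",
            cluster_summary="cluster_summary.csv",
        )
    except (InsufficientDataError, FishhetError) as exc:
        log.warning("multivariate stage skipped: %s", exc)

    manifest = {
        "fishhet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
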