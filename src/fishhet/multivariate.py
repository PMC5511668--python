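"""Factor analysis of heterogeneity indicators and k-means stratification.

Fourteen case-level indicators — amplified-cell percentages, mean counts
and ratios from both the manual (``_M``) and automated (``_A``) procedures,
plus the Ashman's D and bimodality-index values of the automated per-cell
distributions — are standardized and reduced to three orthogonal latent
axes. Extraction is principal-component based (eigendecomposition of the
correlation matrix), rotated with varimax, with regression-method factor
scores; the three factors are auto-labelled amplification / polysomy /
bimodality by the block of variables they load on. Cases are then
stratified by k-means (k = 4 by default) on the factor scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bimodality import BimodalityResult
from .errors import ConfigError, InsufficientDataError, SingularFitError
from .guidelines import CaseSummary, GuidelineThresholds, classify_gh

#: Declared column order of the feature matrix.
FEATURE_COLUMNS = (
    "Cell_Amp_%_M",
    "Cell_Amp_%_A",
    "HER2_A",
    "HER2_M",
    "CEP17_A",
    "CEP17_M",
    "Ratio_A",
    "Ratio_M",
    "AshD_Ratio",
    "AshD_HER2",
    "AshD_CEP17",
    "BIndex_HER2",
    "BIndex_CEP17",
    "BIndex_Ratio",
)

#: Variable blocks used for factor auto-labelling, in tie-break priority order.
FACTOR_BLOCKS = (
    (
        "amplification",
        ("HER2_A", "HER2_M", "Ratio_A", "Ratio_M", "Cell_Amp_%_A", "Cell_Amp_%_M"),
    ),
    ("polysomy", ("CEP17_A", "CEP17_M")),
    (
        "bimodality",
        (
            "AshD_Ratio",
            "AshD_HER2",
            "AshD_CEP17",
            "BIndex_HER2",
            "BIndex_CEP17",
            "BIndex_Ratio",
        ),
    ),
)


@dataclass(frozen=True)
class FeatureMatrix:
    values: pd.DataFrame  # standardized, columns = FEATURE_COLUMNS
    means: pd.Series
    sds: pd.Series


@dataclass(frozen=True)
class FactorModel:
    loadings: pd.DataFrame  # 14 × n_factors, rotated
    scores: pd.DataFrame  # n_cases × n_factors (regression method)
    rotation: str
    labels: dict[str, str]  # factor column -> block label
    label_evidence: pd.DataFrame  # block-mean |loading| per factor


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: pd.Series  # case_id -> cluster id (1-based)
    centroids: np.ndarray  # k × n_factors
    inertia: float


def build_feature_matrix(
    summaries: dict[tuple[str, str], CaseSummary],
    bimod: dict[str, BimodalityResult],
) -> FeatureMatrix:
    """Assemble and standardize the 14-variable case × indicator matrix.

    ``summaries`` maps (case_id, source) to case summaries and must contain
    both AD and MP per case; ``bimod`` maps case_id to the AD bimodality
    profile.
    """
    case_ids = sorted({cid for cid, _ in summaries})
    missing = []
    for cid in case_ids:
        for src in ("AD", "MP"):
            if (cid, src) not in summaries:
                missing.append(f"{cid}:{src}")
        if cid not in bimod:
            missing.append(f"{cid}:bimodality")
    if missing:
        raise InsufficientDataError(
            f"feature matrix assembly: missing inputs for {missing}"
        )

    rows = []
    for cid in case_ids:
        ad, mp, b = summaries[(cid, "AD")], summaries[(cid, "MP")], bimod[cid]
        rows.append(
            {
                "Cell_Amp_%_M": mp.amp_cell_pct,
                "Cell_Amp_%_A": ad.amp_cell_pct,
                "HER2_A": ad.mean_her2,
                "HER2_M": mp.mean_her2,
                "CEP17_A": ad.mean_cep17,
                "CEP17_M": mp.mean_cep17,
                "Ratio_A": ad.ratio,
                "Ratio_M": mp.ratio,
                "AshD_Ratio": b.ratio.ashman_d,
                "AshD_HER2": b.her2.ashman_d,
                "AshD_CEP17": b.cep17.ashman_d,
                "BIndex_HER2": b.her2.bindex,
                "BIndex_CEP17": b.cep17.bindex,
                "BIndex_Ratio": b.ratio.bindex,
            }
        )
    df = pd.DataFrame(rows, index=case_ids, columns=list(FEATURE_COLUMNS))
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise InsufficientDataError(f"missing values in feature columns {bad}")
    means = df.mean()
    sds = df.std(ddof=1)
    zero = sds[sds == 0.0].index.tolist()
    if zero:
        raise SingularFitError(f"zero-variance feature columns: {zero}")
    return FeatureMatrix(values=(df - means) / sds, means=means, sds=sds)


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (SVD formulation, no Kaiser normalization)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (lam * (lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return loadings @ rot


def fit_factors(
    m: FeatureMatrix, n_factors: int = 3, rotation: str = "varimax"
) -> FactorModel:
    """Principal-component extraction, varimax rotation, regression scores."""
    Z = m.values.to_numpy()
    n, p = Z.shape
    if n <= n_factors:
        raise InsufficientDataError(
            f"{n} cases cannot support {n_factors} factors"
        )
    corr = np.corrcoef(Z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise SingularFitError("correlation matrix is singular or undefined")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:n_factors]
    eigval = np.clip(eigval[order], 0.0, None)
    loadings = eigvec[:, order] * np.sqrt(eigval)

    if rotation == "varimax":
        loadings = varimax(loadings)
    elif rotation != "none":
        raise ConfigError(f"unknown rotation {rotation!r}")

    # canonical sign: each factor's largest-|loading| variable loads positively
    for j in range(n_factors):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]

    # regression-method scores for orthogonal PCA factors: F = Z L (L'L)^-1
    scores = Z @ loadings @ np.linalg.inv(loadings.T @ loadings)

    cols = [f"factor{j + 1}" for j in range(n_factors)]
    ldf = pd.DataFrame(loadings, index=m.values.columns, columns=cols)
    sdf = pd.DataFrame(scores, index=m.values.index, columns=cols)

    evidence = pd.DataFrame(
        {
            block: ldf.loc[list(variables)].abs().mean()
            for block, variables in FACTOR_BLOCKS
        }
    )  # factors × blocks
    labels: dict[str, str] = {}
    taken: set[str] = set()
    for block, _ in FACTOR_BLOCKS:  # priority order breaks conflicts
        remaining = [c for c in cols if c not in taken]
        if not remaining:
            break
        best = evidence.loc[remaining, block].idxmax()
        labels[best] = block
        taken.add(best)
    return FactorModel(
        loadings=ldf, scores=sdf, rotation=rotation, labels=labels,
        label_evidence=evidence,
    )


def cluster_cases(
    scores: pd.DataFrame, k: int = 4, seed: int = 0, restarts: int = 50
) -> ClusterResult:
    """k-means on factor scores with multiple restarts; deterministic per seed."""
    X = scores.to_numpy()
    if len(np.unique(X, axis=0)) < k:
        raise InsufficientDataError(
            f"need at least {k} distinct score points for k = {k}"
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    ids = km.fit_predict(X)
    # stable 1-based relabelling by cluster size then first occurrence
    order = sorted(range(k), key=lambda c: (-(ids == c).sum(), np.argmax(ids == c)))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series([relabel[i] for i in ids], index=scores.index, name="cluster")
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=km.cluster_centers_[order],
        inertia=float(km.inertia_),
    )


def summarize_clusters(
    cr: ClusterResult,
    summaries: dict[tuple[str, str], CaseSummary],
    bimod: dict[str, BimodalityResult],
    thr: GuidelineThresholds = GuidelineThresholds(),
    ashman_threshold: float = 2.0,
    clinical_source: str = "MP",
) -> pd.DataFrame:
    """Per-cluster characteristic counts plus a Total column.

    Amplification / polysomy / GH rows come from the ``clinical_source``
    summaries (the conventional manual read by default); Ashman's D rows
    come from the automated bimodality profiles.
    """
    clusters = sorted(cr.assignments.unique())
    rows = {
        "n": {},
        "amplified": {},
        "equivocal": {},
        "negative": {},
        "polysomy": {},
        "gh_ratio": {},
        "gh_her2only": {},
        "ashd_ratio_gt2": {},
        "ashd_her2_gt2": {},
        "ashd_cep17_gt2": {},
    }
    for c in clusters + ["Total"]:
        if c == "Total":
            cases = list(cr.assignments.index)
        else:
            cases = list(cr.assignments.index[cr.assignments == c])
        s = [summaries[(cid, clinical_source)] for cid in cases]
        b = [bimod[cid] for cid in cases]
        rows["n"][c] = len(cases)
        for cat in ("amplified", "equivocal", "negative"):
            rows[cat][c] = sum(x.amplification == cat for x in s)
        rows["polysomy"][c] = sum(x.polysomy for x in s)
        rows["gh_ratio"][c] = sum(classify_gh(x.amp_cell_pct, thr) for x in s)
        rows["gh_her2only"][c] = sum(
            classify_gh(x.amp_cell_pct_her2only, thr) for x in s
        )
        rows["ashd_ratio_gt2"][c] = sum(x.ratio.ashman_d > ashman_threshold for x in b)
        rows["ashd_her2_gt2"][c] = sum(x.her2.ashman_d > ashman_threshold for x in b)
        rows["ashd_cep17_gt2"][c] = sum(x.cep17.ashman_d > ashman_threshold for x in b)
    df = pd.DataFrame(rows).T
    df.columns = [f"cluster{c}" if c != "Total" else "Total" for c in df.columns]
    return df
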