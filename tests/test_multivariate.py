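import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fishhet.errors import InsufficientDataError, SingularFitError
from fishhet.guidelines import CaseSummary
from fishhet.bimodality import BimodalityResult, VariableBimodality
from fishhet.multivariate import (
    FEATURE_COLUMNS,
    build_feature_matrix,
    cluster_cases,
    fit_factors,
    summarize_clusters,
    varimax,
)
from fishhet.pipeline import cohort_indicators
from fishhet.synthetic_cohort import (
    DetectionConfig,
    FOUR_GROUP_MIX,
    archetype_config,
    generate_cohort,
)


def summary_of(cid, src, amp=5.0, her2=2.5, cep17=2.5, ratio=1.0, amph=2.0):
    return CaseSummary(
        case_id=cid, source=src, n_cells=100, mean_her2=her2, mean_cep17=cep17,
        ratio=ratio, amp_cell_pct=amp, amp_cell_pct_her2only=amph,
        amplification="negative", polysomy=cep17 >= 3, gh_ratio=5 < amp < 50,
        gh_her2only=5 < amph < 50,
    )


def bimod_of(cid, dh=1.0, dc=1.0, dr=1.0):
    def v(d):
        return VariableBimodality(ashman_d=d, bindex=d / 2, bimodal=d > 2)

    return BimodalityResult(case_id=cid, source="AD", her2=v(dh), cep17=v(dc), ratio=v(dr))


def random_inputs(n=12, seed=0):
    rng = np.random.default_rng(seed)
    summaries, bimod = {}, {}
    for i in range(n):
        cid = f"C{i}"
        for src in ("AD", "MP"):
            summaries[(cid, src)] = summary_of(
                cid, src, amp=rng.uniform(0, 60), her2=rng.uniform(2, 10),
                cep17=rng.uniform(2, 4), ratio=rng.uniform(0.8, 5), amph=rng.uniform(0, 40),
            )
        bimod[cid] = bimod_of(cid, *rng.uniform(0.5, 4, 3))
    return summaries, bimod


def test_feature_matrix_shape_and_standardization():
    summaries, bimod = random_inputs(20)
    fm = build_feature_matrix(summaries, bimod)
    assert fm.values.shape == (20, 14)
    assert list(fm.values.columns) == list(FEATURE_COLUMNS)
    assert np.allclose(fm.values.mean(), 0.0, atol=1e-12)
    assert np.allclose(fm.values.std(ddof=1), 1.0, atol=1e-12)


def test_feature_matrix_missing_source_named():
    summaries, bimod = random_inputs(5)
    del summaries[("C3", "MP")]
    with pytest.raises(InsufficientDataError, match="C3"):
        build_feature_matrix(summaries, bimod)


def test_feature_matrix_zero_variance_column():
    summaries, bimod = random_inputs(8)
    for cid in {c for c, _ in summaries}:
        bimod[cid] = bimod_of(cid, dh=2.0, dc=1.0, dr=1.0)  # AshD_HER2 constant
    with pytest.raises(SingularFitError, match="AshD_HER2"):
        build_feature_matrix(summaries, bimod)


def test_varimax_preserves_communalities():
    rng = np.random.default_rng(1)
    L = rng.normal(size=(10, 3))
    R = varimax(L)
    assert np.allclose((L**2).sum(axis=1), (R**2).sum(axis=1))


def test_factor_scores_invariant_to_case_order():
    summaries, bimod = random_inputs(15, seed=3)
    fm = build_feature_matrix(summaries, bimod)
    model = fit_factors(fm)
    # reversed assembly order: dict insertion order differs, index identical
    rev_summaries = dict(reversed(list(summaries.items())))
    model2 = fit_factors(build_feature_matrix(rev_summaries, bimod))
    assert np.allclose(model.scores.values, model2.scores.loc[model.scores.index].values)


def test_sign_flip_leaves_labels_and_clusters_unchanged():
    summaries, bimod = random_inputs(16, seed=4)
    model = fit_factors(build_feature_matrix(summaries, bimod))
    flipped = model.scores.copy()
    flipped.iloc[:, 2] = -flipped.iloc[:, 2]
    a = cluster_cases(model.scores, k=3, seed=0)
    b = cluster_cases(flipped, k=3, seed=0)
    assert adjusted_rand_score(a.assignments.values, b.assignments.values) == pytest.approx(1.0)


def test_cluster_recovers_separated_blobs():
    rng = np.random.default_rng(2)
    centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]], dtype=float)
    labels = np.repeat(np.arange(4), 15)
    X = centers[labels] + rng.normal(0, 0.5, (60, 3))
    scores = pd.DataFrame(X, index=[f"c{i}" for i in range(60)])
    cr = cluster_cases(scores, k=4, seed=0)
    assert adjusted_rand_score(labels, cr.assignments.values) >= 0.9


def test_cluster_k1_and_too_few_distinct_points():
    scores = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
    cr = cluster_cases(scores, k=1, seed=0)
    assert set(cr.assignments) == {1}
    assert np.allclose(cr.centroids[0], scores.mean().values)
    dup = pd.DataFrame(np.ones((6, 3)))
    with pytest.raises(InsufficientDataError):
        cluster_cases(dup, k=2, seed=0)


def test_cluster_summary_conserves_totals():
    summaries, bimod = random_inputs(10, seed=6)
    model = fit_factors(build_feature_matrix(summaries, bimod))
    cr = cluster_cases(model.scores, k=3, seed=0)
    table = summarize_clusters(cr, summaries, bimod)
    cluster_cols = [c for c in table.columns if c != "Total"]
    assert (table[cluster_cols].sum(axis=1) == table["Total"]).all()
    assert table.loc["n", "Total"] == 10


def build_archetype_cohort(seed=0, n_cells=1000):
    configs = []
    i = 0
    for name, cnt in FOUR_GROUP_MIX:
        for _ in range(cnt):
            i += 1
            configs.append((archetype_config(name, f"C{i:02d}", n_cells=n_cells), name))
    cohort = generate_cohort(configs, DetectionConfig(), seed=seed)
    return cohort


def test_end_to_end_factor_labels_and_cluster_recovery():
    """Archetype cohort: auto-labelled factors align with their variable blocks
    and 4-means on the scores recovers the planted case groups."""
    cohort = build_archetype_cohort(seed=0)
    summaries, bimod = cohort_indicators(cohort.case_sets)
    fm = build_feature_matrix(
        {k: v for k, v in summaries.items() if k[1] in ("AD", "MP")}, bimod
    )
    model = fit_factors(fm)
    assert set(model.labels.values()) == {"amplification", "polysomy", "bimodality"}
    amp_factor = next(f for f, l in model.labels.items() if l == "amplification")
    assert model.label_evidence.loc[amp_factor, "amplification"] >= 0.6

    cr = cluster_cases(model.scores, k=4, seed=0)
    truth = dict(zip(cohort.truth_labels.case_id, cohort.truth_labels.archetype))
    labels = [truth[c] for c in cr.assignments.index]
    assert adjusted_rand_score(labels, cr.assignments.values) >= 0.7

    # bimodality cross-cuts: HER2-bimodal cases occur in more than one cluster
    bimodal_cases = [cid for cid, b in bimod.items() if b.her2.bimodal]
    assert len({cr.assignments[c] for c in bimodal_cases}) >= 2


def test_factor_blocks_agree_with_sklearn_factor_analysis():
    """Planted 3-block loading structure is recovered identically (per-variable
    dominant factor) by our PCA+varimax and sklearn's ML factor analysis."""
    from sklearn.decomposition import FactorAnalysis

    rng = np.random.default_rng(12)
    n = 200
    F = rng.normal(size=(n, 3))
    L = np.zeros((14, 3))
    for j, rows in enumerate((range(0, 8), range(8, 11), range(11, 14))):
        for r in rows:
            L[r, j] = rng.uniform(0.7, 0.95)
    X = F @ L.T + rng.normal(0, 0.4, (n, 14))
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS),
                      index=[f"c{i}" for i in range(n)])
    from fishhet.multivariate import FeatureMatrix

    fm = FeatureMatrix(values=(df - df.mean()) / df.std(ddof=1),
                       means=df.mean(), sds=df.std(ddof=1))
    ours = fit_factors(fm).loadings.to_numpy()
    sk = FactorAnalysis(n_components=3, rotation="varimax", random_state=0).fit(
        fm.values.to_numpy()
    ).components_.T
    assigned_ours = np.abs(ours).argmax(axis=1)
    assigned_sk = np.abs(sk).argmax(axis=1)
    # same partition of variables into factors, up to factor permutation
    for block in (range(0, 8), range(8, 11), range(11, 14)):
        assert len({assigned_ours[r] for r in block}) == 1
        assert len({assigned_sk[r] for r in block}) == 1
    planted = np.repeat([0, 1, 2], [8, 3, 3])
    from sklearn.metrics import adjusted_rand_score as ari

    assert ari(planted, assigned_ours) == 1.0
    assert ari(planted, assigned_sk) == 1.0
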