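import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lymtrace.dapc import (
    DAPC,
    AlleleEncoder,
    find_clusters,
    hierarchical_dapc,
    redistribute_membership,
    xval_pc_retention,
)
from lymtrace.simulate import (
    build_cluster_model,
    build_hierarchical_model,
    simulate_genotypes,
)

from _oracles import gaussian_posterior_brute
from conftest import build_table


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def test_encode_frequencies_and_imputation():
    t = build_table(
        {"i1": ["AB", "CC"], "i2": ["AA", "CC"], "i3": ["AA", "CC"],
         "i4": [None, "CC"]}
    )
    enc = AlleleEncoder().fit(t)
    X = enc.transform(t)
    assert enc.columns_ == [("L1", "A"), ("L1", "B"), ("L2", "C")]
    np.testing.assert_allclose(X[0, :2], [0.5, 0.5])   # heterozygote
    np.testing.assert_allclose(X[1, :2], [1.0, 0.0])   # homozygote
    # missing imputed with observed column means (A mean = 5/6, B = 1/6)
    np.testing.assert_allclose(X[3, :2], [5 / 6, 1 / 6])
    # non-missing rows sum to 1 per locus
    np.testing.assert_allclose(X[:3, :2].sum(axis=1), 1.0)


def test_encode_haploid_as_indicator():
    t = build_table({"i1": [("X",)], "i2": [("Y",)]}, ploidy=[1])
    X = AlleleEncoder().fit(t).transform(t)
    np.testing.assert_allclose(X, [[1, 0], [0, 1]])


def test_encode_rejects_fully_missing_individual():
    t = build_table({"i1": ["AB"], "i2": [None]})
    with pytest.raises(ValueError, match="missing at all loci"):
        AlleleEncoder().fit(t)


def test_new_data_drops_unseen_alleles_and_uses_training_means():
    train = build_table({"i1": ["AB"], "i2": ["AA"]})
    enc = AlleleEncoder().fit(train)
    query = build_table({"q1": ["AC"], "q2": ["CC"]})
    X = enc.transform(query)
    np.testing.assert_allclose(X[0], [0.5, 0.0])  # C dropped
    np.testing.assert_allclose(X[1], [0.0, 0.0])


# ---------------------------------------------------------------------------
# Cluster search
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["kmeans", "ward"])
def test_two_differentiated_clusters_select_k2(method):
    m = build_cluster_model(40, 6, [0.25, 0.25], seed=1)
    t = simulate_genotypes(m, [30, 30], seed=2)
    X = AlleleEncoder().fit(t).transform(t)
    res = find_clusters(X, k_range=range(1, 7), method=method, n_pcs=20, seed=0)
    assert res.best_k == 2
    # the K=2 labels separate the true populations
    lab = res.labels[2]
    assert len(set(lab[:30])) == 1 and len(set(lab[30:])) == 1


def test_identical_rows_select_k1_with_sentinel():
    X = np.ones((10, 4))
    res = find_clusters(X, k_range=range(1, 4), n_pcs=3, seed=0)
    assert res.bic[1] == -np.inf and res.best_k == 1


def test_k_equal_n_excluded_and_k_above_n_rejected():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(5, 3))
    res = find_clusters(X, k_range=range(1, 6), n_pcs=3, seed=0)
    assert np.isnan(res.bic[5])                 # WSS = 0 at K = n
    with pytest.raises(ValueError):
        find_clusters(X, k_range=range(1, 7), n_pcs=3, seed=0)


# ---------------------------------------------------------------------------
# PC-retention cross-validation
# ---------------------------------------------------------------------------

def test_xval_selects_few_pcs_for_separable_groups():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 1, (25, 40)), rng.normal(8, 1, (25, 40))])
    y = np.array(["a"] * 25 + ["b"] * 25)
    best, curve = xval_pc_retention(X, y, start_pcs=300, reps=5, seed=0)
    assert curve["accuracy"].max() == 1.0
    assert best <= int(curve.loc[curve["accuracy"].idxmax(), "n_pcs"])


def test_xval_random_labels_near_chance():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 30))
    y = np.array(["a", "b"] * 30)
    _, curve = xval_pc_retention(X, y, start_pcs=300, reps=8, seed=0)
    assert curve["accuracy"].mean() == pytest.approx(0.5, abs=0.15)


def test_xval_requires_two_members_per_group():
    X = np.eye(4)
    with pytest.raises(ValueError, match="at least 2"):
        xval_pc_retention(X, np.array(["a", "a", "a", "b"]), reps=2)


# ---------------------------------------------------------------------------
# Fit / posterior
# ---------------------------------------------------------------------------

def test_identical_point_groups_get_confident_posteriors():
    X = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
    y = np.array(["a"] * 5 + ["b"] * 5)
    model = DAPC(n_pcs=2).fit(X, y)
    probs = model.predict_proba(X)
    assert probs[:5, 0].min() > 0.99 and probs[5:, 1].min() > 0.99


def test_posterior_invariant_to_individual_order():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 8))
    y = rng.choice(["a", "b", "c"], 30)
    m1 = DAPC(n_pcs=5).fit(X, y)
    perm = rng.permutation(30)
    m2 = DAPC(n_pcs=5).fit(X[perm], y[perm])
    np.testing.assert_allclose(
        m1.predict_proba(X), m2.predict_proba(X), atol=1e-8
    )


def test_single_column_matrix_fits_one_axis():
    X = np.array([[0.0], [0.1], [1.0], [1.1]])
    y = np.array(["a", "a", "b", "b"])
    model = DAPC(n_pcs=1).fit(X, y)
    assert model.da_vectors_.shape == (1, 1)
    assert (model.predict(X) == y).all()


def test_posterior_matches_full_space_gaussian_oracle():
    """DA-subspace posteriors equal the independently computed full-PC-space
    Gaussian posteriors (pooled covariance, uniform priors) to 1e-8."""
    rng = np.random.default_rng(6)
    centers = {"a": [0, 0, 0, 0], "b": [3, 0, 1, 0], "c": [0, 3, -1, 1]}
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(c, 1.0, size=(7, 4)))
        y += [label] * 7
    X = np.vstack(X)
    y = np.array(y)
    Xq = rng.normal(1, 2, size=(6, 4))
    model = DAPC(n_pcs=3).fit(X, y)
    ours = model.predict_proba(Xq)
    oracle = gaussian_posterior_brute(X, y, Xq, n_pcs=3)
    np.testing.assert_allclose(ours, oracle, atol=1e-8)
    assert ours.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-9)


def test_midpoint_between_identical_cov_groups_is_half_half():
    X = np.vstack([np.zeros((4, 2)), np.ones((4, 2))]) + 1e-3 * np.arange(8)[:, None]
    y = np.array(["a"] * 4 + ["b"] * 4)
    model = DAPC(n_pcs=2).fit(X, y)
    mid = (X[:4].mean(axis=0) + X[4:].mean(axis=0)) / 2
    probs = model.predict_proba(mid[None, :])
    np.testing.assert_allclose(probs, [[0.5, 0.5]], atol=1e-6)


# ---------------------------------------------------------------------------
# Membership post-processing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "row, expected",
    [
        ((0.96, 0.03, 0.01), (1.0, 0.0, 0.0)),
        ((0.60, 0.36, 0.04), (0.625, 0.375, 0.0)),
        ((0.5, 0.5), (0.5, 0.5)),
    ],
)
def test_redistribute_worked_examples(row, expected):
    out = redistribute_membership(np.array(row))
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_redistribute_all_below_floor_becomes_indicator():
    out = redistribute_membership(np.full(30, 1 / 30))
    assert out[0] == 1.0 and out[1:].sum() == 0.0


@given(
    st.lists(st.floats(0.001, 1.0), min_size=2, max_size=8).map(
        lambda v: np.array(v) / np.sum(v)
    )
)
def test_redistribute_is_idempotent_and_normalized(row):
    once = redistribute_membership(row.copy())
    twice = redistribute_membership(once.copy())
    assert once.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(once, twice, atol=1e-12)


# ---------------------------------------------------------------------------
# Hierarchical workflow
# ---------------------------------------------------------------------------

def test_hierarchical_recovers_planted_two_level_structure():
    model, parent = build_hierarchical_model(
        2, 2, f_top=0.35, f_sub=0.12, n_loci=55, alleles_per_locus=8, seed=7
    )
    t = simulate_genotypes(model, [30, 30, 30, 30], seed=8)
    labels, detail = hierarchical_dapc(t, k_range=range(1, 7), seed=9)
    assert labels["cluster"].nunique() == 4
    # leaf clusters must match the planted truth up to label permutation
    truth = np.repeat([0, 1, 2, 3], 30)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, labels["cluster"]) > 0.95


def test_homogeneous_table_yields_single_leaf():
    m = build_cluster_model(20, 6, [0.0], seed=10)
    t = simulate_genotypes(m, [30], seed=11)
    labels, _ = hierarchical_dapc(t, k_range=range(1, 5), seed=12)
    assert labels["cluster"].nunique() == 1


def test_small_groups_pass_through_unsplit():
    m = build_cluster_model(20, 6, [0.3, 0.3], seed=13)
    t = simulate_genotypes(m, [20, 5], seed=14)
    labels, _ = hierarchical_dapc(t, k_range=range(1, 4), min_size=10, seed=15)
    sizes = labels.groupby("group").size()
    small_group = sizes.idxmin()
    assert labels[labels["group"] == small_group]["cluster"].nunique() == 1
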