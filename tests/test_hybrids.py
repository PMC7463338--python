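import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lymtrace.core import MISSING
from lymtrace.hybrids import (
    CLASSES,
    benchmark,
    build_reference,
    categorize_membership,
    classify,
    draw_gamete,
    simulate_cross,
)
from lymtrace.simulate import build_cluster_model, simulate_genotypes

from conftest import build_table


def _fixed_pool(allele: str, n: int = 6, n_loci: int = 4, prefix: str = "p"):
    calls = {f"{prefix}{k}": [allele * 2] * n_loci for k in range(n)}
    pops = {f"{prefix}{k}": prefix for k in range(n)}
    return build_table(calls, pops=pops, groups=pops)


# ---------------------------------------------------------------------------
# Gametes
# ---------------------------------------------------------------------------

def test_fixed_pool_gamete_is_deterministic():
    pool = _fixed_pool("A")
    rng = np.random.default_rng(0)
    g = draw_gamete(pool, rng, mode="frequency")
    assert all(a == "A" for a in g.values())


def test_single_heterozygote_segregates_half_half():
    pool = build_table({"h": ["AB"] * 8})
    rng = np.random.default_rng(1)
    draws = [draw_gamete(pool, rng, mode="individual") for _ in range(500)]
    for locus in pool.panel.ids:
        frac_a = np.mean([d[locus] == "A" for d in draws])
        assert 0.44 <= frac_a <= 0.56        # binomial CI


def test_frequency_gametes_match_pool_frequencies():
    m = build_cluster_model(1, 3, [0.2], seed=2)
    pool = simulate_genotypes(m, [50], seed=3)
    copies = [a for c in pool.calls[:, 0] for a in c]
    p_obs = pd.Series(copies).value_counts(normalize=True)
    rng = np.random.default_rng(4)
    draws = pd.Series(
        [draw_gamete(pool, rng, mode="frequency")["loc01"] for _ in range(10_000)]
    ).value_counts(normalize=True)
    for allele, p in p_obs.items():
        assert draws.get(allele, 0) == pytest.approx(p, abs=0.02)


def test_all_missing_locus_yields_missing_gamete():
    pool = build_table({"i1": [None, "AB"], "i2": [None, "AA"]})
    rng = np.random.default_rng(5)
    g = draw_gamete(pool, rng, mode="frequency")
    assert g["L1"] is None and g["L2"] is not None


# ---------------------------------------------------------------------------
# Crosses
# ---------------------------------------------------------------------------

def test_f1_from_fixed_parents_is_uniformly_heterozygous():
    a, b = _fixed_pool("A", prefix="a"), _fixed_pool("B", prefix="b")
    f1 = simulate_cross(a, b, n=20, class_label="F1", seed=6)
    assert all(c == ("A", "B") for c in f1.calls.ravel())


def test_f2_segregates_one_two_one():
    a, b = _fixed_pool("A", prefix="a"), _fixed_pool("B", prefix="b")
    f1 = simulate_cross(a, b, n=50, class_label="F1", seed=7)
    f2 = simulate_cross(f1, f1, n=4000, mode_a="individual",
                        mode_b="individual", class_label="F2", seed=8)
    counts = pd.Series([c for c in f2.calls[:, 0]]).value_counts(normalize=True)
    assert counts[("A", "B")] == pytest.approx(0.5, abs=0.03)
    assert counts[("A", "A")] == pytest.approx(0.25, abs=0.03)
    assert counts[("B", "B")] == pytest.approx(0.25, abs=0.03)


def test_backcross_segregates_one_to_one():
    a, b = _fixed_pool("A", prefix="a"), _fixed_pool("B", prefix="b")
    f1 = simulate_cross(a, b, n=50, class_label="F1", seed=9)
    bc = simulate_cross(f1, b, n=4000, mode_a="individual",
                        mode_b="frequency", class_label="BC", seed=10)
    counts = pd.Series([c for c in bc.calls[:, 0]]).value_counts(normalize=True)
    assert counts[("A", "B")] == pytest.approx(0.5, abs=0.03)
    assert counts[("B", "B")] == pytest.approx(0.5, abs=0.03)


def test_progeny_allele_frequency_conserved():
    """Expected progeny allele frequency = mean of the two gamete sources."""
    m = build_cluster_model(1, 2, [0.0, 0.0], seed=11)
    m.cluster_freqs[0][0][:] = [0.9, 0.1]
    m.cluster_freqs[1][0][:] = [0.1, 0.9]
    pa = simulate_genotypes(m, [100, 0], seed=12)
    pb = simulate_genotypes(m, [0, 100], pop_names=["x", "y"], seed=13)
    prog = simulate_cross(pa, pb, n=4000, class_label="pr", seed=14)
    copies = [a for c in prog.calls[:, 0] for a in c]
    frac1 = copies.count("001") / len(copies)
    pa_f = np.mean([c.count("001") for c in pa.calls[:, 0]]) / 2
    pb_f = np.mean([c.count("001") for c in pb.calls[:, 0]]) / 2
    assert frac1 == pytest.approx((pa_f + pb_f) / 2, abs=0.02)


def test_mito_block_copied_from_maternal_pool():
    calls_a = {f"a{k}": ["AA", ("X",), ("X",)] for k in range(4)}
    calls_b = {f"b{k}": ["BB", ("Y",), ("Y",)] for k in range(4)}
    a = build_table(calls_a, ploidy=[2, 1, 1])
    b = build_table(calls_b, ploidy=[2, 1, 1])
    prog_a = simulate_cross(a, b, n=30, mito_mode="maternal_a", seed=15)
    assert all(c == ("X",) for c in prog_a.calls[:, 1:].ravel())
    prog_r = simulate_cross(a, b, n=200, mito_mode="random", seed=16)
    mito = [c[0] for c in prog_r.calls[:, 1]]
    assert 0.4 <= np.mean([m == "X" for m in mito]) <= 0.6
    # linked block: both mito loci inherited from the same side
    assert all(
        (prog_r.calls[i, 1][0] == "X") == (prog_r.calls[i, 2][0] == "X")
        for i in range(200)
    )


def test_cross_argument_validation():
    a = _fixed_pool("A", prefix="a")
    with pytest.raises(ValueError):
        simulate_cross(a, a, n=0)
    with pytest.raises(ValueError):
        simulate_cross(a, a.subset(loci=a.panel.ids[:2]), n=1)


# ---------------------------------------------------------------------------
# Reference building
# ---------------------------------------------------------------------------

def test_reference_has_five_classes_and_is_reproducible():
    m = build_cluster_model(12, 6, [0.2, 0.2], seed=21)
    pools = simulate_genotypes(m, [30, 30], pop_names=["agm", "egm"], seed=22)
    agm = pools.subset(individuals=pools.individuals[:30])
    egm = pools.subset(individuals=pools.individuals[30:])
    ref = build_reference(agm, egm, n_per_class=10, seed=23)
    assert ref.class_sizes() == {c: 10 for c in CLASSES}
    ref2 = build_reference(agm, egm, n_per_class=10, seed=23)
    assert all(
        (ref.table.calls[i, j] == ref2.table.calls[i, j])
        or (ref.table.calls[i, j] is MISSING and ref2.table.calls[i, j] is MISSING)
        for i in range(ref.table.n_individuals)
        for j in range(ref.table.n_loci)
    )


def test_overlapping_parent_pools_rejected():
    a = _fixed_pool("A", n=6)
    with pytest.raises(ValueError, match="overlap"):
        build_reference(a, a, n_per_class=3, seed=0)


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

def _row(vals):
    return pd.Series(vals, index=list(CLASSES))


@pytest.mark.parametrize(
    "vals, expected",
    [
        ((0.01, 0.01, 0.08, 0.10, 0.80), "BC"),                   # ratio 8
        ((0.02, 0.02, 0.30, 0.33, 0.33), "UNDETERMINED_HYBRID"),  # rule 2
        # ratio 0.45/0.20 = 2.25 >= 2: rule 1 fires before rule 3
        ((0.45, 0.05, 0.20, 0.15, 0.15), "PURE_AGM"),
        # ratio 1.5 < 2, purebred 0.75: neither decisive nor hybrid-certain
        ((0.45, 0.30, 0.10, 0.10, 0.05), "INCONCLUSIVE"),
        ((0.90, 0.05, 0.03, 0.01, 0.01), "PURE_AGM"),
        ((0.05, 0.90, 0.03, 0.01, 0.01), "PURE_EGM"),
    ],
)
def test_hybrid_rule_ladder(vals, expected):
    res = categorize_membership(_row(vals))
    assert res["category"] == expected
    assert res["purebred_prob"] + res["hybrid_prob"] == pytest.approx(1.0)


@given(st.lists(st.floats(0.0001, 1.0), min_size=5, max_size=5))
def test_rule_ladder_partitions_the_simplex(vals):
    row = _row(np.array(vals) / np.sum(vals))
    res = categorize_membership(row)
    assert res["category"] in {
        "PURE_AGM", "PURE_EGM", "F1", "F2", "BC",
        "UNDETERMINED_HYBRID", "INCONCLUSIVE",
    }


def test_classify_end_to_end_labels_parents(hybrid_reference):
    queries = hybrid_reference.table.subset(
        individuals=hybrid_reference.table.individuals[:5]
        + hybrid_reference.table.individuals[100:105]
    )
    calls = classify(hybrid_reference, queries, seed=0)
    agm = calls.iloc[:5]["category"]
    egm = calls.iloc[5:]["category"]
    assert (agm == "PURE_AGM").mean() >= 0.8
    assert (egm == "PURE_EGM").mean() >= 0.8


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def test_fixed_opposite_parents_benchmark_geometry():
    """Fully diverged fixed parents: parent assignment is perfect and F1/F2
    remain mutually confusable (identical marginal genotype distributions at
    heterozygous-only loci)."""
    a = _fixed_pool("A", n=30, n_loci=12, prefix="a")
    b = _fixed_pool("B", n=30, n_loci=12, prefix="b")
    ref = build_reference(a, b, n_per_class=30, seed=31)
    res = benchmark(ref, reps=3, holdout=5, n_pcs=5, seed=32)
    assert res.per_class_accuracy["P_AGM"] == 1.0
    assert res.per_class_accuracy["P_EGM"] == 1.0
    assert res.f1_f2_confusion > 0.0


def test_benchmark_rejects_oversized_holdout(hybrid_reference):
    with pytest.raises(ValueError, match="too small"):
        benchmark(hybrid_reference, reps=1, holdout=100, seed=0)
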