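import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lymtrace.assign import (
    ReferencePanel,
    assign,
    decide,
    eggmass_consensus,
    montecarlo_xval,
)
from lymtrace.core import ASSIGNED, INCONCLUSIVE
from lymtrace.simulate import build_cluster_model, simulate_genotypes

from conftest import build_table


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "row, ratio, status",
    [
        ((0.6, 0.3, 0.1), 2.0, ASSIGNED),
        ((0.5, 0.4, 0.1), 1.25, INCONCLUSIVE),
        ((1.0, 0.0, 0.0), np.inf, ASSIGNED),
    ],
)
def test_relative_probability_rule(row, ratio, status):
    d = decide(np.array(row), groups=["g1", "g2", "g3"])
    assert d.relative_probability == pytest.approx(ratio)
    assert d.status == status
    assert d.best_group == "g1"


def test_exact_tie_is_inconclusive():
    d = decide(np.array([0.5, 0.5]), groups=["a", "b"])
    assert d.status == INCONCLUSIVE and d.relative_probability == 1.0


def test_decide_needs_two_groups():
    with pytest.raises(ValueError):
        decide(np.array([1.0]), groups=["only"])


@given(
    st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6),
    st.floats(0.1, 10.0),
)
def test_decide_scale_invariant_and_permutation_equivariant(vals, scale):
    row = np.array(vals) / np.sum(vals)
    d1 = decide(row)
    d2 = decide(scale * row / (scale * row).sum())
    assert d1.status == d2.status
    assert d1.relative_probability == pytest.approx(
        d2.relative_probability, rel=1e-9
    )
    perm = np.random.default_rng(0).permutation(len(row))
    d3 = decide(row[perm], groups=[str(p) for p in perm])
    assert d3.best_group == str(int(np.argmax(row))) or (
        d3.status == INCONCLUSIVE
    )


# ---------------------------------------------------------------------------
# Reference panel / assignment
# ---------------------------------------------------------------------------

def test_panel_rejects_small_or_single_groups():
    t = build_table(
        {f"i{k}": ["AB"] for k in range(6)},
        groups={f"i{k}": ("a" if k < 4 else "b") for k in range(6)},
    )
    with pytest.raises(ValueError, match="minimum size"):
        ReferencePanel(t)
    t2 = t.with_labels(group={f"i{k}": "a" for k in range(6)})
    with pytest.raises(ValueError, match="two groups"):
        ReferencePanel(t2)


@pytest.fixture(scope="module")
def fitted_panel(structured_panel_table):
    _, tab = structured_panel_table
    return ReferencePanel(tab, n_pcs=20).fit(seed=0), tab


def test_queries_assigned_to_their_source_group(structured_panel_table):
    model, tab = structured_panel_table
    panel = ReferencePanel(tab, n_pcs=20).fit(seed=0)
    queries = simulate_genotypes(
        model, [5, 5, 5, 5], pop_names=["chn", "adm", "jap", "umb"],
        id_prefix="q", seed=99,
    )
    truth = queries.pop.loc[queries.individuals]
    for engine in ("dapc", "svm"):
        dec, m = assign(panel, queries, engine=engine)
        assert np.allclose(m.values.sum(axis=1), 1.0)
        correct = (dec["best_group"] == truth).mean()
        assert correct >= 0.9
        if engine == "dapc":
            assert (dec["status"] == ASSIGNED).mean() >= 0.9


def test_engines_agree_on_decisive_assignments(structured_panel_table):
    model, tab = structured_panel_table
    panel = ReferencePanel(tab, n_pcs=20).fit(seed=0)
    queries = simulate_genotypes(
        model, [8, 8, 8, 8], pop_names=["chn", "adm", "jap", "umb"],
        id_prefix="z", seed=123,
    )
    d1, _ = assign(panel, queries, engine="dapc")
    d2, _ = assign(panel, queries, engine="svm")
    both = (d1["status"] == ASSIGNED) & (d2["status"] == ASSIGNED)
    agree = (d1.loc[both, "best_group"] == d2.loc[both, "best_group"]).mean()
    assert agree >= 0.9


def test_unrepresented_intermediate_queries_lose_decisiveness():
    """Admixed queries midway between two reference groups are markedly less
    decisively assigned than purebred queries: higher inconclusive rate and
    far lower relative probabilities (simulation-derived property)."""
    m = build_cluster_model(30, 6, [0.05, 0.05], seed=51)
    tab = simulate_genotypes(m, [30, 30], pop_names=["a", "b"], seed=52)
    tab = tab.with_labels(group=tab.pop)
    panel = ReferencePanel(tab, n_pcs=10).fit(seed=0)
    adm = np.full((20, 2), 0.5)
    qmix = simulate_genotypes(m, [20, 0], admixture=adm, id_prefix="mix",
                              seed=53)
    qpure = simulate_genotypes(m, [10, 10], id_prefix="p", seed=54)
    dmix, _ = assign(panel, qmix)
    dpure, _ = assign(panel, qpure)
    assert (dmix["status"] == INCONCLUSIVE).mean() > (
        dpure["status"] == INCONCLUSIVE
    ).mean()
    finite = dmix["relative_probability"].replace(np.inf, np.nan).dropna()
    finite_p = dpure["relative_probability"].replace(np.inf, np.nan).dropna()
    assert finite.median() < finite_p.median()


def test_empty_query_set_yields_empty_output(fitted_panel):
    panel, tab = fitted_panel
    empty = tab.subset(individuals=[])
    dec, m = assign(panel, empty)
    assert dec.empty and m.df.empty


def test_sparse_queries_flagged_unreliable(fitted_panel):
    panel, tab = fitted_panel
    q = tab.subset(individuals=tab.individuals[:1])
    calls = q.calls.copy()
    calls[0, : int(0.6 * q.n_loci)] = None     # typed at 40 % of loci
    sparse = type(q)(q.individuals, q.panel, calls, pop=q.pop, group=q.group,
                     validate=False)
    dec, _ = assign(panel, sparse)
    assert bool(dec["unreliable"].iloc[0])


# ---------------------------------------------------------------------------
# Egg-mass consensus
# ---------------------------------------------------------------------------

def _decisions(rows):
    return pd.DataFrame(
        rows, columns=["individual", "best_group", "status"]
    ).set_index("individual")


def test_eggmass_identical_congruent_conflict():
    dec = _decisions(
        [
            ("e1", "A", ASSIGNED), ("e2", "A", ASSIGNED), ("e3", "A", ASSIGNED),
            ("f1", "A", ASSIGNED), ("f2", "A", INCONCLUSIVE),
            ("g1", "adm", ASSIGNED), ("g2", "jap", ASSIGNED),
            ("g3", "jap", ASSIGNED), ("g4", "jap", ASSIGNED),
        ]
    )
    mass = {"e1": "m1", "e2": "m1", "e3": "m1",
            "f1": "m2", "f2": "m2",
            "g1": "m3", "g2": "m3", "g3": "m3", "g4": "m3"}
    out = eggmass_consensus(dec, mass)
    assert out.loc["m1", "status"] == "IDENTICAL" and out.loc["m1", "consensus"] == "A"
    assert out.loc["m2", "status"] == "CONGRUENT" and out.loc["m2", "consensus"] == "A"
    assert out.loc["m3", "status"] == "CONFLICT" and out.loc["m3", "consensus"] is None


def test_eggmass_inconclusive_pointing_elsewhere_is_conflict():
    dec = _decisions([("x1", "A", ASSIGNED), ("x2", "B", INCONCLUSIVE)])
    out = eggmass_consensus(dec, {"x1": "m", "x2": "m"})
    assert out.loc["m", "status"] == "CONFLICT"


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

def test_xval_well_separated_panel_accurate(structured_panel_table):
    _, tab = structured_panel_table
    res = montecarlo_xval(tab, scheme="leave_n", n_or_frac=5, reps=5,
                          n_pcs=20, seed=1)
    assert res.overall >= 0.95
    assert set(res.per_group.index) == {"chn", "adm", "jap", "umb"}


def test_xval_top_half_uses_30_of_60_loci():
    m = build_cluster_model(60, 6, [0.25, 0.25], seed=31)
    tab = simulate_genotypes(m, [25, 25], seed=32)
    tab = tab.with_labels(group=tab.pop)
    res = montecarlo_xval(tab, scheme="fraction", n_or_frac=0.1, reps=3,
                          loci="top_half_fst", n_pcs=15, seed=2)
    assert all(len(v) == 30 for v in res.loci_used.values())
    assert res.overall_argmax >= 0.9


def test_duplicated_group_panel_near_half_accuracy():
    """One population split under two labels cannot be told apart."""
    m = build_cluster_model(30, 6, [0.2], seed=41)
    tab = simulate_genotypes(m, [40], seed=42)
    labels = {
        ind: ("a" if k % 2 == 0 else "b")
        for k, ind in enumerate(tab.individuals)
    }
    tab = tab.with_labels(group=labels)
    res = montecarlo_xval(tab, scheme="leave_n", n_or_frac=5, reps=6,
                          n_pcs=10, seed=3)
    assert res.overall_argmax == pytest.approx(0.5, abs=0.2)


def test_xval_no_leakage_random_labels_at_chance(structured_panel_table):
    """Permuting group labels must drop held-out accuracy to chance even with
    per-replicate locus ranking (locus selection happens inside training)."""
    _, tab = structured_panel_table
    rng = np.random.default_rng(4)
    perm = rng.permutation(tab.group.loc[tab.individuals].to_numpy())
    shuffled = tab.with_labels(
        group=dict(zip(tab.individuals, perm))
    )
    res = montecarlo_xval(shuffled, scheme="leave_n", n_or_frac=5, reps=5,
                          loci="top_half_fst", n_pcs=20, seed=5)
    assert res.overall_argmax == pytest.approx(0.25, abs=0.15)


def test_xval_group_too_small_raises(structured_panel_table):
    _, tab = structured_panel_table
    with pytest.raises(ValueError, match="too small"):
        montecarlo_xval(tab, scheme="leave_n", n_or_frac=30, reps=1, seed=0)
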