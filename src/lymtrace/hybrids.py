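"""Hybrid-class simulation and classification (F1, F2, backcross detection).

Progenies are built by Mendelian gamete draws.  Gametes from a parental pool
are drawn from the pool's allele frequencies (independently per locus);
gametes from a progeny pool used as a parent (F1 x F1, F1 x parent) instead
draw one individual and segregate one of its two alleles per locus, which
preserves the inter-locus identity disequilibrium that distinguishes F2 and
backcross genomes from random-union genotypes.  Mitochondrial haploid loci
are copied as one linked block from the designated maternal pool.

Classification uses a five-class reference {pure AGM, pure EGM, F1, F2, BC}
scored by the assignment engines, with the decision ladder: a decisive
relative probability (>= 2) names the class; otherwise a specimen whose
combined purebred probability falls below 0.05 while the combined hybrid
probability exceeds 0.95 is an undetermined hybrid; anything else is
inconclusive.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable
from .assign import ASSIGNED, ReferencePanel, decide

CLASSES = ("P_AGM", "P_EGM", "F1", "F2", "BC")

PURE_AGM = "PURE_AGM"
PURE_EGM = "PURE_EGM"
UNDETERMINED_HYBRID = "UNDETERMINED_HYBRID"
INCONCLUSIVE = "INCONCLUSIVE"

_CLASS_TO_CATEGORY = {
    "P_AGM": PURE_AGM,
    "P_EGM": PURE_EGM,
    "F1": "F1",
    "F2": "F2",
    "BC": "BC",
}


@dataclasses.dataclass
class HybridReference:
    """Labelled five-class genotype pools used as classifier training data."""

    table: GenotypeTable          # group labels in CLASSES
    classes: tuple[str, ...] = CLASSES
    provenance: str = "simulated"

    def class_sizes(self) -> dict[str, int]:
        return self.table.group.value_counts().to_dict()


# ---------------------------------------------------------------------------
# Gamete draws and crosses
# ---------------------------------------------------------------------------

def _pool_freqs(pool: GenotypeTable, j: int):
    alleles: list[str] = []
    for c in pool.calls[:, j]:
        if c is not MISSING:
            alleles.extend(c)
    if not alleles:
        return None, None
    vals, counts = np.unique(alleles, return_counts=True)
    return vals, counts / counts.sum()


def draw_gamete(
    pool: GenotypeTable,
    rng: np.random.Generator,
    mode: str = "frequency",
) -> dict[str, str | None]:
    """One haploid nuclear gamete from a pool.

    ``frequency``: each locus's allele drawn independently from the pool
    allele frequencies (how parental pools contribute).  ``individual``: one
    random pool member contributes; each locus segregates one of its two
    alleles (true Mendelian segregation).  Loci with an all-missing pool, or
    missing in the drawn individual, yield a missing gamete allele.
    """
    if pool.n_individuals == 0:
        raise ValueError("empty pool")
    out: dict[str, str | None] = {}
    nuclear = [(j, loc) for j, loc in enumerate(pool.panel) if loc.ploidy == 2]
    if mode == "frequency":
        for j, loc in nuclear:
            vals, p = _pool_freqs(pool, j)
            out[loc.locus_id] = (
                None if vals is None else str(rng.choice(vals, p=p))
            )
    elif mode == "individual":
        i = int(rng.integers(pool.n_individuals))
        for j, loc in nuclear:
            c = pool.calls[i, j]
            out[loc.locus_id] = None if c is MISSING else c[int(rng.integers(2))]
    else:
        raise ValueError(f"unknown gamete mode {mode!r}")
    return out


def simulate_cross(
    pool_a: GenotypeTable,
    pool_b: GenotypeTable,
    n: int = 100,
    mode_a: str = "frequency",
    mode_b: str = "frequency",
    mito_mode: str = "random",
    class_label: str = "progeny",
    seed: int = 0,
) -> GenotypeTable:
    """Simulate ``n`` progeny: one gamete from each pool per diploid locus.

    Mitochondrial haploid loci are copied as one linked block from a random
    individual of the maternal pool (``maternal_a`` / ``maternal_b``;
    ``random`` flips a fair coin per progeny, mirroring reciprocal crosses).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pool_a.panel.ids != pool_b.panel.ids:
        raise ValueError("pools must share a panel")
    rng = np.random.default_rng(seed)
    panel = pool_a.panel
    haploid_cols = [j for j, loc in enumerate(panel) if loc.ploidy == 1]
    calls = np.empty((n, len(panel)), dtype=object)
    ids = [f"{class_label}_{i + 1:03d}" for i in range(n)]
    for i in range(n):
        ga = draw_gamete(pool_a, rng, mode=mode_a)
        gb = draw_gamete(pool_b, rng, mode=mode_b)
        for j, loc in enumerate(panel):
            if loc.ploidy != 2:
                continue
            a, b = ga[loc.locus_id], gb[loc.locus_id]
            calls[i, j] = MISSING if a is None or b is None else tuple(sorted((a, b)))
        if haploid_cols:
            if mito_mode == "maternal_a":
                mpool = pool_a
            elif mito_mode == "maternal_b":
                mpool = pool_b
            elif mito_mode == "random":
                mpool = pool_a if rng.random() < 0.5 else pool_b
            else:
                raise ValueError(f"unknown mito_mode {mito_mode!r}")
            m = int(rng.integers(mpool.n_individuals))
            for j in haploid_cols:
                calls[i, j] = mpool.calls[m, j]
    return GenotypeTable(
        ids, panel, calls,
        pop={i: class_label for i in ids},
        group={i: class_label for i in ids},
        validate=False,
    )


def build_reference(
    agm_pool: GenotypeTable,
    egm_pool: GenotypeTable,
    n_per_class: int = 100,
    seed: int = 0,
) -> HybridReference:
    """Assemble the five-class reference: sampled parents plus simulated F1
    (AGM x EGM), F2 (F1 x F1) and BC (F1 x EGM) progenies, ``n_per_class``
    each."""
    if set(agm_pool.individuals) & set(egm_pool.individuals):
        raise ValueError("parental pools overlap")
    rng = np.random.default_rng(seed)

    def sample(pool: GenotypeTable, label: str) -> GenotypeTable:
        if pool.n_individuals < n_per_class:
            raise ValueError(
                f"pool for {label} smaller than n_per_class={n_per_class}"
            )
        take = list(
            rng.choice(pool.individuals, size=n_per_class, replace=False)
        )
        sub = pool.subset(individuals=take)
        return sub.with_labels(group={i: label for i in take},
                               pop={i: label for i in take})

    agm = sample(agm_pool, "P_AGM")
    egm = sample(egm_pool, "P_EGM")
    f1 = simulate_cross(
        agm, egm, n=n_per_class, mode_a="frequency", mode_b="frequency",
        class_label="F1", seed=int(rng.integers(2**31 - 1)),
    )
    f2 = simulate_cross(
        f1, f1, n=n_per_class, mode_a="individual", mode_b="individual",
        class_label="F2", seed=int(rng.integers(2**31 - 1)),
    )
    bc = simulate_cross(
        f1, egm, n=n_per_class, mode_a="individual", mode_b="frequency",
        class_label="BC", seed=int(rng.integers(2**31 - 1)),
    )
    table = GenotypeTable.concat([agm, egm, f1, f2, bc])
    return HybridReference(table=table, provenance="simulated")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def categorize_membership(
    row: pd.Series,
    threshold: float = 2.0,
    purebred_floor: float = 0.05,
    hybrid_floor: float = 0.95,
) -> dict:
    """Apply the hybrid decision ladder to one five-class membership row."""
    d = decide(row, threshold=threshold)
    purebred = float(row.get("P_AGM", 0.0) + row.get("P_EGM", 0.0))
    hybrid = float(sum(row.get(c, 0.0) for c in ("F1", "F2", "BC")))
    if d.status == ASSIGNED:
        category = _CLASS_TO_CATEGORY[d.best_group]
    elif purebred < purebred_floor and hybrid > hybrid_floor:
        category = UNDETERMINED_HYBRID
    else:
        category = INCONCLUSIVE
    return {
        "category": category,
        "best_class": d.best_group,
        "relative_probability": d.relative_probability,
        "purebred_prob": purebred,
        "hybrid_prob": hybrid,
    }


def fit_reference(
    reference: HybridReference,
    n_pcs: int | None = 10,
    loci: str = "nuclear",
    seed: int = 0,
) -> ReferencePanel:
    table = reference.table
    if loci == "nuclear":
        table = table.nuclear()
    elif loci != "all":
        raise ValueError(f"unknown loci selection {loci!r}")
    return ReferencePanel(table, n_pcs=n_pcs).fit(seed=seed)


def classify(
    reference: HybridReference | ReferencePanel,
    queries: GenotypeTable,
    engine: str = "dapc",
    threshold: float = 2.0,
    purebred_floor: float = 0.05,
    hybrid_floor: float = 0.95,
    loci: str = "nuclear",
    n_pcs: int | None = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify specimens against the five-class reference.

    Returns one row per query: category (PURE_AGM, PURE_EGM, F1, F2, BC,
    UNDETERMINED_HYBRID or INCONCLUSIVE), the best class and its relative
    probability, and the combined purebred/hybrid probabilities.
    """
    panel = (
        reference
        if isinstance(reference, ReferencePanel)
        else fit_reference(reference, n_pcs=n_pcs, loci=loci, seed=seed)
    )
    q = queries.subset(loci=panel.table.panel.ids)
    m = panel.membership(q, engine=engine)
    rows = []
    for ind in q.individuals:
        res = categorize_membership(
            m.df.loc[ind], threshold=threshold,
            purebred_floor=purebred_floor, hybrid_floor=hybrid_floor,
        )
        res["individual"] = ind
        rows.append(res)
    return pd.DataFrame(rows).set_index("individual")


# ---------------------------------------------------------------------------
# Cross-validated benchmark
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BenchmarkResult:
    per_class_accuracy: pd.Series        # argmax accuracy per class
    per_class_decisive: pd.Series        # decisive-rule accuracy per class
    confusion: pd.DataFrame              # mean argmax confusion (rows = truth)
    f1_f2_confusion: float               # mean mutual F1<->F2 misclassification

    @property
    def parent_accuracy(self) -> float:
        return float(self.per_class_accuracy[["P_AGM", "P_EGM"]].min())

    @property
    def backcross_accuracy(self) -> float:
        return float(self.per_class_accuracy["BC"])


def benchmark(
    reference: HybridReference,
    engine: str = "dapc",
    reps: int = 20,
    holdout: int = 10,
    n_pcs: int | None = 10,
    loci: str = "nuclear",
    threshold: float = 2.0,
    seed: int = 0,
) -> BenchmarkResult:
    """Stratified Monte-Carlo cross-validation over the five classes.

    Per replicate, ``holdout`` individuals per class are withheld, the
    reference is refit on the remainder, and held-out individuals are scored.
    Reports per-class argmax accuracy (the convention of the reference
    engine's cross-validation), the decisive-rule accuracy alongside, the mean
    confusion matrix, and the mutual F1/F2 confusion rate.
    """
    table = reference.table
    if loci == "nuclear":
        table = table.nuclear()
    rng = np.random.default_rng(seed)
    groups = table.group.loc[table.individuals]
    by_class = {c: list(groups.index[groups == c]) for c in CLASSES}
    classes = [c for c in CLASSES if by_class[c]]
    conf = pd.DataFrame(0.0, index=classes, columns=classes)
    acc_rows = []
    for rep in range(reps):
        test_ids: list[str] = []
        for c in classes:
            if holdout >= len(by_class[c]):
                raise ValueError(f"class {c!r} too small for holdout {holdout}")
            test_ids.extend(rng.choice(by_class[c], size=holdout, replace=False))
        train = table.subset(
            individuals=[i for i in table.individuals if i not in set(test_ids)]
        )
        panel = ReferencePanel(train, n_pcs=n_pcs).fit(
            seed=int(rng.integers(2**31 - 1))
        )
        test = table.subset(individuals=test_ids)
        m = panel.membership(test, engine=engine)
        pred = m.df.idxmax(axis=1)
        for ind in test_ids:
            truth = groups.loc[ind]
            conf.loc[truth, pred.loc[ind]] += 1
            d = decide(m.df.loc[ind], threshold=threshold)
            acc_rows.append(
                {
                    "rep": rep,
                    "class": truth,
                    "argmax_correct": pred.loc[ind] == truth,
                    "decisive_correct": d.status == ASSIGNED
                    and d.best_group == truth,
                }
            )
    df = pd.DataFrame(acc_rows)
    per_class = df.groupby("class")["argmax_correct"].mean().reindex(classes)
    per_class_dec = df.groupby("class")["decisive_correct"].mean().reindex(classes)
    conf /= reps * holdout
    f1f2 = float(
        (conf.loc["F1", "F2"] + conf.loc["F2", "F1"]) / 2
        if "F1" in conf.index and "F2" in conf.index
        else np.nan
    )
    return BenchmarkResult(
        per_class_accuracy=per_class,
        per_class_decisive=per_class_dec,
        confusion=conf,
        f1_f2_confusion=f1f2,
    )
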