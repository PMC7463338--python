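"""Population diversity summaries, Weir-Cockerham F_ST, and an LD screen.

All statistics use nuclear (diploid) loci only; the mitochondrial loci are a
single linked block for which heterozygosity indices do not apply.  Missing
data are handled per locus by complete-case analysis (no imputation here).

F_ST follows the Weir & Cockerham (1984) variance-components estimator for
multi-allelic loci, combined across alleles and loci as the ratio of summed
components (the convention most F-statistics packages use for multilocus
estimates); negative combined estimates are reported as computed.
"""
from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable

__all__ = [
    "diversity_summary",
    "pairwise_fst",
    "per_locus_fst",
    "rank_loci_by_fst",
    "top_fst_loci",
    "ld_screen",
]


def _labels(table: GenotypeTable, by) -> pd.Series:
    if isinstance(by, str):
        s = getattr(table, "group" if by == "group" else "pop")
        if s is None:
            raise ValueError(f"table has no {by!r} labels")
    elif isinstance(by, Mapping):
        s = pd.Series({i: by.get(i) for i in table.individuals})
    else:
        s = pd.Series(by, index=table.individuals)
    if s.isna().any():
        missing = list(s.index[s.isna()])
        raise ValueError(f"individuals without population label: {missing}")
    return s


def _locus_counts(table: GenotypeTable, j: int, members: dict[str, list[int]]):
    """Per-population allele-copy counts, heterozygote-carrier counts and
    typed-individual counts at nuclear locus column j."""
    alleles = table.alleles_at(j)
    aidx = {a: k for k, a in enumerate(alleles)}
    A = len(alleles)
    pops = list(members)
    copies = np.zeros((len(pops), A))
    hets = np.zeros((len(pops), A))
    n_ind = np.zeros(len(pops))
    for pi, p in enumerate(pops):
        for r in members[p]:
            c = table.calls[r, j]
            if c is MISSING:
                continue
            n_ind[pi] += 1
            a1, a2 = c
            copies[pi, aidx[a1]] += 1
            copies[pi, aidx[a2]] += 1
            if a1 != a2:
                hets[pi, aidx[a1]] += 1
                hets[pi, aidx[a2]] += 1
    return alleles, copies, hets, n_ind


def _wc_components(copies, hets, n_ind):
    """Weir-Cockerham (1984) variance components summed over alleles at one
    locus.  Populations without typed individuals are dropped; returns
    (a, b, c) sums or None when fewer than two populations remain or the
    locus is monomorphic."""
    keep = n_ind > 0
    if keep.sum() < 2:
        return None
    copies, hets, n_ind = copies[keep], hets[keep], n_ind[keep]
    r = len(n_ind)
    nbar = n_ind.mean()
    if nbar <= 1:
        return None
    sum_n = n_ind.sum()
    nc = (sum_n - (n_ind**2).sum() / sum_n) / (r - 1)
    if nc <= 0:
        return None
    p = copies / (2 * n_ind[:, None])
    h = hets / n_ind[:, None]
    pbar = (n_ind[:, None] * p).sum(axis=0) / sum_n
    s2 = (n_ind[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_ind[:, None] * h).sum(axis=0) / sum_n
    inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
    a = nbar / nc * (s2 - inner / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if (pbar * (1 - pbar)).sum() == 0:
        return None  # monomorphic across these populations
    return float(a.sum()), float(b.sum()), float(c.sum())


# ---------------------------------------------------------------------------
# Diversity summary
# ---------------------------------------------------------------------------

def diversity_summary(
    table: GenotypeTable,
    by: str | Mapping = "pop",
    sites: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population diversity indices over nuclear loci.

    Columns: ``n_sites`` (collection sites, when a site mapping is supplied),
    ``n`` individuals, ``P`` polymorphic-locus count, ``A_N`` mean alleles per
    locus, ``P_R`` mean private alleles per locus, ``D`` average unbiased gene
    diversity over all loci, ``H_O``/``H_E`` mean observed/expected
    heterozygosity over the loci polymorphic within the population.  Gene
    diversity per locus is the unbiased ``n/(n-1) * (1 - sum p^2)`` with ``n``
    counted in gene copies.
    """
    t = table.nuclear()
    labels = _labels(t, by)
    pops = list(dict.fromkeys(labels.loc[t.individuals]))
    members = {
        p: [r for r, i in enumerate(t.individuals) if labels.loc[i] == p]
        for p in pops
    }
    for p, rows in members.items():
        if not rows:
            raise ValueError(f"population {p!r} has no individuals")

    # observed alleles per (pop, locus) for private-allele accounting
    observed: dict[str, list[set[str]]] = {p: [] for p in pops}
    for j in range(t.n_loci):
        for p in pops:
            seen = set()
            for r in members[p]:
                c = t.calls[r, j]
                if c is not MISSING:
                    seen.update(c)
            observed[p].append(seen)

    rows_out = []
    for p in pops:
        P = 0
        a_counts, privates, ho, he, d_all = [], [], [], [], []
        for j in range(t.n_loci):
            seen = observed[p][j]
            typed = [
                t.calls[r, j] for r in members[p] if t.calls[r, j] is not MISSING
            ]
            if not typed:
                continue
            a_counts.append(len(seen))
            others = set().union(
                *(observed[q][j] for q in pops if q != p)
            ) if len(pops) > 1 else set()
            privates.append(len(seen - others))
            copies = [a for c in typed for a in c]
            n = len(copies)
            freq = pd.Series(copies).value_counts(normalize=True).to_numpy()
            gd = 1 - (freq**2).sum()
            gd_unbiased = n / (n - 1) * gd if n > 1 else 0.0
            d_all.append(gd_unbiased)
            if len(seen) >= 2:
                P += 1
                he.append(gd_unbiased)
                ho.append(np.mean([c[0] != c[1] for c in typed]))
        rows_out.append(
            {
                "pop": p,
                "n_sites": (
                    len({sites[i] for i in labels.index[labels == p]})
                    if sites
                    else np.nan
                ),
                "n": len(members[p]),
                "P": P,
                "A_N": float(np.mean(a_counts)) if a_counts else np.nan,
                "P_R": float(np.mean(privates)) if privates else np.nan,
                "D": float(np.mean(d_all)) if d_all else np.nan,
                "H_O": float(np.mean(ho)) if ho else 0.0,
                "H_E": float(np.mean(he)) if he else 0.0,
            }
        )
    return pd.DataFrame(rows_out).set_index("pop")


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _fst_between(table: GenotypeTable, members: dict[str, list[int]]) -> float:
    num = den = 0.0
    any_locus = False
    for j in range(table.n_loci):
        _, copies, hets, n_ind = _locus_counts(table, j, members)
        comp = _wc_components(copies, hets, n_ind)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
        any_locus = True
    if not any_locus or den == 0:
        return np.nan
    return num / den


def pairwise_fst(table: GenotypeTable, by: str | Mapping = "group") -> pd.DataFrame:
    """Pairwise multi-allelic Weir-Cockerham F_ST between clusters, combined
    across loci as a ratio of summed variance components.  Diagonal is 0;
    pairs with no co-typed polymorphic locus come back NaN."""
    t = table.nuclear()
    labels = _labels(t, by)
    pops = list(dict.fromkeys(labels.loc[t.individuals]))
    if len(pops) < 2:
        raise ValueError("need at least two clusters")
    members = {
        p: [r for r, i in enumerate(t.individuals) if labels.loc[i] == p]
        for p in pops
    }
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for p, q in itertools.combinations(pops, 2):
        v = _fst_between(t, {p: members[p], q: members[q]})
        out.loc[p, q] = out.loc[q, p] = v
    return out


def per_locus_fst(table: GenotypeTable, by: str | Mapping = "group") -> pd.Series:
    """Multi-group Weir-Cockerham estimate per nuclear locus (NaN where
    undefined, e.g. monomorphic loci)."""
    t = table.nuclear()
    labels = _labels(t, by)
    pops = list(dict.fromkeys(labels.loc[t.individuals]))
    members = {
        p: [r for r, i in enumerate(t.individuals) if labels.loc[i] == p]
        for p in pops
    }
    vals = {}
    for j, lid in enumerate(t.panel.ids):
        _, copies, hets, n_ind = _locus_counts(t, j, members)
        comp = _wc_components(copies, hets, n_ind)
        if comp is None:
            vals[lid] = np.nan
        else:
            a, b, c = comp
            vals[lid] = a / (a + b + c) if (a + b + c) != 0 else np.nan
    return pd.Series(vals, name="fst")


def rank_loci_by_fst(table: GenotypeTable, by: str | Mapping = "group") -> pd.Series:
    """Loci ordered by descending per-locus F_ST; ties break by locus id and
    loci with undefined F_ST (monomorphic) rank last."""
    fst = per_locus_fst(table, by)
    order = sorted(
        fst.index, key=lambda l: (np.isnan(fst[l]), -(fst[l] if not np.isnan(fst[l]) else 0), l)
    )
    return fst.loc[order]


def top_fst_loci(
    table: GenotypeTable, by: str | Mapping = "group", fraction: float = 0.5
) -> list[str]:
    """The top ``fraction`` of nuclear loci by F_ST (the study's 'top half')."""
    ranked = rank_loci_by_fst(table, by)
    k = int(round(fraction * len(ranked)))
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# Linkage-disequilibrium screen
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LdResult:
    pvalues: pd.DataFrame
    skipped: list[tuple[str, str]]
    n_pairs: int
    alpha: float
    significant_fraction: float      # after Bonferroni correction
    uncorrected_fraction: float


def _g_stat(codes_a: np.ndarray, codes_b: np.ndarray, ka: int, kb: int) -> float:
    tab = np.zeros((ka, kb))
    np.add.at(tab, (codes_a, codes_b), 1)
    n = tab.sum()
    e = tab.sum(axis=1, keepdims=True) * tab.sum(axis=0, keepdims=True) / n
    mask = tab > 0
    return float(2 * (tab[mask] * np.log(tab[mask] / e[mask])).sum())


def ld_screen(
    table: GenotypeTable,
    n_perm: int = 200,
    alpha: float = 0.05,
    min_n: int = 5,
    seed: int = 0,
) -> LdResult:
    """Permutation G-test of genotypic independence for every nuclear locus
    pair.  The null is built by permuting one locus's genotypes across the
    co-typed individuals; p = (1 + #{perm >= obs}) / (n_perm + 1), exact by
    construction.  Pairs with fewer than ``min_n`` co-typed individuals are
    skipped and flagged.  The significant fraction is Bonferroni-corrected."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    t = table.nuclear()
    rng = np.random.default_rng(seed)
    ids = t.panel.ids
    # genotype codes per locus (None = missing)
    geno_codes: list[np.ndarray] = []
    n_geno: list[int] = []
    for j in range(t.n_loci):
        seen: dict[tuple, int] = {}
        col = np.full(t.n_individuals, -1)
        for r in range(t.n_individuals):
            c = t.calls[r, j]
            if c is MISSING:
                continue
            col[r] = seen.setdefault(c, len(seen))
        geno_codes.append(col)
        n_geno.append(max(len(seen), 1))
    pvals = pd.DataFrame(np.nan, index=ids, columns=ids)
    skipped = []
    sig = unc = tested = 0
    pairs = list(itertools.combinations(range(t.n_loci), 2))
    for ja, jb in pairs:
        ca, cb = geno_codes[ja], geno_codes[jb]
        ok = (ca >= 0) & (cb >= 0)
        if ok.sum() < min_n:
            skipped.append((ids[ja], ids[jb]))
            continue
        a, b = ca[ok], cb[ok]
        obs = _g_stat(a, b, n_geno[ja], n_geno[jb])
        ge = 0
        for _ in range(n_perm):
            if _g_stat(a, rng.permutation(b), n_geno[ja], n_geno[jb]) >= obs:
                ge += 1
        p = (1 + ge) / (n_perm + 1)
        pvals.loc[ids[ja], ids[jb]] = pvals.loc[ids[jb], ids[ja]] = p
        tested += 1
        if p <= alpha:
            unc += 1
        if p <= alpha / len(pairs):
            sig += 1
    return LdResult(
        pvalues=pvals,
        skipped=skipped,
        n_pairs=tested,
        alpha=alpha,
        significant_fraction=sig / tested if tested else np.nan,
        uncorrected_fraction=unc / tested if tested else np.nan,
    )
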