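"""Synthetic data generation: structured genotypes, amplicon panels, reads.

Cluster differentiation follows the Balding-Nichols model: each cluster's
allele frequencies at a locus are Dirichlet draws around the ancestral
frequencies with concentration ``p * (1 - F) / F``, so a cluster with drift
parameter ``F`` is differentiated from the ancestral pool by F_ST ~ F, and two
clusters with drifts ``F_j``, ``F_k`` show pairwise F_ST ~ (F_j + F_k) / 2.

Mitochondrial (haploid) loci are simulated as a single linked block: one
cluster-of-origin and one frequency quantile are drawn per individual and
shared across the block, which induces the complete linkage expected of a
non-recombining genome.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .core import MISSING, GenotypeTable, Locus, LocusPanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode()


def _allele_names(k: int) -> list[str]:
    return [f"{i + 1:03d}" for i in range(k)]


# ---------------------------------------------------------------------------
# Cluster model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterModel:
    """Balding-Nichols allele-frequency model for differentiated clusters."""

    allele_names: list[list[str]]          # per locus
    ancestral: list[np.ndarray]            # per locus, sums to 1
    cluster_freqs: list[list[np.ndarray]]  # [cluster][locus]
    fst: np.ndarray                        # per-cluster drift F

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_freqs)

    @property
    def n_loci(self) -> int:
        return len(self.ancestral)


def build_cluster_model(
    n_loci: int,
    alleles_per_locus: int | Sequence[int],
    fst: Sequence[float],
    seed: int = 0,
    ancestral: list[np.ndarray] | None = None,
    ancestral_alpha: float = 1.0,
) -> ClusterModel:
    """Draw ancestral frequencies (symmetric Dirichlet with concentration
    ``ancestral_alpha``; values < 1 give the skewed many-rare-alleles spectra
    typical of haplotype panels) and per-cluster drifted frequencies.  ``fst``
    gives one drift parameter per cluster; F = 0 copies the ancestral
    frequencies exactly.  Deterministic under a fixed seed."""
    fst = np.asarray(fst, dtype=float)
    if ((fst < 0) | (fst >= 1)).any():
        raise ValueError("per-cluster F must lie in [0, 1)")
    if np.isscalar(alleles_per_locus):
        alleles_per_locus = [int(alleles_per_locus)] * n_loci
    if any(k < 1 for k in alleles_per_locus):
        raise ValueError("alleles_per_locus must be >= 1")
    rng = np.random.default_rng(seed)
    if ancestral is None:
        ancestral = [
            rng.dirichlet(np.full(k, ancestral_alpha)) for k in alleles_per_locus
        ]
    cluster_freqs: list[list[np.ndarray]] = []
    for F in fst:
        if F == 0:
            cluster_freqs.append([p.copy() for p in ancestral])
        else:
            conc = (1.0 - F) / F
            cluster_freqs.append(
                [rng.dirichlet(np.maximum(p * conc, 1e-12)) for p in ancestral]
            )
    names = [_allele_names(len(p)) for p in ancestral]
    return ClusterModel(names, list(ancestral), cluster_freqs, fst)


def build_hierarchical_model(
    n_top: int,
    n_sub: int,
    f_top: float,
    f_sub: float,
    n_loci: int,
    alleles_per_locus: int = 8,
    seed: int = 0,
) -> tuple[ClusterModel, list[int]]:
    """Two-level drift: top-level groups drift ``f_top`` from the ancestral
    pool; each group spawns ``n_sub`` subclusters drifting ``f_sub`` from the
    group frequencies.  Returns the leaf-level model and each leaf's top-group
    index."""
    rng = np.random.default_rng(seed)
    ancestral = [rng.dirichlet(np.ones(alleles_per_locus)) for _ in range(n_loci)]
    top = [
        [rng.dirichlet(np.maximum(p * (1 - f_top) / f_top, 1e-12)) for p in ancestral]
        for _ in range(n_top)
    ]
    leaves: list[list[np.ndarray]] = []
    parent: list[int] = []
    for g in range(n_top):
        for _ in range(n_sub):
            leaves.append(
                [
                    rng.dirichlet(np.maximum(p * (1 - f_sub) / f_sub, 1e-12))
                    for p in top[g]
                ]
            )
            parent.append(g)
    names = [_allele_names(alleles_per_locus) for _ in range(n_loci)]
    model = ClusterModel(
        names, ancestral, leaves, np.full(len(leaves), f_sub)
    )
    return model, parent


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def _dummy_panel(n_loci: int, ploidy: np.ndarray) -> LocusPanel:
    return LocusPanel(
        [
            Locus(f"loc{j + 1:02d}", "N" * 40, (1, 10_000), ploidy=int(ploidy[j]))
            for j in range(n_loci)
        ]
    )


def simulate_genotypes(
    model: ClusterModel,
    sizes: Sequence[int],
    panel: LocusPanel | None = None,
    admixture: np.ndarray | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    pop_names: Sequence[str] | None = None,
    id_prefix: str | None = None,
) -> GenotypeTable:
    """Draw genotypes: each allele copy picks a source cluster (pure membership
    by default, or per-individual ``admixture`` rows over clusters) and then an
    allele from that cluster's locus frequencies.  Haploid loci (from the
    panel) form one linked block sharing a single draw per individual.  Each
    call is independently set missing with probability ``missing_rate``."""
    if not 0 <= missing_rate <= 0.25:
        raise ValueError("missing_rate must lie in [0, 0.25]")
    K, L = model.n_clusters, model.n_loci
    if len(sizes) != K and admixture is None:
        raise ValueError(f"{len(sizes)} sizes for {K} clusters")
    n = int(np.sum(sizes))
    if admixture is not None:
        admixture = np.asarray(admixture, dtype=float)
        if admixture.shape != (n, K):
            raise ValueError("admixture must be (sum(sizes), n_clusters)")
        if not np.allclose(admixture.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("admixture rows must sum to 1")
    else:
        admixture = np.zeros((n, K))
        start = 0
        for k, s in enumerate(sizes):
            admixture[start : start + s, k] = 1.0
            start += s
    if pop_names is None:
        pop_names = [f"pop{k + 1}" for k in range(len(sizes))]
    if panel is None:
        panel = _dummy_panel(L, np.full(L, 2))
    if len(panel) != L:
        raise ValueError("panel size does not match model loci")
    ploidy = panel.ploidy

    rng = np.random.default_rng(seed)
    cumQ = np.cumsum(admixture, axis=1)

    def pick_sources() -> np.ndarray:
        u = rng.random(n)
        return (u[:, None] > cumQ).sum(axis=1)

    allele_idx = np.zeros((n, L, 2), dtype=int)
    diploid_cols = [j for j in range(L) if ploidy[j] == 2]
    haploid_cols = [j for j in range(L) if ploidy[j] == 1]
    for copy in range(2):
        src = {j: pick_sources() for j in diploid_cols}
        for j in diploid_cols:
            for k in range(K):
                mask = src[j] == k
                if mask.any():
                    p = model.cluster_freqs[k][j]
                    allele_idx[mask, j, copy] = rng.choice(
                        len(p), size=int(mask.sum()), p=p
                    )
    if haploid_cols:
        # one linked block: shared source cluster and shared quantile
        src = pick_sources()
        u = rng.random(n)
        for j in haploid_cols:
            for k in range(K):
                mask = src == k
                if mask.any():
                    cum = np.cumsum(model.cluster_freqs[k][j])
                    allele_idx[mask, j, 0] = np.searchsorted(cum, u[mask])

    miss = rng.random((n, L)) < missing_rate
    calls = np.empty((n, L), dtype=object)
    for j in range(L):
        names = model.allele_names[j]
        for i in range(n):
            if miss[i, j]:
                calls[i, j] = MISSING
            elif ploidy[j] == 1:
                calls[i, j] = (names[allele_idx[i, j, 0]],)
            else:
                a, b = names[allele_idx[i, j, 0]], names[allele_idx[i, j, 1]]
                calls[i, j] = (a, b) if a <= b else (b, a)

    ids, pops = [], {}
    start = 0
    for k, s in enumerate(sizes):
        for i in range(s):
            name = (
                f"{id_prefix}{start + i + 1}"
                if id_prefix
                else f"{pop_names[k]}_{i + 1:03d}"
            )
            ids.append(name)
            pops[name] = pop_names[k]
        start += s
    return GenotypeTable(
        ids, panel, calls, pop=pops, group=dict(pops), validate=False
    )


# ---------------------------------------------------------------------------
# Panel sequences
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PanelSeqs:
    """Reference and per-allele amplicon sequences for each locus."""

    refs: dict[str, str]
    alleles: dict[str, dict[str, str]]  # locus -> allele id -> sequence
    snp_positions: dict[str, list[int]] = dataclasses.field(default_factory=dict)

    def seq_of(self, locus_id: str, allele_id: str) -> str:
        return self.alleles[locus_id][allele_id]

    def allele_of(self, locus_id: str, seq: str) -> str | None:
        for aid, s in self.alleles[locus_id].items():
            if s == seq:
                return aid
        return None


def design_panel(
    n_nuclear: int = 55,
    n_mito: int = 5,
    length_window: tuple[int, int] = (350, 425),
    seed: int = 0,
) -> LocusPanel:
    """Random panel with study-like geometry: amplicons in the 350-425 bp
    window, 55 diploid nuclear + 5 haploid mitochondrial loci by default."""
    rng = np.random.default_rng(seed)
    loci = []
    for j in range(n_nuclear + n_mito):
        anchor = _BASES[rng.integers(0, 4, 40)].tobytes().decode()
        ploidy = 2 if j < n_nuclear else 1
        prefix = "nuc" if ploidy == 2 else "mt"
        idx = j + 1 if ploidy == 2 else j - n_nuclear + 1
        loci.append(Locus(f"{prefix}{idx:02d}", anchor, length_window, ploidy=ploidy))
    return LocusPanel(loci)


def make_panel_seqs(
    panel: LocusPanel,
    alleles_per_locus: int | Sequence[int] = 12,
    snp_median: int = 42,
    snp_log_sigma: float = 0.47,
    snps_in_anchor: bool = False,
    seed: int = 0,
) -> PanelSeqs:
    """Generate per-locus reference and allele sequences.

    SNP counts per locus follow a rounded lognormal with the given median
    (sigma 0.47 puts the quartiles near 30 and 57).  SNPs are placed outside
    the 40-bp anchor by default so anchoring is genotype-independent; set
    ``snps_in_anchor`` to stress-test the 90 % anchor rule.  All allele
    sequences of a locus share its length and are pairwise distinct.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(alleles_per_locus):
        alleles_per_locus = [int(alleles_per_locus)] * len(panel)
    refs: dict[str, str] = {}
    alleles: dict[str, dict[str, str]] = {}
    snp_positions: dict[str, list[int]] = {}
    for loc, n_alleles in zip(panel, alleles_per_locus):
        lo, hi = loc.length_window
        length = int(rng.integers(lo, hi + 1))
        ref = np.empty(length, dtype=np.uint8)
        anchor = np.frombuffer(loc.anchor.encode(), dtype=np.uint8)
        if (anchor == ord("N")).any():
            anchor = _BASES[rng.integers(0, 4, 40)]
        ref[:40] = anchor
        ref[40:] = _BASES[rng.integers(0, 4, length - 40)]
        first = 0 if snps_in_anchor else 40
        max_snps = length - first
        n_snps = int(np.clip(round(np.exp(rng.normal(np.log(snp_median), snp_log_sigma))), 1, max_snps - 1))
        if n_alleles > 4 ** n_snps:
            raise ValueError(
                f"locus {loc.locus_id!r}: {n_alleles} alleles require more than "
                f"4^{n_snps} haplotypes"
            )
        pos = rng.choice(np.arange(first, length), size=n_snps, replace=False)
        seen: set[bytes] = set()
        out: dict[str, str] = {}
        for aid in _allele_names(n_alleles):
            while True:
                var = ref.copy()
                var[pos] = _BASES[rng.integers(0, 4, n_snps)]
                key = var.tobytes()
                if key not in seen:
                    seen.add(key)
                    out[aid] = key.decode()
                    break
        refs[loc.locus_id] = ref.tobytes().decode()
        alleles[loc.locus_id] = out
        snp_positions[loc.locus_id] = sorted(int(p) for p in pos)
    return PanelSeqs(refs, alleles, snp_positions)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _phred_char(error: float) -> str:
    q = 40 if error <= 0 else int(np.clip(round(-10 * np.log10(error)), 2, 40))
    return chr(33 + q)


def _mutate(codes: np.ndarray, error: float, rng) -> np.ndarray:
    """Independent substitution errors on a (n_reads, read_len) base-code
    matrix; an error replaces the base with one of the three others."""
    if error <= 0:
        return codes
    k = rng.binomial(codes.size, error)
    if k == 0:
        return codes
    flat = rng.choice(codes.size, size=k, replace=False)
    shift = rng.integers(1, 4, size=k).astype(np.uint8)
    codes = codes.copy()
    codes.flat[flat] = (codes.flat[flat] + shift) % 4
    return codes


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i


def _to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_reads(
    table: GenotypeTable,
    seqs: PanelSeqs,
    mean_depth: float = 50.0,
    base_error: float = 0.002,
    junk_fraction: float = 0.0,
    read_len: int = 300,
    strand_flip: float = 0.5,
    seed: int = 0,
) -> dict[str, list[tuple[str, str, str, str, str]]]:
    """Simulate paired amplicon reads per individual.

    Per (individual, locus): Poisson(``mean_depth``) read pairs, each drawn
    from one of the individual's allele sequences (fair coin for diploid
    heterozygotes); the forward read covers the 5' end and the reverse read the
    3' end, overlapping across the amplicon.  Substitution errors are applied
    independently per read at ``base_error``; Phred characters encode that
    rate.  ``junk_fraction`` extra pairs per individual are drawn from random
    templates (they merge but match no anchor).  Pairs are strand-flipped with
    probability ``strand_flip``.
    """
    if not 0 <= base_error <= 0.05:
        raise ValueError("base_error must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    qc = _phred_char(base_error)
    out: dict[str, list] = {}
    loci = table.panel.loci
    for i, ind in enumerate(table.individuals):
        pairs: list[tuple[str, str, str, str, str]] = []
        serial = 0
        for j, loc in enumerate(loci):
            call = table.calls[i, j]
            if call is MISSING:
                continue
            depth = rng.poisson(mean_depth)
            if depth == 0:
                continue
            hap_ids = list(call)
            counts = (
                rng.multinomial(depth, [1 / len(hap_ids)] * len(hap_ids))
                if len(set(hap_ids)) > 1
                else [depth]
            )
            if len(set(hap_ids)) == 1:
                hap_ids = [hap_ids[0]]
            for aid, n_reads in zip(dict.fromkeys(hap_ids), counts):
                if n_reads == 0:
                    continue
                tmpl = _to_codes(seqs.seq_of(loc.locus_id, aid))
                L = len(tmpl)
                r1 = np.tile(tmpl[: min(read_len, L)], (n_reads, 1))
                r2 = np.tile(tmpl[max(0, L - read_len):][::-1], (n_reads, 1))
                r2 = (3 - r2) % 4  # complement in code space
                r1 = _mutate(r1, base_error, rng)
                r2 = _mutate(r2, base_error, rng)
                flips = rng.random(n_reads) < strand_flip
                for r in range(n_reads):
                    s1, s2 = _codes_to_str(r1[r]), _codes_to_str(r2[r])
                    if flips[r]:
                        s1, s2 = s2, s1
                    serial += 1
                    pairs.append(
                        (f"{ind}:{loc.locus_id}:{serial}", s1, qc * len(s1), s2, qc * len(s2))
                    )
        n_junk = int(round(junk_fraction * len(pairs)))
        for r in range(n_junk):
            L = int(rng.integers(350, 426))
            tmpl = rng.integers(0, 4, L).astype(np.uint8)
            s1 = _codes_to_str(_mutate(np.atleast_2d(tmpl[:read_len]), base_error, rng)[0])
            rc = (3 - tmpl[max(0, L - read_len):][::-1]) % 4
            s2 = _codes_to_str(_mutate(np.atleast_2d(rc), base_error, rng)[0])
            pairs.append((f"{ind}:junk:{r + 1}", s1, qc * len(s1), s2, qc * len(s2)))
        out[ind] = pairs
    return out


def genotypes_to_sequences(table: GenotypeTable, seqs: PanelSeqs) -> GenotypeTable:
    """Translate allele ids into full haplotype sequences (for comparing a
    truth table against sequence-keyed calls from the read pipeline)."""
    calls = np.empty_like(table.calls)
    for j, loc in enumerate(table.panel):
        for i in range(table.n_individuals):
            c = table.calls[i, j]
            calls[i, j] = (
                MISSING
                if c is MISSING
                else tuple(sorted(seqs.seq_of(loc.locus_id, a) for a in c))
            )
    return GenotypeTable(
        table.individuals, table.panel, calls,
        pop=table.pop, group=table.group, eggmass=table.eggmass, validate=False,
    )


# Parental-pool emulation for the hybrid study: 55 nuclear loci; a skewed
# ancestral haplotype spectrum (Dirichlet concentration 0.3 over 24 alleles)
# and asymmetric drift - mild for the diverse Asian pool, strong for the
# founder-bottlenecked North American pool - calibrated so the realized
# pairwise Weir-Cockerham F_ST is ~0.23 and the two pools show the observed
# gene-diversity contrast (H_E ~0.78 vs ~0.5).
HYBRID_STUDY = {
    "n_loci": 55,
    "alleles_per_locus": 24,
    "fst": (0.05, 0.41),
    "ancestral_alpha": 0.3,
}


def hybrid_study_model(seed: int = 0) -> ClusterModel:
    """The two-cluster parental model behind the hybrid-detection emulation
    (see :data:`HYBRID_STUDY` for the calibrated defaults)."""
    return build_cluster_model(
        HYBRID_STUDY["n_loci"],
        HYBRID_STUDY["alleles_per_locus"],
        HYBRID_STUDY["fst"],
        ancestral_alpha=HYBRID_STUDY["ancestral_alpha"],
        seed=seed,
    )


def simulate_hybrid_study(
    model: ClusterModel,
    n_parents: int = 100,
    n_per_class: int = 100,
    panel: LocusPanel | None = None,
    seed: int = 0,
):
    """Convenience wrapper: simulate two parental pools from a 2-cluster model
    and build the five-class hybrid reference (parents, F1, F2, BC)."""
    from .hybrids import build_reference

    if model.n_clusters != 2:
        raise ValueError("hybrid study needs a 2-cluster parental model")
    pools = simulate_genotypes(
        model, [n_parents, n_parents], panel=panel,
        pop_names=["AGM", "EGM"], seed=seed,
    )
    agm = pools.subset(individuals=pools.individuals[:n_parents])
    egm = pools.subset(individuals=pools.individuals[n_parents:])
    ref = build_reference(agm, egm, n_per_class=n_per_class, seed=seed + 1)
    for cls, size in ref.class_sizes().items():
        assert size == min(n_per_class, n_parents), (cls, size)
    return ref
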