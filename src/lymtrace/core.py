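"""Core data model: locus panels, multi-allelic genotype tables, membership matrices.

The panel targets multi-SNP amplicons ("loci"); an allele is the full haplotype
sequence of one amplified locus copy, identified by an opaque string (a sequence,
a hash, or an integer code from a Genepop file).  Diploid nuclear loci carry two
alleles per individual, haploid mitochondrial loci one.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ANCHOR_LEN = 40
MISSING = None

_VALID_PLOIDY = (1, 2)


@dataclasses.dataclass(frozen=True)
class Locus:
    """One amplicon locus: id, 40-bp anchor, amplicon length window, ploidy."""

    locus_id: str
    anchor: str
    length_window: tuple[int, int]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if len(self.anchor) != ANCHOR_LEN:
            raise ValueError(
                f"locus {self.locus_id!r}: anchor must be {ANCHOR_LEN} bp, "
                f"got {len(self.anchor)}"
            )
        lo, hi = self.length_window
        if lo > hi:
            raise ValueError(f"locus {self.locus_id!r}: length window min > max")
        if self.ploidy not in _VALID_PLOIDY:
            raise ValueError(f"locus {self.locus_id!r}: ploidy must be 1 or 2")


class LocusPanel:
    """Ordered collection of loci with unique ids."""

    def __init__(self, loci: Sequence[Locus]):
        loci = list(loci)
        if not loci:
            raise ValueError("panel must contain at least one locus")
        ids = [loc.locus_id for loc in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids in panel")
        self.loci = loci
        self.ids = ids
        self.by_id = {loc.locus_id: loc for loc in loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.by_id[key]
        return self.loci[key]

    @property
    def ploidy(self) -> np.ndarray:
        return np.array([loc.ploidy for loc in self.loci], dtype=int)

    @property
    def nuclear_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci if loc.ploidy == 2]

    @property
    def haploid_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci if loc.ploidy == 1]

    def subset(self, ids: Sequence[str]) -> "LocusPanel":
        return LocusPanel([self.by_id[i] for i in ids])


def as_call(alleles: Iterable[str] | None, ploidy: int):
    """Normalize one genotype call to a sorted tuple of allele ids, or MISSING."""
    if alleles is None:
        return MISSING
    alleles = tuple(str(a) for a in alleles)
    if len(alleles) != ploidy:
        raise ValueError(f"call {alleles} does not match ploidy {ploidy}")
    return tuple(sorted(alleles))


def _as_series(mapping, individuals, name):
    if mapping is None:
        return None
    if isinstance(mapping, pd.Series):
        s = mapping.reindex(individuals)
    else:
        s = pd.Series({i: mapping.get(i) for i in individuals}, name=name)
        s = s.reindex(individuals)
    s.name = name
    return s


class GenotypeTable:
    """Individuals x loci table of multi-allelic calls.

    ``calls`` is an object array of shape (n_individuals, n_loci); each cell is
    a sorted tuple of allele-id strings of the locus's ploidy, or ``None`` for
    missing.  Optional per-individual labels: sampling population (``pop``),
    analysis cluster (``group``), and egg-mass membership (``eggmass``).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        panel: LocusPanel,
        calls: np.ndarray,
        pop: Mapping[str, str] | pd.Series | None = None,
        group: Mapping[str, str] | pd.Series | None = None,
        eggmass: Mapping[str, str] | pd.Series | None = None,
        validate: bool = True,
    ):
        individuals = [str(i) for i in individuals]
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (len(individuals), len(panel)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(individuals)}, {len(panel)})"
            )
        self.individuals = individuals
        self.panel = panel
        self.calls = calls
        self.pop = _as_series(pop, individuals, "pop")
        self.group = _as_series(group, individuals, "group")
        self.eggmass = _as_series(eggmass, individuals, "eggmass")
        if validate:
            self._validate()

    def _validate(self) -> None:
        ploidy = self.panel.ploidy
        for j, loc in enumerate(self.panel):
            for i in range(len(self.individuals)):
                c = self.calls[i, j]
                if c is MISSING:
                    continue
                if not isinstance(c, tuple) or len(c) != ploidy[j]:
                    raise ValueError(
                        f"individual {self.individuals[i]!r}, locus "
                        f"{loc.locus_id!r}: call {c!r} violates ploidy {ploidy[j]}"
                    )

    # -- basic views ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def locus_index(self, locus_id: str) -> int:
        return self.panel.ids.index(locus_id)

    def call(self, individual: str, locus_id: str):
        return self.calls[self.individuals.index(individual), self.locus_index(locus_id)]

    def alleles_at(self, j: int) -> list[str]:
        """Sorted distinct alleles observed at locus column ``j``."""
        seen: set[str] = set()
        for c in self.calls[:, j]:
            if c is not MISSING:
                seen.update(c)
        return sorted(seen)

    def missing_fraction(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        miss = np.array(
            [[c is MISSING for c in row] for row in self.calls], dtype=float
        )
        return miss.mean(axis=1) if self.n_loci else np.zeros(self.n_individuals)

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        inds = list(individuals) if individuals is not None else self.individuals
        locs = list(loci) if loci is not None else self.panel.ids
        ridx = [self.individuals.index(i) for i in inds]
        cidx = [self.panel.ids.index(l) for l in locs]
        sub = self.calls[np.ix_(ridx, cidx)]

        def pick(s):
            return None if s is None else s.loc[inds]

        return GenotypeTable(
            inds,
            self.panel.subset(locs),
            sub,
            pop=pick(self.pop),
            group=pick(self.group),
            eggmass=pick(self.eggmass),
            validate=False,
        )

    def nuclear(self) -> "GenotypeTable":
        return self.subset(loci=self.panel.nuclear_ids)

    def with_labels(
        self, pop=None, group=None, eggmass=None
    ) -> "GenotypeTable":
        return GenotypeTable(
            self.individuals,
            self.panel,
            self.calls,
            pop=pop if pop is not None else self.pop,
            group=group if group is not None else self.group,
            eggmass=eggmass if eggmass is not None else self.eggmass,
            validate=False,
        )

    @staticmethod
    def concat(tables: Sequence["GenotypeTable"]) -> "GenotypeTable":
        """Stack tables that share one panel (e.g. hybrid reference classes)."""
        if not tables:
            raise ValueError("no tables to concatenate")
        panel = tables[0].panel
        for t in tables[1:]:
            if t.panel.ids != panel.ids:
                raise ValueError("panels differ between tables")
        inds = [i for t in tables for i in t.individuals]
        calls = np.concatenate([t.calls for t in tables], axis=0)

        def cat(attr):
            parts = [getattr(t, attr) for t in tables]
            if all(p is None for p in parts):
                return None
            parts = [
                p if p is not None else pd.Series(index=t.individuals, dtype=object)
                for p, t in zip(parts, tables)
            ]
            return pd.concat(parts)

        return GenotypeTable(
            inds, panel, calls,
            pop=cat("pop"), group=cat("group"), eggmass=cat("eggmass"),
            validate=False,
        )


class MembershipMatrix:
    """Individuals x groups posterior membership probabilities (rows sum to 1)."""

    TOL = 1e-9

    def __init__(self, df: pd.DataFrame):
        vals = df.to_numpy(dtype=float)
        if vals.size and ((vals < -self.TOL).any() or (vals > 1 + self.TOL).any()):
            raise ValueError("membership entries must lie in [0, 1]")
        if vals.size and not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        self.df = df

    @property
    def individuals(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def row(self, individual: str) -> pd.Series:
        return self.df.loc[individual]


ASSIGNED = "ASSIGNED"
INCONCLUSIVE = "INCONCLUSIVE"


@dataclasses.dataclass(frozen=True)
class AssignmentDecision:
    """Outcome of the relative-probability decision rule for one specimen."""

    individual: str
    best_group: str
    relative_probability: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in (ASSIGNED, INCONCLUSIVE):
            raise ValueError(f"invalid status {self.status!r}")
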