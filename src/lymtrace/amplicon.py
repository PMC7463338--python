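"""Amplicon read processing and multi-allelic genotype calling.

Pipeline: contig pre-filters (marker discovery stage), adapter/quality
trimming and pair merging, anchor-based locus assignment (>= 90 % identity
over the first 40 bp), collapsing identical reads, calling the top two
haplotypes per locus, and specimen-level QC (mean depth >= 10X and at most 15
failed loci).

The heterozygote-acceptance rule (second haplotype needs at least
``max(min_minor_reads, minor_ratio * top count)`` reads) and the per-locus
depth floor suppress sequencing-error haplotypes at typical 50X depth; both
are configurable.
"""
from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable, LocusPanel
from .simulate import revcomp

log = logging.getLogger(__name__)

UNASSIGNED = None

MIN_READ_LEN = 225          # minimum merged read length retained
ANCHOR_MIN_MATCH = 36       # 90 % of the first 40 bp


# ---------------------------------------------------------------------------
# Contig filters (marker discovery)
# ---------------------------------------------------------------------------

def filter_contigs(
    contigs: Iterable[tuple[str, float, int]],
    min_coverage: float = 20.0,
    max_coverage: float = 10_000.0,
) -> list[str]:
    """Keep contig ids with coverage in [20X, 10,000X] and at least one
    variant site (drops low-coverage, repetitive and monomorphic contigs);
    input order preserved."""
    kept = []
    for cid, cov, n_var in contigs:
        if cov < 0:
            raise ValueError(f"contig {cid!r}: negative coverage")
        if min_coverage <= cov <= max_coverage and n_var >= 1:
            kept.append(cid)
    return kept


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MergedRead:
    sequence: str
    mean_quality: float
    source_individual: str = ""


def _quals(q: str) -> np.ndarray:
    return np.frombuffer(q.encode(), dtype=np.uint8).astype(int) - 33


def _trim_adapter(seq: str, qual: str, adapters: Sequence[str]) -> tuple[str, str]:
    cut = len(seq)
    for ad in adapters:
        pos = seq.find(ad[: max(8, min(len(ad), 12))])
        if pos != -1:
            cut = min(cut, pos)
    return seq[:cut], qual[:cut]


def _trim_quality(seq: str, qual: str, floor: int) -> tuple[str, str]:
    q = _quals(qual)
    end = len(seq)
    while end > 0 and q[end - 1] < floor:
        end -= 1
    return seq[:end], qual[:end]


def merge_pair(
    s1: str,
    q1: str,
    s2: str,
    q2: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> tuple[str, str] | None:
    """Merge a read pair via the reverse-complement overlap of the mate.

    Seeds of the mate's prefix are searched in the forward read; a candidate
    overlap is accepted when mismatches stay within ``max_mismatch_frac``.
    Where the reads disagree, the higher-quality base wins.  Returns
    (sequence, quality) or None when unmergeable.
    """
    b = revcomp(s2)
    qb = q2[::-1]
    n1, n2 = len(s1), len(b)
    if min(n1, n2) < min_overlap:
        return None
    a_arr = np.frombuffer(s1.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    seed_len = 16
    for seed_start in (0, seed_len, 2 * seed_len):
        if seed_start + seed_len > n2:
            break
        seed = b[seed_start : seed_start + seed_len]
        pos = s1.find(seed)
        while pos != -1:
            offset = pos - seed_start
            if offset >= 0:
                overlap = min(n1 - offset, n2)
                if overlap >= min_overlap:
                    mism = int(
                        (a_arr[offset : offset + overlap] != b_arr[:overlap]).sum()
                    )
                    if mism <= max_mismatch_frac * overlap:
                        qa = _quals(q1)
                        qbv = _quals(qb)
                        ov_a = a_arr[offset : offset + overlap].copy()
                        ov_qa = qa[offset : offset + overlap].copy()
                        take_b = qbv[:overlap] > ov_qa
                        ov_a[take_b] = b_arr[:overlap][take_b]
                        ov_q = np.maximum(ov_qa, qbv[:overlap])
                        seq = (
                            s1[:offset]
                            + ov_a.tobytes().decode()
                            + b[overlap:]
                        )
                        qual = (
                            q1[:offset]
                            + (ov_q + 33).astype(np.uint8).tobytes().decode()
                            + qb[overlap:]
                        )
                        return seq, qual
            pos = s1.find(seed, pos + 1)
    return None


def preprocess(
    pairs: Iterable[tuple[str, str, str, str, str]],
    adapters: Sequence[str] = (),
    quality_floor: int = 2,
    min_length: int = MIN_READ_LEN,
    source_individual: str = "",
) -> list[MergedRead]:
    """Trim adapters and low-quality 3' tails, merge overlapping pairs, and
    drop unmergeable pairs and merged reads shorter than ``min_length`` bp."""
    merged: list[MergedRead] = []
    for _name, s1, q1, s2, q2 in pairs:
        if adapters:
            s1, q1 = _trim_adapter(s1, q1, adapters)
            s2, q2 = _trim_adapter(s2, q2, adapters)
        if quality_floor > 0:
            s1, q1 = _trim_quality(s1, q1, quality_floor)
            s2, q2 = _trim_quality(s2, q2, quality_floor)
        m = merge_pair(s1, q1, s2, q2)
        if m is None:
            continue
        seq, qual = m
        if len(seq) < min_length:
            continue
        merged.append(
            MergedRead(seq, float(_quals(qual).mean()), source_individual)
        )
    return merged


def preprocess_fastq(r1_path, r2_path, **kwargs) -> list[MergedRead]:
    from .io import read_fastq_pairs

    return preprocess(read_fastq_pairs(r1_path, r2_path), **kwargs)


# ---------------------------------------------------------------------------
# Locus assignment
# ---------------------------------------------------------------------------

class AnchorIndex:
    """Precomputed anchor matrix for the 90 %-of-40-bp locus assignment rule."""

    def __init__(self, panel: LocusPanel, min_match: int = ANCHOR_MIN_MATCH):
        self.panel = panel
        self.min_match = min_match
        self._anchors = np.array(
            [np.frombuffer(loc.anchor.encode(), dtype=np.uint8) for loc in panel]
        )
        self.n_ambiguous = 0

    def assign(self, seq: str) -> tuple[str | None, str]:
        """Assign a merged read to a locus, trying both orientations.

        Returns (locus_id or None, sequence in anchor orientation).  Reads
        whose best anchor identity is below 36/40, or that tie between loci,
        are unassigned (ties are counted in ``n_ambiguous``).
        """
        if len(seq) < 40:
            return UNASSIGNED, seq
        best_locus, best_score, best_seq, tie = None, -1, seq, False
        for oriented in (seq, revcomp(seq)):
            pre = np.frombuffer(oriented[:40].encode(), dtype=np.uint8)
            scores = (self._anchors == pre).sum(axis=1)
            top = int(scores.max())
            if top > best_score:
                best_score = top
                ties = int((scores == top).sum())
                tie = ties > 1
                best_locus = self.panel.ids[int(scores.argmax())]
                best_seq = oriented
            elif top == best_score and top >= self.min_match:
                # equal best in the other orientation counts as a tie unless
                # it is the same locus
                if self.panel.ids[int(scores.argmax())] != best_locus or int(
                    (scores == top).sum()
                ) > 1:
                    tie = True
        if best_score < self.min_match:
            return UNASSIGNED, best_seq
        if tie:
            self.n_ambiguous += 1
            return UNASSIGNED, best_seq
        return best_locus, best_seq


def assign_locus(read: MergedRead | str, panel: LocusPanel) -> str | None:
    """One-shot wrapper around :class:`AnchorIndex` for a single read."""
    seq = read.sequence if isinstance(read, MergedRead) else read
    return AnchorIndex(panel).assign(seq)[0]


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CallerConfig:
    min_locus_depth: int = 6
    min_minor_reads: int = 3
    minor_ratio: float = 0.2
    min_length: int = MIN_READ_LEN
    quality_floor: int = 2


def call_genotype(
    reads_by_locus: dict[str, Counter],
    panel: LocusPanel,
    config: CallerConfig = CallerConfig(),
) -> dict[str, dict]:
    """Call one individual's genotypes from locus-assigned collapsed reads.

    Per locus: haplotypes outside the locus length window are discarded; the
    remaining depth must reach ``min_locus_depth`` or the call is MISSING; the
    top haplotype is allele 1 and the runner-up becomes allele 2 only if its
    count reaches ``max(min_minor_reads, minor_ratio * top)``.  Haploid loci
    always take the top haplotype only.  Count ties break lexicographically by
    sequence, so calls are deterministic.
    """
    rows: dict[str, dict] = {}
    for loc in panel:
        counter = reads_by_locus.get(loc.locus_id, Counter())
        lo, hi = loc.length_window
        items = [
            (seq, cnt) for seq, cnt in counter.items() if lo <= len(seq) <= hi
        ]
        items.sort(key=lambda t: (-t[1], t[0]))
        depth = sum(cnt for _, cnt in items)
        row = {"depth": depth, "top": items[:2]}
        if depth < config.min_locus_depth or not items:
            row["status"] = "MISSING"
            row["call"] = MISSING
        elif loc.ploidy == 1:
            row["status"] = "HOM"
            row["call"] = (items[0][0],)
        else:
            top_seq, top_cnt = items[0]
            if len(items) > 1:
                second_seq, second_cnt = items[1]
                need = max(config.min_minor_reads, config.minor_ratio * top_cnt)
                if second_cnt >= need:
                    row["status"] = "HET"
                    row["call"] = tuple(sorted((top_seq, second_seq)))
                else:
                    row["status"] = "HOM"
                    row["call"] = (top_seq, top_seq)
            else:
                row["status"] = "HOM"
                row["call"] = (top_seq, top_seq)
        rows[loc.locus_id] = row
    return rows


def call_individuals(
    reads_by_individual: dict[str, Iterable],
    panel: LocusPanel,
    config: CallerConfig = CallerConfig(),
    preprocessed: bool = False,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Full per-individual pipeline: preprocess (unless given MergedReads),
    assign loci, collapse, call.  Alleles are the haplotype sequences
    themselves.  Returns the pre-QC table and a per-individual report with
    mean depth and failed-locus counts."""
    index = AnchorIndex(panel)
    individuals = list(reads_by_individual)
    calls = np.empty((len(individuals), len(panel)), dtype=object)
    report_rows = []
    for i, ind in enumerate(individuals):
        data = reads_by_individual[ind]
        merged = (
            list(data)
            if preprocessed
            else preprocess(
                data,
                quality_floor=config.quality_floor,
                min_length=config.min_length,
                source_individual=ind,
            )
        )
        by_locus: dict[str, Counter] = {}
        for mr in merged:
            locus, oriented = index.assign(mr.sequence)
            if locus is not UNASSIGNED:
                by_locus.setdefault(locus, Counter())[oriented] += 1
        rows = call_genotype(by_locus, panel, config)
        depths = np.array([rows[l]["depth"] for l in panel.ids], dtype=float)
        n_failed = sum(1 for l in panel.ids if rows[l]["call"] is MISSING)
        for j, l in enumerate(panel.ids):
            calls[i, j] = rows[l]["call"]
        report_rows.append(
            {
                "individual": ind,
                "mean_depth": float(depths.mean()) if len(depths) else 0.0,
                "n_failed_loci": int(n_failed),
            }
        )
    table = GenotypeTable(individuals, panel, calls, validate=False)
    return table, pd.DataFrame(report_rows).set_index("individual")


# ---------------------------------------------------------------------------
# Specimen QC
# ---------------------------------------------------------------------------

def qc_filter(
    report: pd.DataFrame,
    table: GenotypeTable,
    min_mean_depth: float = 10.0,
    max_failed_loci: int = 15,
) -> tuple[GenotypeTable, dict]:
    """Exclude specimens with mean per-locus depth < 10X or more than 15
    failed loci (> 25 % missing on a 60-locus panel).  The boundary is strict:
    exactly 15 failed loci is retained."""
    exclusions = []
    kept = []
    for ind in table.individuals:
        mean_depth = float(report.loc[ind, "mean_depth"])
        n_failed = int(report.loc[ind, "n_failed_loci"])
        reasons = []
        if mean_depth < min_mean_depth:
            reasons.append(f"mean depth {mean_depth:.1f} < {min_mean_depth:g}X")
        if n_failed > max_failed_loci:
            reasons.append(f"{n_failed} failed loci > {max_failed_loci}")
        if reasons:
            exclusions.append({"individual": ind, "reasons": reasons})
        else:
            kept.append(ind)
    qc = {
        "n_input": table.n_individuals,
        "n_retained": len(kept),
        "excluded": exclusions,
    }
    return table.subset(individuals=kept), qc
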