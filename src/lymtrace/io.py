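"""Readers and writers: Genepop, STRUCTURE input, internal CSV tables, panel YAML.

Genepop carries no population names and no haploid dialect, so the writer embeds
two bookkeeping tokens in the free-text title line: ``pops=a,b,...`` (block
labels in file order) and ``haploid=loc1,loc2,...`` (loci stored as duplicated
homozygous diploids).  The reader honours the tokens when present and otherwise
falls back to ``pop1..popN`` and an all-diploid interpretation, which is the
behaviour expected for third-party files.
"""
from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, GenotypeTable, Locus, LocusPanel, as_call

log = logging.getLogger(__name__)


class GenepopParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _parse_genepop_token(token: str, line_no: int):
    """One genotype token -> allele pair or MISSING (2- or 3-digit codes)."""
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {line_no}: genotype token {token!r} is not 4 or 6 digits"
        )
    if not token.isdigit():
        raise GenepopParseError(f"line {line_no}: non-numeric genotype {token!r}")
    a1, a2 = token[:w], token[w:]
    miss = "0" * w
    if a1 == miss and a2 == miss:
        return MISSING
    if a1 == miss or a2 == miss:
        raise GenepopParseError(
            f"line {line_no}: half-missing genotype {token!r} not supported"
        )
    return a1, a2


def read_genepop(path) -> GenotypeTable:
    """Read a Genepop file into a GenotypeTable.

    Allele codes are preserved verbatim as allele-id strings.  POP blocks set
    the ``pop`` label.  Raises :class:`GenepopParseError` naming the offending
    line on malformed input.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    title = lines[0]
    pop_names = None
    haploid: set[str] = set()
    m = re.search(r"pops=([^;]*)", title)
    if m:
        pop_names = [p for p in m.group(1).split(",") if p]
    m = re.search(r"haploid=([^;]*)", title)
    if m:
        haploid = {h for h in m.group(1).split(",") if h}

    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    if not locus_names:
        raise GenepopParseError("no locus names before first POP")

    individuals: list[str] = []
    pops: dict[str, str] = {}
    rows: list[list] = []
    pop_idx = -1
    block_size = 0
    for line_no0 in range(i, len(lines)):
        line = lines[line_no0]
        line_no = line_no0 + 1
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            if pop_idx >= 0 and block_size == 0:
                raise GenepopParseError(f"line {line_no}: empty population block")
            pop_idx += 1
            block_size = 0
            continue
        if "," not in line:
            raise GenepopParseError(f"line {line_no}: expected 'id , genotypes'")
        ind_id, geno = line.split(",", 1)
        ind_id = ind_id.strip()
        if not ind_id:
            raise GenepopParseError(f"line {line_no}: empty individual id")
        if ind_id in pops:
            raise GenepopParseError(f"line {line_no}: duplicate individual {ind_id!r}")
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"line {line_no}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        calls = [_parse_genepop_token(t, line_no) for t in tokens]
        individuals.append(ind_id)
        if pop_names is not None and pop_idx < len(pop_names):
            pops[ind_id] = pop_names[pop_idx]
        else:
            pops[ind_id] = f"pop{pop_idx + 1}"
        rows.append(calls)
        block_size += 1
    if pop_idx >= 0 and block_size == 0:
        raise GenepopParseError("trailing empty population block")
    if not individuals:
        raise GenepopParseError("no individuals found")

    loci = []
    for name in locus_names:
        ploidy = 1 if name in haploid else 2
        loci.append(Locus(name, "N" * 40, (1, 10_000), ploidy=ploidy))
    panel = LocusPanel(loci)
    calls = np.empty((len(individuals), len(loci)), dtype=object)
    for r, row in enumerate(rows):
        for c, pair in enumerate(row):
            if pair is MISSING:
                calls[r, c] = MISSING
            elif loci[c].ploidy == 1:
                if pair[0] != pair[1]:
                    raise GenepopParseError(
                        f"haploid locus {loci[c].locus_id!r} carries two distinct "
                        f"alleles for {individuals[r]!r}"
                    )
                calls[r, c] = (pair[0],)
            else:
                calls[r, c] = tuple(sorted(pair))
    return GenotypeTable(individuals, panel, calls, pop=pops)


def _allele_codes(table: GenotypeTable, j: int) -> dict[str, str]:
    """Map locus-j alleles to 3-digit codes, preserving numeric codes <= 999."""
    alleles = table.alleles_at(j)
    if len(alleles) > 999:
        raise ValueError(
            f"locus {table.panel.ids[j]!r} has {len(alleles)} alleles; Genepop "
            "3-digit codes support at most 999 - recode the table first"
        )
    if all(a.isdigit() and 0 < int(a) <= 999 for a in alleles) and len(
        {int(a) for a in alleles}
    ) == len(alleles):
        return {a: f"{int(a):03d}" for a in alleles}
    return {a: f"{k + 1:03d}" for k, a in enumerate(alleles)}


def write_genepop(table: GenotypeTable, path, title: str = "lymtrace export") -> None:
    """Write a GenotypeTable as 3-digit Genepop.

    Haploid loci are emitted as duplicated homozygous diploids (Genepop has no
    haploid dialect for mixed panels); the convention and the population labels
    are recorded in the title line.  Output is deterministic for a fixed table.
    """
    codes = [_allele_codes(table, j) for j in range(table.n_loci)]
    pops = (
        table.pop
        if table.pop is not None
        else pd.Series({i: "pop1" for i in table.individuals})
    )
    pop_order = list(dict.fromkeys(pops.loc[table.individuals]))
    haploid = table.panel.haploid_ids
    header = f"{title}; pops={','.join(map(str, pop_order))}"
    if haploid:
        header += f"; haploid={','.join(haploid)}"
        log.warning(
            "haploid loci %s written as duplicated homozygous diploids", haploid
        )
    out = [header]
    out.extend(table.panel.ids)
    for p in pop_order:
        out.append("POP")
        block = [i for i in table.individuals if pops.loc[i] == p]
        if not block:
            raise ValueError(f"empty population block {p!r}")
        for ind in block:
            r = table.individuals.index(ind)
            toks = []
            for j, loc in enumerate(table.panel):
                c = table.calls[r, j]
                if c is MISSING:
                    toks.append("000000")
                elif loc.ploidy == 1:
                    toks.append(codes[j][c[0]] * 2)
                else:
                    toks.append(codes[j][c[0]] + codes[j][c[1]])
            out.append(f"{ind} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------

def write_structure(table: GenotypeTable, path, nuclear_only: bool = True) -> None:
    """Write STRUCTURE two-row-per-individual input (integer alleles, -9 missing).

    Haploid mitochondrial loci are dropped when ``nuclear_only`` (the Bayesian
    clustering they feed assumes unlinked markers), otherwise duplicated.
    """
    if table.n_individuals == 0:
        raise ValueError("empty table")
    t = table.nuclear() if nuclear_only else table
    codes = [
        {a: k + 1 for k, a in enumerate(t.alleles_at(j))} for j in range(t.n_loci)
    ]
    pops = t.pop
    pop_code = (
        {p: k + 1 for k, p in enumerate(dict.fromkeys(pops.loc[t.individuals]))}
        if pops is not None
        else None
    )
    lines = ["\t".join(["id", "pop"] + t.panel.ids)]
    for r, ind in enumerate(t.individuals):
        for copy in range(2):
            row = [ind, str(pop_code[pops.loc[ind]]) if pop_code else "1"]
            for j, loc in enumerate(t.panel):
                c = t.calls[r, j]
                if c is MISSING:
                    row.append("-9")
                elif loc.ploidy == 1:
                    row.append(str(codes[j][c[0]]))
                else:
                    row.append(str(codes[j][c[copy]]))
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Internal CSV table
# ---------------------------------------------------------------------------

NA = "NA"


def write_table_csv(table: GenotypeTable, path) -> None:
    """One row per individual; two columns per diploid locus (``loc.1``,
    ``loc.2``), one per haploid locus; ``NA`` = missing; UTF-8."""
    cols: dict[str, list] = {"id": list(table.individuals)}
    for label in ("pop", "group", "eggmass"):
        s = getattr(table, label)
        cols[label] = (
            [NA if pd.isna(v) else str(v) for v in s.loc[table.individuals]]
            if s is not None
            else [NA] * table.n_individuals
        )
    for j, loc in enumerate(table.panel):
        if loc.ploidy == 2:
            c1, c2 = [], []
            for r in range(table.n_individuals):
                c = table.calls[r, j]
                c1.append(NA if c is MISSING else c[0])
                c2.append(NA if c is MISSING else c[1])
            cols[f"{loc.locus_id}.1"] = c1
            cols[f"{loc.locus_id}.2"] = c2
        else:
            cols[loc.locus_id] = [
                NA if table.calls[r, j] is MISSING else table.calls[r, j][0]
                for r in range(table.n_individuals)
            ]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_table_csv(path, panel: LocusPanel | None = None) -> GenotypeTable:
    """Read the internal CSV format; locus structure inferred from headers
    unless an explicit panel is given."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta = [c for c in ("id", "pop", "group", "eggmass") if c in df.columns]
    locus_cols = [c for c in df.columns if c not in meta]
    if panel is None:
        loci: list[Locus] = []
        seen: list[str] = []
        for c in locus_cols:
            if c.endswith(".1"):
                loci.append(Locus(c[:-2], "N" * 40, (1, 10_000), ploidy=2))
                seen.append(c[:-2])
            elif c.endswith(".2"):
                if c[:-2] not in seen:
                    raise ValueError(f"column {c!r} without matching .1 column")
            else:
                loci.append(Locus(c, "N" * 40, (1, 10_000), ploidy=1))
                seen.append(c)
        panel = LocusPanel(loci)
    individuals = list(df["id"])
    calls = np.empty((len(df), len(panel)), dtype=object)
    for j, loc in enumerate(panel):
        if loc.ploidy == 2:
            a1 = df[f"{loc.locus_id}.1"].to_numpy()
            a2 = df[f"{loc.locus_id}.2"].to_numpy()
            for r in range(len(df)):
                if a1[r] == NA or a2[r] == NA:
                    if (a1[r] == NA) != (a2[r] == NA):
                        raise ValueError(
                            f"half-missing diploid call at row {r}, locus "
                            f"{loc.locus_id!r}"
                        )
                    calls[r, j] = MISSING
                else:
                    calls[r, j] = as_call((a1[r], a2[r]), 2)
        else:
            a = df[loc.locus_id].to_numpy()
            for r in range(len(df)):
                calls[r, j] = MISSING if a[r] == NA else (a[r],)

    def lab(name):
        if name not in df.columns:
            return None
        s = pd.Series(df[name].to_numpy(), index=individuals)
        s = s.mask(s == NA)
        return None if s.isna().all() else s

    return GenotypeTable(
        individuals, panel, calls,
        pop=lab("pop"), group=lab("group"), eggmass=lab("eggmass"),
    )


# ---------------------------------------------------------------------------
# Panel YAML
# ---------------------------------------------------------------------------

def write_panel_yaml(panel: LocusPanel, path) -> None:
    data = [
        {
            "locus_id": loc.locus_id,
            "anchor": loc.anchor,
            "length_min": loc.length_window[0],
            "length_max": loc.length_window[1],
            "ploidy": loc.ploidy,
        }
        for loc in panel
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_panel_yaml(path) -> LocusPanel:
    data = yaml.safe_load(Path(path).read_text())
    return LocusPanel(
        [
            Locus(
                d["locus_id"],
                d["anchor"],
                (int(d["length_min"]), int(d["length_max"])),
                ploidy=int(d.get("ploidy", 2)),
            )
            for d in data
        ]
    )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path, r2_path):
    """Yield (name, seq1, qual1, seq2, qual2) from paired FASTQ files.

    Raises on unequal record counts (mate mismatch).
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gz(r1_path) as h1, _open_maybe_gz(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError("mate FASTQ files have unequal record counts")
            yield rec1[0].split()[0], rec1[1], rec1[2], rec2[1], rec2[2]


def write_fastq_pairs(pairs, r1_path, r2_path) -> None:
    """Write (name, seq1, qual1, seq2, qual2) tuples to paired FASTQ (.gz ok)."""
    with _open_maybe_gz(r1_path, "wt") as h1, _open_maybe_gz(r2_path, "wt") as h2:
        for name, s1, q1, s2, q2 in pairs:
            h1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            h2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
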