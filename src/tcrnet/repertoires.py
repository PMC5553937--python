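"""Clonotype tables: reading, writing, aggregation and subset selection.

A clonotype is a unique CDR3 amino-acid sequence within one individual,
possibly encoded by several nucleotide variants.  Repertoires aggregate
rows of a clonotype table to the AA level; cohorts are ordered collections
of repertoires over which sharing levels are computed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string under the standard code."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


class FormatError(ValueError):
    """Raised when a clonotype table is missing required columns."""


@dataclass
class Clonotype:
    """One unique CDR3 AA sequence within an individual."""

    cdr3_aa: str
    total_count: int
    nt_variants: dict[str, int] = field(default_factory=dict)
    v_usage: dict[str, int] = field(default_factory=dict)
    j_usage: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard AA letters in {self.cdr3_aa!r}: {sorted(bad)}")
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if self.nt_variants:
            if sum(self.nt_variants.values()) != self.total_count:
                raise ValueError("nt_variant counts must sum to total_count")
            for nt in self.nt_variants:
                if translate(nt) != self.cdr3_aa:
                    raise ValueError(f"nt variant {nt} does not translate to {self.cdr3_aa}")

    @property
    def n_nt_variants(self) -> int:
        return len(self.nt_variants)

    def dominant_gene(self, which: str) -> tuple[str, float]:
        """Most-used V or J gene of this clonotype and the count fraction it explains."""
        usage = self.v_usage if which.upper() == "V" else self.j_usage
        if not usage:
            raise ValueError(f"no {which} usage data for {self.cdr3_aa}")
        total = sum(usage.values())
        gene = max(sorted(usage), key=usage.__getitem__)
        return gene, usage[gene] / total


@dataclass
class LoadReport:
    """Row-level accounting for one table read."""

    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_invalid_aa: int = 0
    n_dropped_nonpositive_count: int = 0
    dropped_rows: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return (
            f"rows={self.n_rows} loaded={self.n_loaded} "
            f"dropped_invalid_aa={self.n_dropped_invalid_aa} "
            f"dropped_nonpositive_count={self.n_dropped_nonpositive_count}"
        )


class Repertoire:
    """An individual's clonotype collection, keyed by CDR3 AA sequence."""

    def __init__(
        self,
        individual_id: str,
        clonotypes: Iterable[Clonotype] = (),
        metadata: Mapping[str, str] | None = None,
        parent_total_count: int | None = None,
    ) -> None:
        self.individual_id = individual_id
        self.metadata: dict[str, str] = dict(metadata or {})
        self.clonotypes: dict[str, Clonotype] = {}
        for c in clonotypes:
            if c.cdr3_aa in self.clonotypes:
                raise ValueError(f"duplicate clonotype {c.cdr3_aa}")
            self.clonotypes[c.cdr3_aa] = c
        # When this repertoire is a subset, frequencies are reported
        # relative to the parent's total read count.
        self.parent_total_count = parent_total_count

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __contains__(self, cdr3_aa: str) -> bool:
        return cdr3_aa in self.clonotypes

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes.values())

    def __getitem__(self, cdr3_aa: str) -> Clonotype:
        return self.clonotypes[cdr3_aa]

    @property
    def total_count(self) -> int:
        return sum(c.total_count for c in self.clonotypes.values())

    @property
    def sequences(self) -> set[str]:
        return set(self.clonotypes)

    def frequency(self, cdr3_aa: str) -> float:
        """Relative abundance of one clonotype (0 if absent).

        For subsets produced by :func:`top_n` / :func:`random_subset` the
        denominator is the parent repertoire's total count.
        """
        denom = self.parent_total_count or self.total_count
        c = self.clonotypes.get(cdr3_aa)
        return c.total_count / denom if c else 0.0

    def frequencies(self) -> dict[str, float]:
        denom = self.parent_total_count or self.total_count
        return {aa: c.total_count / denom for aa, c in self.clonotypes.items()}

    def accumulated_frequency(self) -> float:
        """Share of parent total counts carried by this (subset) repertoire."""
        denom = self.parent_total_count or self.total_count
        return sum(c.total_count for c in self.clonotypes.values()) / denom


@dataclass
class Cohort:
    """Named, ordered collection of repertoires from one species."""

    name: str
    repertoires: list[Repertoire]
    species: str = ""

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.repertoires]
        if len(ids) != len(set(ids)):
            raise ValueError("individual_id must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    @property
    def universe(self) -> set[str]:
        """All unique CDR3 AA sequences present in any member."""
        out: set[str] = set()
        for rep in self.repertoires:
            out |= rep.sequences
        return out


_TSV_COLUMNS = {"cdr3_aa": "cdr3_aa", "count": "count", "v_gene": "v_gene",
                "j_gene": "j_gene", "cdr3_nt": "cdr3_nt"}
_AIRR_COLUMNS = {"cdr3_aa": "junction_aa", "count": "duplicate_count",
                 "v_gene": "v_call", "j_gene": "j_call", "cdr3_nt": "junction"}


def read_repertoire(
    path,
    format: str = "tsv",
    individual_id: str | None = None,
    metadata: Mapping[str, str] | None = None,
) -> tuple[Repertoire, LoadReport]:
    """Read a clonotype table and aggregate rows to AA-level clonotypes.

    Two dialects are supported: ``tsv`` (columns cdr3_aa, count, v_gene,
    j_gene, optional cdr3_nt) and ``airr`` (AIRR Rearrangement fields
    junction_aa, duplicate_count, v_call, j_call, optional junction).
    Rows whose CDR3 AA is empty, contains a stop (``*``) or non-standard
    letters, or whose count is non-positive, are dropped and tallied in
    the returned :class:`LoadReport`.
    """
    if format not in ("tsv", "airr"):
        raise ValueError(f"unknown format {format!r}")
    cols = _TSV_COLUMNS if format == "tsv" else _AIRR_COLUMNS
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [cols["cdr3_aa"], cols["count"], cols["v_gene"], cols["j_gene"]]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} for format {format!r}")
    has_nt = cols["cdr3_nt"] in df.columns

    report = LoadReport(n_rows=len(df))
    agg: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        aa = rec[cols["cdr3_aa"]].strip()
        if not aa or set(aa) - AA_ALPHABET:
            report.n_dropped_invalid_aa += 1
            report.dropped_rows.append(aa)
            continue
        try:
            count = int(float(rec[cols["count"]]))
        except ValueError:
            count = 0
        if count <= 0:
            report.n_dropped_nonpositive_count += 1
            report.dropped_rows.append(aa)
            continue
        entry = agg.setdefault(aa, {"count": 0, "nt": {}, "v": {}, "j": {}})
        entry["count"] += count
        v, j = rec[cols["v_gene"]].strip(), rec[cols["j_gene"]].strip()
        if v:
            entry["v"][v] = entry["v"].get(v, 0) + count
        if j:
            entry["j"][j] = entry["j"].get(j, 0) + count
        if has_nt:
            nt = rec[cols["cdr3_nt"]].strip().upper()
            if nt:
                entry["nt"][nt] = entry["nt"].get(nt, 0) + count
        report.n_loaded += 1

    clonotypes = []
    for aa, e in agg.items():
        nt_variants = e["nt"]
        # nt rows may not cover every read if some rows lacked a junction;
        # the invariant only binds when nt data fully accounts for counts
        if nt_variants and sum(nt_variants.values()) != e["count"]:
            nt_variants = {}
        clonotypes.append(
            Clonotype(cdr3_aa=aa, total_count=e["count"], nt_variants=nt_variants,
                      v_usage=e["v"], j_usage=e["j"])
        )
    ind = individual_id if individual_id is not None else str(path)
    return Repertoire(ind, clonotypes, metadata=metadata), report


def write_repertoire(rep: Repertoire, path, format: str = "tsv") -> None:
    """Write a repertoire back to a clonotype table (one row per nt variant,
    or one row per clonotype when nt data is absent)."""
    if format not in ("tsv", "airr"):
        raise ValueError(f"unknown format {format!r}")
    cols = _TSV_COLUMNS if format == "tsv" else _AIRR_COLUMNS
    rows = []
    for c in sorted(rep.clonotypes.values(), key=lambda c: c.cdr3_aa):
        v = max(sorted(c.v_usage), key=c.v_usage.__getitem__) if c.v_usage else ""
        j = max(sorted(c.j_usage), key=c.j_usage.__getitem__) if c.j_usage else ""
        if c.nt_variants:
            for nt in sorted(c.nt_variants):
                rows.append({cols["cdr3_aa"]: c.cdr3_aa, cols["count"]: c.nt_variants[nt],
                             cols["v_gene"]: v, cols["j_gene"]: j, cols["cdr3_nt"]: nt})
        else:
            rows.append({cols["cdr3_aa"]: c.cdr3_aa, cols["count"]: c.total_count,
                         cols["v_gene"]: v, cols["j_gene"]: j, cols["cdr3_nt"]: ""})
    header = [cols["cdr3_aa"], cols["count"], cols["v_gene"], cols["j_gene"], cols["cdr3_nt"]]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_cohort(paths, name: str, species: str = "", format: str = "tsv") -> Cohort:
    """Read several clonotype tables into one cohort (one file per individual)."""
    reps = []
    for p in paths:
        rep, _ = read_repertoire(p, format=format)
        reps.append(rep)
    return Cohort(name=name, repertoires=reps, species=species)


def top_n(rep: Repertoire, n: int) -> Repertoire:
    """The n most abundant clonotypes, ties broken by AA sequence.

    Deterministic across runs: sort by (count descending, cdr3_aa ascending).
    The returned subset records the parent total count so that accumulated
    frequency is the subset's share of the parent repertoire.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(rep.clonotypes.values(), key=lambda c: (-c.total_count, c.cdr3_aa))
    return Repertoire(
        rep.individual_id,
        ordered[:n],
        metadata={**rep.metadata, "selection": f"top:{n}"},
        parent_total_count=rep.total_count,
    )


def random_subset(rep: Repertoire, n: int, seed: int) -> Repertoire:
    """Uniform sample of n unique clonotypes (not abundance-weighted)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(rep):
        raise ValueError(f"n={n} exceeds number of unique clonotypes ({len(rep)})")
    rng = random.Random(seed)
    chosen = rng.sample(sorted(rep.clonotypes), n)
    return Repertoire(
        rep.individual_id,
        [rep.clonotypes[aa] for aa in chosen],
        metadata={**rep.metadata, "selection": f"random:{n}:seed={seed}"},
        parent_total_count=rep.total_count,
    )


def random_subsets(rep: Repertoire, n: int, k: int, seed: int) -> list[Repertoire]:
    """k independent random subsets derived from one master seed."""
    ss = random.Random(seed)
    return [random_subset(rep, n, ss.randrange(2**32)) for _ in range(k)]
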