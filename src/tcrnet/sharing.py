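"""Sharing levels against reference cohorts and clonotype classification.

The sharing level of a CDR3 AA sequence is the number of individuals of a
reference cohort whose repertoire contains it (presence = at least one
read by default; a count floor is configurable).  Classification schemes
combine within-species thresholds into categories such as cross-species
(CS-) public.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats as sps

from .repertoires import Cohort, Repertoire


@dataclass
class SharingTable:
    """Per-sequence sharing levels against one reference cohort."""

    levels: dict[str, int]
    cohort_size: int
    cohort_name: str = ""

    def level(self, cdr3_aa: str) -> int:
        return self.levels.get(cdr3_aa, 0)

    def __getitem__(self, cdr3_aa: str) -> int:
        return self.level(cdr3_aa)

    def sequences_at_level(self, level: int) -> set[str]:
        return {aa for aa, s in self.levels.items() if s == level}

    def sequences_at_least(self, level: int) -> set[str]:
        return {aa for aa, s in self.levels.items() if s >= level}


def sharing_levels(
    cohort: Cohort,
    seqs: Iterable[str] | None = None,
    min_count: int = 1,
    leave_out: str | None = None,
) -> SharingTable:
    """Number of cohort individuals containing each sequence.

    With `seqs` given, only those sequences are scored (absent ones get 0);
    otherwise the whole cohort universe is scored.  `leave_out` excludes one
    individual_id from the count (leave-self-out scoring).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    reps = [r for r in cohort if r.individual_id != leave_out]
    presence: list[set[str]] = []
    for rep in reps:
        if min_count <= 1:
            presence.append(rep.sequences)
        else:
            presence.append({c.cdr3_aa for c in rep if c.total_count >= min_count})
    if seqs is None:
        levels: dict[str, int] = {}
        for pres in presence:
            for aa in pres:
                levels[aa] = levels.get(aa, 0) + 1
    else:
        levels = {aa: sum(aa in pres for pres in presence) for aa in set(seqs)}
    return SharingTable(levels=levels, cohort_size=len(reps), cohort_name=cohort.name)


@dataclass
class CategoryScheme:
    """Threshold scheme classifying sequences by two-species sharing.

    Defaults follow the reference convention: species-A public means shared
    by >= 25 of 28 individuals, species-B public means shared by all 11;
    relatively-private means shared by 0-5 of 11.
    """

    public_min_a: int = 25
    public_min_b: int = 11
    relatively_private_max: int = 5

    def validate(self, n_a: int, n_b: int) -> None:
        if self.public_min_a > n_a:
            raise ValueError(f"public_min_a={self.public_min_a} exceeds cohort size {n_a}")
        if self.public_min_b > n_b:
            raise ValueError(f"public_min_b={self.public_min_b} exceeds cohort size {n_b}")

    @classmethod
    def scaled(cls, n_a: int, n_b: int) -> "CategoryScheme":
        """Default thresholds rescaled to other cohort sizes (25/28, 11/11, 5/11)."""
        return cls(
            public_min_a=max(1, math.ceil(n_a * 25 / 28)),
            public_min_b=n_b,
            relatively_private_max=max(0, math.floor(n_b * 5 / 11)),
        )

    def category(self, s_a: int, s_b: int) -> str:
        """Four-way partition: cs_public / public_a_only / public_b_only / not_public."""
        pa, pb = s_a >= self.public_min_a, s_b >= self.public_min_b
        if pa and pb:
            return "cs_public"
        if pa:
            return "public_a_only"
        if pb:
            return "public_b_only"
        return "not_public"

    def is_relatively_private(self, s_b: int) -> bool:
        return 0 <= s_b <= self.relatively_private_max


def cs_public(
    table_a: SharingTable, table_b: SharingTable, scheme: CategoryScheme | None = None
) -> set[str]:
    """Sequences public (or nearly so) in both species."""
    scheme = scheme or CategoryScheme()
    scheme.validate(table_a.cohort_size, table_b.cohort_size)
    set_a = table_a.sequences_at_least(scheme.public_min_a)
    set_b = table_b.sequences_at_least(scheme.public_min_b)
    return set_a & set_b


@dataclass
class CrossSpeciesSharing:
    """Per-sharing-level cross-species overlap plus the global intersection."""

    fraction_by_level: dict[int, float]
    counts_by_level: dict[int, tuple[int, int]]  # level -> (shared, total)
    intersection: set[str] = field(repr=False, default_factory=set)


def cross_species_sharing(cohort_a: Cohort, cohort_b: Cohort) -> CrossSpeciesSharing:
    """For each sharing level in cohort A, the fraction of sequences found in
    at least one individual of cohort B; plus the universe intersection."""
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValueError("cohorts must be non-empty")
    table_a = sharing_levels(cohort_a)
    universe_b = cohort_b.universe
    shared: dict[int, int] = {}
    totals: dict[int, int] = {}
    for aa, s in table_a.levels.items():
        totals[s] = totals.get(s, 0) + 1
        if aa in universe_b:
            shared[s] = shared.get(s, 0) + 1
    fraction = {s: shared.get(s, 0) / totals[s] for s in totals}
    counts = {s: (shared.get(s, 0), totals[s]) for s in totals}
    return CrossSpeciesSharing(
        fraction_by_level=fraction,
        counts_by_level=counts,
        intersection=set(table_a.levels) & universe_b,
    )


def cumulative_frequency(rep: Repertoire, seqs: Iterable[str]) -> float:
    """Summed relative abundance of the given sequences within a repertoire."""
    return sum(rep.frequency(aa) for aa in set(seqs))


def frequency_by_sharing_profile(
    rep_subset: Repertoire, sharing: SharingTable
) -> dict[int, float]:
    """Partition of a subset's frequency mass by sharing level (0..N).

    Frequencies are relative to the subset's parent repertoire, so the
    profile sums to the subset's accumulated frequency.
    """
    profile = {s: 0.0 for s in range(sharing.cohort_size + 1)}
    for c in rep_subset:
        profile[sharing.level(c.cdr3_aa)] += rep_subset.frequency(c.cdr3_aa)
    return profile


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    method: str
    n: int
    defined: bool = True


def degree_sharing_correlation(
    net, sharing: SharingTable, method: str = "pearson"
) -> CorrelationResult:
    """Correlation between node degree and sharing level across network nodes."""
    nodes = sorted(net.nodes)
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes")
    deg = np.array([net.degree(n) for n in nodes], dtype=float)
    sh = np.array([sharing.level(n) for n in nodes], dtype=float)
    return _correlate(deg, sh, method)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> CorrelationResult:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), method, len(x), defined=False)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), method, len(x))


def abundance_degree_r2(net) -> float:
    """Squared Pearson correlation of log-abundance vs degree over nodes
    carrying an `abundance` attribute."""
    nodes = [n for n, d in net.nodes(data=True) if d.get("abundance")]
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes with abundance")
    logab = np.log(np.array([net.nodes[n]["abundance"] for n in nodes], dtype=float))
    deg = np.array([net.degree(n) for n in nodes], dtype=float)
    res = _correlate(logab, deg, "pearson")
    return res.r ** 2 if res.defined else float("nan")


def mean_degree_by_sharing(net, sharing: SharingTable) -> dict[int, float]:
    """Mean node degree at each sharing level present in the network."""
    sums: dict[int, list[int]] = {}
    for n in net.nodes:
        sums.setdefault(sharing.level(n), []).append(net.degree(n))
    return {s: float(np.mean(v)) for s, v in sorted(sums.items())}


def mean_betweenness_by_sharing(net, sharing: SharingTable, normalized: bool = False) -> dict[int, float]:
    from .network import betweenness

    btw = betweenness(net, normalized=normalized)
    sums: dict[int, list[float]] = {}
    for n in net.nodes:
        sums.setdefault(sharing.level(n), []).append(btw[n])
    return {s: float(np.mean(v)) for s, v in sorted(sums.items())}


def write_sharing_table(path, seqs, table_a: SharingTable, table_b: SharingTable | None = None,
                        scheme: CategoryScheme | None = None) -> None:
    """TSV export: cdr3_aa, s_a, N_a[, s_b, N_b, category]."""
    scheme = scheme or CategoryScheme()
    with open(path, "w") as fh:
        if table_b is None:
            fh.write("cdr3_aa\ts\tN\n")
            for aa in sorted(seqs):
                fh.write(f"{aa}\t{table_a.level(aa)}\t{table_a.cohort_size}\n")
        else:
            fh.write("cdr3_aa\ts_a\tN_a\ts_b\tN_b\tcategory\n")
            for aa in sorted(seqs):
                sa, sb = table_a.level(aa), table_b.level(aa)
                fh.write(f"{aa}\t{sa}\t{table_a.cohort_size}\t{sb}\t{table_b.cohort_size}\t"
                         f"{scheme.category(sa, sb)}\n")
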