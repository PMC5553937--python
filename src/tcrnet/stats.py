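"""Repertoire evenness, convergent recombination and the small tests used
throughout the analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .repertoires import Repertoire, top_n, random_subset
from .sharing import SharingTable


@dataclass
class GiniResult:
    coefficient: float
    n: int
    provenance: str = ""


def gini(abundances, provenance: str = "") -> GiniResult:
    """Gini inequality coefficient of an abundance vector.

    0 for perfectly even abundances; 1 - 1/n when a single clone carries
    all reads.  Computed from the sorted-vector identity
    G = sum_i (2i - n - 1) x_(i) / (n * sum x), equivalent to half the
    relative mean absolute difference.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("abundances must be a non-empty 1-d vector")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("at least one abundance must be positive")
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    g = float(((2 * i - n - 1) * xs).sum() / (n * total))
    return GiniResult(coefficient=g, n=n, provenance=provenance)


def repertoire_gini(rep: Repertoire, top: int | None = 1000) -> GiniResult:
    """Gini over the top-N clonotype counts (default 1000, the analysis
    convention); `top=None` uses the full repertoire."""
    sub = top_n(rep, top) if top is not None else rep
    counts = [c.total_count for c in sub]
    return gini(counts, provenance=f"{rep.individual_id}:top={top}")


@dataclass
class ConvergenceProfile:
    """Mean number of distinct nt variants per AA clonotype, by sharing level."""

    mean_nt_per_aa: dict[int, float]
    group_sizes: dict[int, int]


def convergent_recombination(rep: Repertoire, sharing: SharingTable) -> ConvergenceProfile:
    """Group AA clonotypes by sharing level; mean distinct-nt-variant count
    per group.  Requires nucleotide data on every clonotype."""
    if not any(c.nt_variants for c in rep):
        raise ValueError("repertoire carries no nucleotide variant data")
    sums: dict[int, list[int]] = {}
    for c in rep:
        if not c.nt_variants:
            continue
        sums.setdefault(sharing.level(c.cdr3_aa), []).append(len(c.nt_variants))
    return ConvergenceProfile(
        mean_nt_per_aa={s: float(np.mean(v)) for s, v in sorted(sums.items())},
        group_sizes={s: len(v) for s, v in sorted(sums.items())},
    )


def nt_variant_frequencies(rep: Repertoire, cdr3_aa: str) -> dict[str, float]:
    """Relative frequencies of the nucleotide variants encoding one AA
    clonotype (stacked-bar detail for named sequences)."""
    c = rep[cdr3_aa]
    if not c.nt_variants:
        raise ValueError(f"no nt variants recorded for {cdr3_aa}")
    return {nt: cnt / c.total_count for nt, cnt in c.nt_variants.items()}


def subsample_connectivity_curve(
    rep: Repertoire,
    sizes,
    reps: int = 10,
    seed: int = 0,
    mode: str = "top",
):
    """Clustered-node counts of distance-1 networks at several sample sizes.

    Returns a list of dict rows (size, replicate, clustered_nodes) plus a
    summary {size: (mean, se)}.  `mode="top"` is deterministic (reps
    ignored); `mode="random"` averages over seeded replicates.
    """
    from .network import build_network, clustered_node_count
    from .repertoires import random_subsets

    if mode not in ("top", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for size in sizes:
        if size > len(rep):
            raise ValueError(f"size {size} exceeds unique clonotype count {len(rep)}")
        if mode == "top":
            subsets = [top_n(rep, size)]
        else:
            subsets = random_subsets(rep, size, reps, seed)
        for i, sub in enumerate(subsets):
            net = build_network(sub.sequences)
            rows.append({"size": size, "replicate": i,
                         "clustered_nodes": clustered_node_count(net)})
    summary = {}
    for size in sizes:
        vals = np.array([r["clustered_nodes"] for r in rows if r["size"] == size], dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        summary[size] = (float(vals.mean()), se)
    return rows, summary


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (sample odds ratio ad/bc, p).  The p-value sums hypergeometric
    probabilities no larger than the observed table's (probability-mass
    two-sided rule).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


def paired_rank_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired vectors.

    Exact (sign-flip distribution of midranks) for <= 25 non-zero
    differences; normal approximation with tie correction otherwise.
    All-zero differences are undefined and raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)


def standard_error(values) -> float:
    """Sample SD / sqrt(k) across individuals."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / np.sqrt(v.size))
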