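"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (full DP
matrices, exhaustive enumeration, pairwise sums) and stays independent of
the code paths it validates.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix dynamic-programming edit distance."""
    m = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    m[:, 0] = np.arange(len(a) + 1)
    m[0, :] = np.arange(len(b) + 1)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            m[i, j] = min(
                m[i - 1, j] + 1,
                m[i, j - 1] + 1,
                m[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(m[len(a), len(b)])


def all_pairs_distance1_edges(seqs) -> set:
    """Brute-force distance-1 edge set via the DP matrix (small sets)."""
    seqs = sorted(seqs)
    edges = set()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if dp_levenshtein(seqs[i], seqs[j]) == 1:
                edges.add((seqs[i], seqs[j]))
    return edges


def _encode_by_length(seqs):
    groups = {}
    for s in seqs:
        groups.setdefault(len(s), []).append(s)
    encoded = {}
    for length, members in groups.items():
        arr = np.frombuffer("".join(members).encode(), dtype=np.uint8)
        encoded[length] = (members, arr.reshape(len(members), length))
    return encoded


def _dp_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized DP edit-distance matrix between two batches of
    equal-length-per-batch sequences; returns (nA, nB) distances.

    The left-cell recurrence cur[j] = min(tmp[j-1], cur[j-1] + 1) is
    solved as a prefix minimum on cur[j] - j, so each DP row is a few
    whole-array operations instead of an inner loop.
    """
    na, la = A.shape
    nb, lb = B.shape
    jr = np.arange(lb + 1, dtype=np.int16)
    prev = np.broadcast_to(jr, (na, nb, lb + 1)).copy()
    work = np.empty((na, nb, lb + 1), dtype=np.int16)
    for i in range(la):
        mism = (A[:, i, None, None] != B[None, :, :])
        tmp = np.minimum(prev[:, :, 1:] + 1, prev[:, :, :-1] + mism)
        work[:, :, 0] = i + 1
        np.subtract(tmp, jr[1:], out=work[:, :, 1:])
        u = np.minimum.accumulate(work, axis=2)
        prev = u + jr
    return prev[:, :, -1]


def all_pairs_distance1_edges_fast(seqs) -> set:
    """All-pairs DP oracle vectorized over length groups (larger sets).

    Computes the full DP distance for every pair of sequences and keeps
    pairs at distance exactly 1.
    """
    encoded = _encode_by_length(seqs)
    lengths = sorted(encoded)
    edges = set()
    for li in lengths:
        mi, Ai = encoded[li]
        for lj in lengths:
            if lj < li:
                continue
            mj, Aj = encoded[lj]
            dist = _dp_block(Ai, Aj)
            ii, jj = np.nonzero(dist == 1)
            for a, b in zip(ii, jj):
                sa, sb = mi[a], mj[b]
                if sa != sb:
                    edges.add((sa, sb) if sa < sb else (sb, sa))
    return edges


def gini_mean_absolute_difference(x) -> float:
    """G = sum_{i,j} |x_i - x_j| / (2 n^2 mean)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mad = np.abs(x[:, None] - x[None, :]).sum()
    return float(mad / (2 * n * n * x.mean()))


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, summing exact rational hypergeometric probabilities
    no larger than the observed table's."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def wilcoxon_signflip_enumeration(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns.

    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) over the 2^n equally
    likely sign assignments of the rank magnitudes.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in product((False, True), repeat=n):
        w = ranks[list(signs)].sum()
        n_le += w <= w_obs
        n_ge += w >= w_obs
    total = 2 ** n
    return min(1.0, 2 * min(n_le, n_ge) / total)


def brute_force_sharing(cohort, seq: str) -> int:
    """Membership scan across every repertoire."""
    return sum(1 for rep in cohort if seq in rep.sequences)


def rank_based_correlation(x, y) -> float:
    """Spearman rho from first principles: Pearson on midranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size)
        sv = v[order]
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def pearson_correlation(x, y) -> float:
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum()))
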