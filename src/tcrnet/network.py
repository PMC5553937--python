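"""Levenshtein-distance-1 similarity networks over CDR3 AA sequences.

Nodes are unique AA sequences; an edge joins two sequences whose edit
distance (unit-cost substitution / insertion / deletion) is exactly 1.
Clusters are connected components of two or more nodes.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by full dynamic programming.

    This is the reference oracle; :func:`within_distance_one` is the fast
    predicate used for network construction.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def within_distance_one(a: str, b: str) -> bool:
    """True iff edit distance between a and b is exactly 1 (O(len))."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(a), len(b)
    if la < lb:
        a, b, la, lb = b, a, lb, la
    if la - lb > 1:
        return False
    if la == lb:
        # exactly one mismatching position
        return sum(x != y for x, y in zip(a, b)) == 1
    # lengths differ by 1: b must equal a with one character deleted
    i = 0
    while i < lb and a[i] == b[i]:
        i += 1
    return a[i + 1 :] == b[i:]


class DeletionVariantIndex:
    """Neighbor index: bucket each sequence under itself and every
    single-character-deleted form; distance-1 pairs share a bucket.

    Candidate pairs from shared buckets are verified with the exact
    predicate, so false positives (e.g. transpositions) are rejected.
    """

    def __init__(self, seqs: Iterable[str]) -> None:
        self._buckets: dict[str, list[str]] = defaultdict(list)
        self._seqs: set[str] = set()
        for s in seqs:
            self.add(s)

    @staticmethod
    def _keys(s: str):
        yield s
        for i in range(len(s)):
            yield s[:i] + s[i + 1 :]

    def add(self, s: str) -> None:
        if s in self._seqs:
            raise ValueError(f"duplicate sequence {s!r}")
        self._seqs.add(s)
        for k in self._keys(s):
            self._buckets[k].append(s)

    def neighbors(self, query: str) -> set[str]:
        """All indexed sequences at edit distance exactly 1 from query."""
        cands: set[str] = set()
        for k in self._keys(query):
            cands.update(self._buckets.get(k, ()))
        cands.discard(query)
        return {c for c in cands if within_distance_one(query, c)}

    def edges(self) -> set[tuple[str, str]]:
        """All distance-1 pairs among indexed sequences (sorted tuples)."""
        out: set[tuple[str, str]] = set()
        for members in self._buckets.values():
            if len(members) < 2:
                continue
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    if a == b:
                        continue
                    pair = (a, b) if a < b else (b, a)
                    if pair not in out and within_distance_one(a, b):
                        out.add(pair)
        return out


@dataclass
class Cluster:
    """A connected component of >= 2 nodes."""

    cluster_id: int
    members: frozenset[str]
    edge_count: int

    def __len__(self) -> int:
        return len(self.members)


def build_network(
    seqs: Iterable[str],
    attributes: Mapping[str, Mapping] | None = None,
    provenance: str = "",
) -> nx.Graph:
    """Build the distance-1 similarity graph over a set of unique sequences.

    `attributes` maps cdr3_aa -> dict of node attributes (abundance,
    sharing level, v_usage/j_usage tallies, ...), attached verbatim.
    """
    seqs = list(seqs)
    if len(seqs) != len(set(seqs)):
        raise ValueError("input sequences must be unique")
    g = nx.Graph(provenance=provenance)
    g.add_nodes_from(seqs)
    index = DeletionVariantIndex(seqs)
    g.add_edges_from(index.edges())
    if attributes:
        for node in g.nodes:
            attrs = attributes.get(node)
            if attrs:
                g.nodes[node].update(attrs)
    return g


def network_from_repertoire(rep, sharing=None, provenance: str = "") -> nx.Graph:
    """Convenience: network over a repertoire's clonotypes with abundance,
    usage tallies and (optionally) sharing-level node attributes."""
    attrs = {}
    for c in rep:
        a = {"abundance": c.total_count, "frequency": rep.frequency(c.cdr3_aa),
             "v_usage": dict(c.v_usage), "j_usage": dict(c.j_usage)}
        if sharing is not None:
            a["sharing"] = sharing.level(c.cdr3_aa)
        attrs[c.cdr3_aa] = a
    return build_network(rep.sequences, attributes=attrs, provenance=provenance)


def clusters(net: nx.Graph) -> list[Cluster]:
    """Connected components of size >= 2, largest first (ties: min member)."""
    comps = [c for c in nx.connected_components(net) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [
        Cluster(cluster_id=i, members=frozenset(c),
                edge_count=net.subgraph(c).number_of_edges())
        for i, c in enumerate(comps, 1)
    ]


def clustered_node_count(net: nx.Graph) -> int:
    return sum(len(c) for c in clusters(net))


def edge_count(net: nx.Graph) -> int:
    return net.number_of_edges()


def degree(net: nx.Graph) -> dict[str, int]:
    return dict(net.degree())


def betweenness(net: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness centrality, unnormalized by default
    (the figure-level comparisons are within equal-sized networks)."""
    return nx.betweenness_centrality(net, normalized=normalized)


def cluster_dominant_gene(net: nx.Graph, cluster: Cluster, which: str = "J") -> tuple[str, float]:
    """Gene with the largest summed usage count over the cluster's members,
    plus the fraction of summed counts it explains."""
    key = "v_usage" if which.upper() == "V" else "j_usage"
    totals: dict[str, int] = defaultdict(int)
    for node in cluster.members:
        usage = net.nodes[node].get(key) or {}
        for gene, cnt in usage.items():
            totals[gene] += cnt
    if not totals:
        raise ValueError(f"no {which} usage data in cluster {cluster.cluster_id}")
    total = sum(totals.values())
    gene = max(sorted(totals), key=totals.__getitem__)
    return gene, totals[gene] / total


def node_dominant_gene(net: nx.Graph, node: str, which: str = "J") -> tuple[str, float]:
    key = "v_usage" if which.upper() == "V" else "j_usage"
    usage = net.nodes[node].get(key) or {}
    if not usage:
        raise ValueError(f"no {which} usage data for node {node}")
    total = sum(usage.values())
    gene = max(sorted(usage), key=usage.__getitem__)
    return gene, usage[gene] / total


_SCALAR = (str, int, float, bool)


def export_graph(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML or SIF (Cytoscape-loadable)."""
    if format == "graphml":
        g = nx.Graph(**{k: v for k, v in net.graph.items() if isinstance(v, _SCALAR)})
        g.add_nodes_from(net.nodes)
        g.add_edges_from(net.edges)
        for n, data in net.nodes(data=True):
            g.nodes[n].update({k: v for k, v in data.items() if isinstance(v, _SCALAR)})
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in net.edges):
                fh.write(f"{a}\tld1\t{b}\n")
            for n in sorted(net.nodes):
                if net.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def node_attribute_table(net: nx.Graph, path=None):
    """Per-node attribute table (CSV when path given, else list of dicts):
    id, abundance, sharing, category, dominant V/J, degree, betweenness,
    cluster id."""
    deg = degree(net)
    btw = betweenness(net)
    cluster_of: dict[str, int] = {}
    for cl in clusters(net):
        for m in cl.members:
            cluster_of[m] = cl.cluster_id
    rows = []
    for n in sorted(net.nodes):
        data = net.nodes[n]
        try:
            dv = node_dominant_gene(net, n, "V")[0]
        except ValueError:
            dv = ""
        try:
            dj = node_dominant_gene(net, n, "J")[0]
        except ValueError:
            dj = ""
        rows.append({
            "cdr3_aa": n,
            "abundance": data.get("abundance", ""),
            "sharing": data.get("sharing", ""),
            "category": data.get("category", ""),
            "dominant_v": dv,
            "dominant_j": dj,
            "degree": deg[n],
            "betweenness": btw[n],
            "cluster_id": cluster_of.get(n, ""),
        })
    if path is not None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["cdr3_aa"])
            writer.writeheader()
            writer.writerows(rows)
    return rows
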