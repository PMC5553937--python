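"""Linking externally annotated CDR3 sequences to similarity networks.

Annotations (sequence + free-text label + category) are matched to a
network either as identical nodes or via a single edit step; linked
annotations inherit the matched node's cluster.  Category enrichment of
self-related annotations among clustered sequences is tested with a
Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network import DeletionVariantIndex, clusters
from .stats import fisher_exact_2x2

CATEGORIES = ("autoimmune", "tumor", "allograft", "pathogen")
_SELF_RELATED = {"autoimmune": True, "tumor": True, "allograft": True, "pathogen": False}


@dataclass(frozen=True)
class AnnotationRecord:
    cdr3_aa: str
    label: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")

    @property
    def self_related(self) -> bool:
        return _SELF_RELATED[self.category]


def read_annotations(path) -> list[AnnotationRecord]:
    """Annotation TSV: columns cdr3_aa, label, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cdr3_aa", "label", "category"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    return [AnnotationRecord(r.cdr3_aa, r.label, r.category) for r in df.itertuples()]


@dataclass
class AnnotationLink:
    record: AnnotationRecord
    status: str                      # identical-node | distance-1-neighbor | unlinked
    matched_node: str | None = None
    cluster_id: int | None = None    # None when matched only to isolated nodes
    candidate_clusters: tuple[int, ...] = ()
    linked_to_isolated_only: bool = False

    @property
    def linked(self) -> bool:
        return self.status != "unlinked"

    @property
    def clustered(self) -> bool:
        """Linked to a node inside a >= 2-node component."""
        return self.linked and self.cluster_id is not None


@dataclass
class LinkageResult:
    links: list[AnnotationLink]

    @property
    def n_identical(self) -> int:
        return sum(l.status == "identical-node" for l in self.links)

    @property
    def n_distance1(self) -> int:
        return sum(l.status == "distance-1-neighbor" for l in self.links)

    @property
    def n_linked(self) -> int:
        return self.n_identical + self.n_distance1

    @property
    def n_clustered(self) -> int:
        return sum(l.clustered for l in self.links)

    def by_cluster(self) -> dict[int, list[AnnotationLink]]:
        out: dict[int, list[AnnotationLink]] = {}
        for l in self.links:
            if l.cluster_id is not None:
                out.setdefault(l.cluster_id, []).append(l)
        return out


def link_annotations(net, annotations: list[AnnotationRecord]) -> LinkageResult:
    """Classify each annotation as identical to a node, at distance 1 from
    one, or unlinked.

    Cluster assignment uses the matched node (identical case) or, among all
    distance-1 neighbors, prefers clustered nodes, breaking ties by largest
    cluster then lexicographic node id.  All candidate clusters are kept.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    cls = clusters(net)
    cluster_of: dict[str, int] = {}
    cluster_size: dict[int, int] = {}
    for cl in cls:
        cluster_size[cl.cluster_id] = len(cl.members)
        for m in cl.members:
            cluster_of[m] = cl.cluster_id
    index = DeletionVariantIndex(net.nodes)

    links = []
    for rec in annotations:
        if rec.cdr3_aa in net.nodes:
            cid = cluster_of.get(rec.cdr3_aa)
            links.append(AnnotationLink(
                record=rec, status="identical-node", matched_node=rec.cdr3_aa,
                cluster_id=cid,
                candidate_clusters=(cid,) if cid is not None else (),
                linked_to_isolated_only=cid is None,
            ))
            continue
        neighbors = index.neighbors(rec.cdr3_aa)
        if not neighbors:
            links.append(AnnotationLink(record=rec, status="unlinked"))
            continue
        clustered = sorted(
            (n for n in neighbors if n in cluster_of),
            key=lambda n: (-cluster_size[cluster_of[n]], n),
        )
        cand = tuple(sorted({cluster_of[n] for n in clustered}))
        if clustered:
            best = clustered[0]
            links.append(AnnotationLink(
                record=rec, status="distance-1-neighbor", matched_node=best,
                cluster_id=cluster_of[best], candidate_clusters=cand,
            ))
        else:
            links.append(AnnotationLink(
                record=rec, status="distance-1-neighbor",
                matched_node=min(neighbors), cluster_id=None,
                candidate_clusters=(), linked_to_isolated_only=True,
            ))
    return LinkageResult(links=links)


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: clustered / unclustered; cols: self / non-self
    odds_ratio: float
    p_value: float
    clustered_self_fraction: float
    overall_self_fraction: float
    degenerate: bool = False


def category_enrichment(linkage: LinkageResult) -> EnrichmentResult:
    """Self-related enrichment among network-clustered annotations.

    Builds the non-overlapping clustered-vs-unclustered x self-vs-nonself
    table and applies the Fisher exact test; also reports the overlapping
    percentage framing (clustered self fraction vs overall self fraction).
    """
    cl_self = cl_non = un_self = un_non = 0
    for l in linkage.links:
        if l.clustered:
            if l.record.self_related:
                cl_self += 1
            else:
                cl_non += 1
        else:
            if l.record.self_related:
                un_self += 1
            else:
                un_non += 1
    table = ((cl_self, cl_non), (un_self, un_non))
    n_cl, n_un = cl_self + cl_non, un_self + un_non
    n_all = n_cl + n_un
    degenerate = n_cl == 0 or n_un == 0
    if degenerate:
        return EnrichmentResult(table, float("nan"), float("nan"),
                                cl_self / n_cl if n_cl else float("nan"),
                                (cl_self + un_self) / n_all, degenerate=True)
    odds, p = fisher_exact_2x2(table)
    return EnrichmentResult(
        table=table, odds_ratio=odds, p_value=p,
        clustered_self_fraction=cl_self / n_cl,
        overall_self_fraction=(cl_self + un_self) / n_all,
    )


def write_linkage_report(linkage: LinkageResult, path) -> None:
    rows = [{
        "cdr3_aa": l.record.cdr3_aa,
        "label": l.record.label,
        "category": l.record.category,
        "self_related": l.record.self_related,
        "status": l.status,
        "matched_node": l.matched_node or "",
        "cluster_id": "" if l.cluster_id is None else l.cluster_id,
        "candidate_clusters": ";".join(map(str, l.candidate_clusters)),
    } for l in linkage.links]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
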