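"""Inclusive sequence-similarity network construction.

Nodes are sequences (singletons included); at most one edge per unordered
pair, carrying the statistics and alignment intervals of the retained best
hit. An edge exists when at least one pairwise hit in either direction has
an E-value strictly below the build threshold (default 1e-5), the regime in
which false positive hits between non-homologous proteins are not expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import SequenceRecord, SimilarityHit

DEFAULT_BUILD_THRESHOLD = 1e-5


@dataclass
class SimilarityNetwork:
    """Undirected similarity graph plus its build threshold.

    Edge data keys: ``evalue``, ``bitscore``, ``aln_length`` of the retained
    hit, and ``intervals`` — a mapping from each endpoint id to the hit's
    (start, end) on that endpoint's own coordinates. Node data: ``length``
    and ``genome_id`` from the sequence records.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    build_threshold: float = DEFAULT_BUILD_THRESHOLD

    def interval_on(self, u: str, v: str, node: str) -> tuple[int, int]:
        """Retained-hit interval of edge (u, v) on ``node``'s coordinates."""
        return self.graph.edges[u, v]["intervals"][node]

    def evalue(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["evalue"]

    def subnetwork(self, nodes: Iterable[str]) -> "SimilarityNetwork":
        """Induced subgraph on ``nodes``, edge/node attributes retained."""
        return SimilarityNetwork(
            graph=self.graph.subgraph(list(nodes)).copy(),
            build_threshold=self.build_threshold,
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    hits: Iterable[SimilarityHit],
    sequences: Iterable[SequenceRecord],
    threshold: float = DEFAULT_BUILD_THRESHOLD,
) -> SimilarityNetwork:
    """Symmetrize hits and keep, per unordered pair, the best E-value hit.

    Self-hits never become edges. Hits at E-value equal to or above the
    threshold are excluded (strict ``<``). Ties on E-value are broken by
    higher bitscore, then by the direction whose query_id sorts first, so
    builds are deterministic regardless of input order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    records = {r.seq_id: r for r in sequences}
    if not records:
        raise ValueError("no sequences given")

    best: dict[frozenset[str], SimilarityHit] = {}
    for h in hits:
        if h.query_id not in records or h.subject_id not in records:
            missing = h.query_id if h.query_id not in records else h.subject_id
            raise ValueError(f"hit references unknown sequence {missing!r}")
        if h.is_self or h.evalue >= threshold:
            continue
        if h.q_end > records[h.query_id].length or \
                h.s_end > records[h.subject_id].length:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id}: coordinates exceed "
                "sequence length"
            )
        key = frozenset((h.query_id, h.subject_id))
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h

    g = nx.Graph()
    for r in records.values():
        g.add_node(r.seq_id, length=r.length, genome_id=r.genome_id)
    for h in best.values():
        g.add_edge(
            h.query_id,
            h.subject_id,
            evalue=h.evalue,
            bitscore=h.bitscore,
            aln_length=h.aln_length,
            intervals={
                h.query_id: (h.q_start, h.q_end),
                h.subject_id: (h.s_start, h.s_end),
            },
        )
    return SimilarityNetwork(graph=g, build_threshold=threshold)


def _hit_rank(h: SimilarityHit) -> tuple[float, float, str]:
    return (h.evalue, -h.bitscore, h.query_id)


@dataclass
class ComponentPartition:
    """Connected components of size >= 2 (decreasing size) and singletons."""

    components: list[set[str]]
    singletons: list[str]

    @property
    def n_clusters(self) -> int:
        return len(self.components)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def giant(self) -> set[str]:
        return self.components[0] if self.components else set()


def connected_components(network: SimilarityNetwork) -> ComponentPartition:
    """Simple-linkage partition; singletons reported separately from
    clusters of two sequences or more."""
    comps = [set(c) for c in nx.connected_components(network.graph)]
    clusters = sorted(
        (c for c in comps if len(c) > 1),
        key=lambda c: (-len(c), min(c)),
    )
    singletons = sorted(x for c in comps if len(c) == 1 for x in c)
    return ComponentPartition(components=clusters, singletons=singletons)
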