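"""Network statistics: first-pass Louvain communities, community supergraph
with cycle edges, categorical assortativity, betweenness centrality and
composite/non-composite contrasts.

The "first pass" of Louvain is the local-moving phase only — starting from
singleton communities, nodes are repeatedly swept in a seed-shuffled order
and moved to the neighboring community with the largest positive modularity
gain until a full sweep makes no move. No hierarchical aggregation is
performed: the resulting communities are the densely connected groups that
the community supergraph then pools into supernodes. Cycles among
supernodes are the diagnostic of gene remodeling (pure divergence thins a
similarity network into trees and chains but cannot close cycles), so each
supergraph edge is flagged as in-cycle iff it is not a bridge.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.community import modularity as nx_modularity

logger = logging.getLogger(__name__)


def _as_graph(network) -> nx.Graph:
    """Accept either a SimilarityNetwork wrapper or a bare nx.Graph."""
    if isinstance(network, nx.Graph):
        return network
    return network.graph


@dataclass
class CommunityPartition:
    labels: dict[str, int]  # node -> community id
    modularity: float

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.labels.items():
            out.setdefault(cid, set()).add(node)
        return out


def louvain_first_pass(network, seed: int = 0) -> CommunityPartition:
    """Single-level Louvain local moving on the unweighted graph.

    Ties in modularity gain go to the smallest community id, and the sweep
    order is a seed-shuffled fixed permutation, so the partition is
    deterministic given the seed. An edgeless graph yields the all-singleton
    partition with modularity 0; an empty (no-node) graph is an error.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    comm = {node: i for i, node in enumerate(nodes)}
    m = g.number_of_edges()
    if m == 0:
        return CommunityPartition(labels=comm, modularity=0.0)

    degree = dict(g.degree)
    comm_total = {comm[n]: degree[n] for n in nodes}  # sum of degrees per comm
    order = list(nodes)
    random.Random(seed).shuffle(order)

    two_m = 2.0 * m
    moved = True
    while moved:
        moved = False
        for node in order:
            old = comm[node]
            k_i = degree[node]
            # links from node into each neighboring community
            links: dict[int, int] = {}
            for nb in g.neighbors(node):
                if nb == node:
                    continue
                links[comm[nb]] = links.get(comm[nb], 0) + 1
            # take node out of its community
            comm_total[old] -= k_i
            best_comm, best_gain = old, _gain(
                links.get(old, 0), comm_total[old], k_i, two_m)
            for cand in sorted(links):
                if cand == old:
                    continue
                gain = _gain(links[cand], comm_total[cand], k_i, two_m)
                if gain > best_gain or (gain == best_gain and cand < best_comm):
                    best_comm, best_gain = cand, gain
            comm_total[best_comm] = comm_total.get(best_comm, 0) + k_i
            if best_comm != old:
                comm[node] = best_comm
                moved = True

    # compact community ids to 0..k-1 in order of smallest member
    groups: dict[int, list[str]] = {}
    for node in nodes:
        groups.setdefault(comm[node], []).append(node)
    remap = {
        cid: rank
        for rank, cid in enumerate(sorted(groups, key=lambda c: groups[c][0]))
    }
    labels = {node: remap[comm[node]] for node in nodes}
    parts = [set(v) for v in groups.values()]
    return CommunityPartition(labels=labels, modularity=nx_modularity(g, parts))


def _gain(k_i_in: int, tot: float, k_i: int, two_m: float) -> float:
    """Modularity gain of joining a community (node currently removed)."""
    return k_i_in / two_m * 2.0 - tot * k_i / (two_m * two_m) * 2.0


def community_supergraph(network, partition: CommunityPartition) -> nx.Graph:
    """Pool communities into supernodes: node attribute ``size``, edge
    attribute ``count`` (inter-community edge count) and ``in_cycle``."""
    g = _as_graph(network)
    sg = nx.Graph()
    sizes: dict[int, int] = {}
    for node, cid in partition.labels.items():
        sizes[cid] = sizes.get(cid, 0) + 1
    for cid, size in sizes.items():
        sg.add_node(cid, size=size)
    for u, v in g.edges:
        cu, cv = partition.labels[u], partition.labels[v]
        if cu == cv:
            continue
        if sg.has_edge(cu, cv):
            sg.edges[cu, cv]["count"] += 1
        else:
            sg.add_edge(cu, cv, count=1)
    cycle_edges(sg)
    return sg


def cycle_edges(supergraph: nx.Graph) -> dict[tuple, bool]:
    """Flag each edge as lying on some cycle — equivalently, not a bridge.

    Sets the ``in_cycle`` edge attribute and returns the flag map.
    """
    bridges = set()
    for u, v in nx.bridges(supergraph):
        bridges.add(frozenset((u, v)))
    flags = {}
    for u, v in supergraph.edges:
        flag = frozenset((u, v)) not in bridges
        supergraph.edges[u, v]["in_cycle"] = flag
        flags[(u, v)] = flag
    return flags


# ---------------------------------------------------------------------------
# Assortativity
# ---------------------------------------------------------------------------

def attribute_assortativity(
    network, label_map, exclude_unlabeled: bool = True
) -> float:
    """Newman's categorical assortativity r over the edge-endpoint mixing
    matrix: r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i), each
    undirected edge counted in both orientations.

    Edges touching unlabeled nodes are dropped when ``exclude_unlabeled``
    (otherwise the missing label acts as a category of its own). A graph
    whose evaluated edges all join a single label has an undefined
    coefficient (denominator 0) — that is an error, distinct from r = 1
    computed over two or more labels.
    """
    g = _as_graph(network)
    counts: dict[tuple, float] = {}
    total = 0
    for u, v in g.edges:
        lu = label_map.get(u)
        lv = label_map.get(v)
        if exclude_unlabeled and (lu is None or lv is None):
            continue
        counts[(lu, lv)] = counts.get((lu, lv), 0) + 1
        counts[(lv, lu)] = counts.get((lv, lu), 0) + 1
        total += 2
    if total == 0:
        raise ValueError("no edge with both endpoints labeled")
    labels = sorted({l for pair in counts for l in pair}, key=repr)
    e = {pair: c / total for pair, c in counts.items()}
    trace = sum(e.get((l, l), 0.0) for l in labels)
    a = {l: sum(e.get((l, k), 0.0) for k in labels) for l in labels}
    sum_ab = sum(a[l] * a[l] for l in labels)
    if 1.0 - sum_ab == 0.0:
        raise ValueError(
            "assortativity undefined: all evaluated edges share one label "
            f"({labels[0]!r}); this is not r=1"
        )
    return (trace - sum_ab) / (1.0 - sum_ab)


def per_class_assortativity(network, label_map) -> dict[str, float]:
    """Per-class coefficient via the binary indicator label (class vs rest).

    Classes whose indicator has no evaluable mixed edge set (e.g. every
    labeled edge inside the class) are reported absent.
    """
    classes = sorted({v for v in label_map.values() if v is not None})
    out: dict[str, float] = {}
    for cls in classes:
        indicator = {
            node: (lbl == cls) for node, lbl in label_map.items()
            if lbl is not None
        }
        try:
            out[cls] = attribute_assortativity(network, indicator)
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# Betweenness
# ---------------------------------------------------------------------------

def betweenness(
    network,
    mode: str = "exact",
    k_pivots: int = 5000,
    seed: int | None = None,
) -> dict[str, float]:
    """Normalized shortest-path betweenness, endpoints excluded.

    ``approximate`` uses the pivot estimator — single-source shortest paths
    from ``k_pivots`` uniformly sampled sources, accumulated dependencies
    rescaled by n/k — and equals the exact computation when k = n.
    ``k_pivots`` larger than the node count is clamped with a notice.
    """
    g = _as_graph(network)
    n = g.number_of_nodes()
    if mode == "exact":
        return nx.betweenness_centrality(g, normalized=True)
    if mode != "approximate":
        raise ValueError(f"unknown betweenness mode {mode!r}")
    if k_pivots < 1:
        raise ValueError("k_pivots must be >= 1")
    if k_pivots > n:
        logger.info("k_pivots=%d exceeds node count %d; clamped", k_pivots, n)
        k_pivots = n
    return nx.betweenness_centrality(g, k=k_pivots, normalized=True, seed=seed)


@dataclass
class BetweennessContrast:
    mean_composite: float
    mean_noncomposite: float
    ratio: float

    @property
    def ratio_1dp(self) -> float:
        return round(self.ratio, 1)

    @property
    def ratio_nearest_int(self) -> int:
        return round(self.ratio)


def group_betweenness_contrast(
    centralities: dict[str, float], composite_ids
) -> BetweennessContrast:
    """Arithmetic mean betweenness of composite vs non-composite nodes and
    their ratio; both groups must be non-empty."""
    composite_ids = set(composite_ids)
    comp = [v for k, v in centralities.items() if k in composite_ids]
    non = [v for k, v in centralities.items() if k not in composite_ids]
    if not comp or not non:
        raise ValueError("both composite and non-composite groups must be "
                         "non-empty")
    mc = sum(comp) / len(comp)
    mn = sum(non) / len(non)
    if mn == 0.0:
        raise ValueError("non-composite mean betweenness is zero")
    return BetweennessContrast(mean_composite=mc, mean_noncomposite=mn,
                               ratio=mc / mn)
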