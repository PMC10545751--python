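"""Global association network: merging, module detection, null tests.

Subset edge lists are merged into one undirected simple graph; modules
are detected by iterative removal of the highest-betweenness edge with
the resulting component partition scored by Newman-Girvan modularity,
and the observed modularity is tested against rewired null networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

from ._util import stage_rng

__all__ = [
    "ModuleAssignment",
    "merge_subset_networks",
    "modularity",
    "edge_betweenness_clusters",
    "rewire_null_test",
]


@dataclass
class ModuleAssignment:
    """A node -> module partition with its modularity score."""

    membership: dict
    modularity_q: float
    null_p: float | None = None
    removal_order: list = field(default_factory=list)


def merge_subset_networks(edge_lists) -> nx.Graph:
    """Union of per-subset edge lists into one simple undirected graph.

    Duplicate edges across subsets collapse to a single edge carrying the
    maximum correlation as ``weight`` and the sorted tuple of contributing
    subsets as ``subsets``. Merging is idempotent and order-invariant.
    """
    edge_lists = list(edge_lists)
    if not edge_lists:
        raise ValueError("need at least one edge list")
    g = nx.Graph()
    for edges in edge_lists:
        for row in edges.itertuples(index=False):
            u, v = str(row.asv_i), str(row.asv_j)
            if u == v:
                raise ValueError(f"self-loop on {u}")
            subset = getattr(row, "subset", "")
            r = float(row.r)
            if g.has_edge(u, v):
                data = g[u][v]
                data["weight"] = max(data["weight"], r)
                data["subsets"] = tuple(sorted(set(data["subsets"]) | {subset}))
            else:
                g.add_edge(u, v, weight=r, subsets=(subset,))
    return g


def modularity(graph: nx.Graph, membership) -> float:
    """Newman-Girvan Q of a partition on the unweighted graph:
    ``sum_c (L_c / m - (d_c / 2m)^2)``."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    missing = [n for n in graph.nodes if n not in membership]
    if missing:
        raise KeyError(f"node without module membership: {missing[0]!r}")
    labels = {}
    within = {}
    degsum = {}
    for u, v in graph.edges:
        cu, cv = membership[u], membership[v]
        if cu == cv:
            within[cu] = within.get(cu, 0) + 1
    for n, d in graph.degree:
        c = membership[n]
        degsum[c] = degsum.get(c, 0) + d
    q = 0.0
    for c, dsum in degsum.items():
        q += within.get(c, 0) / m - (dsum / (2.0 * m)) ** 2
    return q


def _relabel(nodes, labels):
    """Deterministic module ids: order of first appearance over sorted nodes."""
    mapping = {}
    out = {}
    for n, lab in zip(nodes, labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[n] = mapping[lab]
    return out


def edge_betweenness_clusters(graph: nx.Graph) -> ModuleAssignment:
    """Divisive edge-betweenness clustering, cut at maximum modularity.

    Edges are removed one at a time in order of decreasing betweenness
    (ties broken by lexicographic edge id, so the result is
    deterministic); after each removal the connected-component partition
    is scored with :func:`modularity` on the *original* graph and the
    best-scoring partition is returned. Singleton components stay their
    own modules.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    idx = {n: i for i, n in enumerate(nodes)}
    edges = sorted((min(u, v), max(u, v)) for u, v in graph.edges)
    m = len(edges)
    if m == 0:
        return ModuleAssignment({n: i + 1 for i, n in enumerate(nodes)}, 0.0)

    ei = np.array([idx[u] for u, v in edges])
    ej = np.array([idx[v] for u, v in edges])
    deg = np.zeros(len(nodes))
    for k in range(m):
        deg[ei[k]] += 1
        deg[ej[k]] += 1

    def score(labels):
        labels = np.asarray(labels)
        within_mask = labels[ei] == labels[ej]
        nlab = labels.max() + 1
        l_c = np.bincount(labels[ei][within_mask], minlength=nlab)
        d_c = np.bincount(labels, weights=deg, minlength=nlab)
        return float((l_c / m - (d_c / (2.0 * m)) ** 2).sum())

    work = ig.Graph(n=len(nodes), edges=list(zip(ei.tolist(), ej.tolist())))
    names = list(edges)
    labels = work.connected_components().membership
    best_q, best_labels = score(labels), list(labels)
    removal_order = []
    while work.ecount() > 0:
        eb = work.edge_betweenness()
        mx = max(eb)
        cands = [k for k, b in enumerate(eb) if b >= mx - 1e-9]
        k = min(cands, key=lambda c: names[c])
        removal_order.append(names[k])
        work.delete_edges(k)
        del names[k]
        labels = work.connected_components().membership
        q = score(labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, list(labels)

    membership = _relabel(nodes, best_labels)
    return ModuleAssignment(membership, best_q, removal_order=removal_order)


def _rewire_endpoints(graph: nx.Graph, p: float, rng) -> nx.Graph:
    """Resample each edge endpoint independently with probability ``p``;
    self-loops and duplicates produced by rewiring are dropped."""
    nodes = sorted(graph.nodes)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    for u, v in sorted((min(a, b), max(a, b)) for a, b in graph.edges):
        if rng.random() < p:
            u = nodes[rng.integers(len(nodes))]
        if rng.random() < p:
            v = nodes[rng.integers(len(nodes))]
        if u != v:
            out.add_edge(u, v)
    return out


def _rewire_degree_preserving(graph: nx.Graph, p: float, rng) -> nx.Graph:
    out = graph.copy()
    nswap = max(1, int(round(p * graph.number_of_edges())))
    try:
        nx.double_edge_swap(out, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(2**31)))
    except nx.NetworkXError:
        pass  # too few edges to swap; keep as is
    return out


def rewire_null_test(
    graph: nx.Graph,
    n: int = 999,
    p_rewire: float = 0.5,
    seed: int = 0,
    mode: str = "endpoint",
) -> tuple[float, float, np.ndarray]:
    """Test observed modularity against rewired networks.

    Each of ``n`` null instances rewires the graph (``endpoint``:
    independent endpoint resampling at probability ``p_rewire``, edge
    count preserved up to dedup; ``degree``: degree-preserving double
    edge swaps), is re-clustered by edge betweenness, and contributes its
    modularity. Returns ``(p, q_obs, q_null)`` with
    ``p = #{Q_null >= Q_obs} / n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if graph.number_of_edges() < 2:
        raise ValueError("need at least 2 edges for the rewiring null")
    rng = stage_rng(seed, "rewire", mode)
    q_obs = edge_betweenness_clusters(graph).modularity_q
    rewire = _rewire_endpoints if mode == "endpoint" else _rewire_degree_preserving
    q_null = np.empty(n)
    for b in range(n):
        h = rewire(graph, p_rewire, rng)
        if h.number_of_edges() == 0:
            q_null[b] = 0.0
            continue
        q_null[b] = edge_betweenness_clusters(h).modularity_q
    p = float((q_null >= q_obs - 1e-12).sum() / n)
    return p, q_obs, q_null
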