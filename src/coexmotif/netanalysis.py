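"""Graph analysis: centrality, neighborhoods, Markov clustering, cluster
graphs, label-shuffled nulls and GML export.

Networks are undirected :class:`networkx.Graph` objects whose edges carry a
``weight`` attribute (the CLR or similarity score).  Centralities are purely
combinatorial: degree centrality is deg(v)/(n-1) and betweenness uses
unweighted shortest paths normalized by (n-1)(n-2)/2, so both lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ContractError, UnknownGeneError


def degree_centrality(net: nx.Graph) -> dict[str, float]:
    if net.number_of_nodes() < 2:
        raise ContractError("degree centrality needs at least 2 nodes")
    return nx.degree_centrality(net)


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Fraction of shortest paths between other node pairs passing through v."""
    if net.number_of_nodes() < 3:
        raise ContractError("betweenness centrality needs at least 3 nodes")
    return nx.betweenness_centrality(net, normalized=True, weight=None)


def top_k_by_centrality(
    net: nx.Graph, k: int, measure: str = "degree"
) -> tuple[list[tuple[str, float]], float]:
    """Top-k nodes (descending centrality, ties by id) and their mean centrality."""
    if measure == "degree":
        cent = degree_centrality(net)
    elif measure == "betweenness":
        cent = betweenness_centrality(net)
    else:
        raise ContractError(f"unknown centrality measure {measure!r}")
    if k > len(cent):
        raise ContractError("k exceeds node count")
    ranked = sorted(cent.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    mean = float(np.mean([v for _, v in ranked])) if k else 0.0
    return ranked, mean


def neighborhood(net: nx.Graph, seed: str, include_seed: bool = False) -> set[str]:
    """Direct neighbors of ``seed``; the seed itself excluded unless flagged."""
    if seed not in net:
        raise UnknownGeneError(f"gene {seed!r} not in network")
    out = set(net.neighbors(seed))
    out.discard(seed)
    if include_seed:
        out.add(seed)
    return out


def expand_neighborhood(net_full, genes, expansion_tau: float, base_tau: float) -> nx.Graph:
    """Recruit genes whose CLR to any member exceeds ``expansion_tau``, then
    induce the thresholded subnetwork on the enlarged set at ``base_tau``.

    ``net_full`` is a :class:`coexmotif.inference.CLRNetwork` (full score
    matrix), not a thresholded graph.
    """
    if expansion_tau < 0:
        raise ContractError("expansion_tau must be non-negative")
    genes = sorted(set(genes))
    lookup = {g: i for i, g in enumerate(net_full.gene_ids)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise UnknownGeneError(f"genes not in CLR network: {missing[:5]}")
    idx = np.array([lookup[g] for g in genes], dtype=np.int64)
    if np.isfinite(expansion_tau):
        best = net_full.clr[idx, :].max(axis=0)
        recruited = {net_full.gene_ids[j] for j in np.flatnonzero(best > expansion_tau)}
    else:
        recruited = set()
    enlarged = sorted(set(genes) | recruited)
    eidx = np.array([lookup[g] for g in enlarged], dtype=np.int64)
    sub = net_full.clr[np.ix_(eidx, eidx)]
    g = nx.Graph(threshold=float(base_tau))
    g.add_nodes_from(enlarged)
    ii, jj = np.nonzero(np.triu(sub > base_tau, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(enlarged[i], enlarged[j], weight=float(sub[i, j]))
    return g


@dataclass
class Clustering:
    """A partition of graph nodes into integer-labelled clusters."""

    partition: dict
    converged: bool = True

    def clusters(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, cid in self.partition.items():
            out.setdefault(cid, []).append(node)
        for members in out.values():
            members.sort()
        return out


def mcl_cluster(
    net: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> Clustering:
    """Markov clustering of a weighted undirected graph.

    Self-loops are set to each column's maximum weight, columns are
    normalized, and expansion (matrix squaring) alternates with inflation
    (entrywise power and renormalization), pruning entries below ``prune``,
    until the iterate changes by less than ``tol`` or ``max_iter`` is hit.
    Clusters are the connected components of the limit matrix's support.
    """
    if inflation <= 1:
        raise ContractError("inflation must be > 1")
    nodes = sorted(net.nodes())
    n = len(nodes)
    if n == 0:
        return Clustering({}, True)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        if u == v:
            continue
        w = float(data.get("weight", 1.0))
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    colmax = a.max(axis=0)
    np.fill_diagonal(a, np.where(colmax > 0, colmax, 1.0))
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():
            inflated[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
            colsum = inflated.sum(axis=0, keepdims=True)
        new = inflated / colsum
        change = np.abs(new - m).max()
        m = new
        if change < tol:
            converged = True
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    ii, jj = np.nonzero(m > 0)
    support.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i != j)
    components = sorted(nx.connected_components(support), key=min)
    partition = {}
    for cid, comp in enumerate(components):
        for i in comp:
            partition[nodes[i]] = cid
    return Clustering(partition, converged)


def cluster_graph(net: nx.Graph, clustering: Clustering) -> nx.Graph:
    """Collapse clusters into nodes; clusters link iff an original edge crosses."""
    missing = [v for v in net.nodes() if v not in clustering.partition]
    if missing:
        raise ContractError(f"partition does not cover nodes: {missing[:5]}")
    g = nx.Graph()
    for cid, members in sorted(clustering.clusters().items()):
        g.add_node(cid, size=len(members), members=",".join(str(m) for m in members))
    for u, v in net.edges():
        cu, cv = clustering.partition[u], clustering.partition[v]
        if cu != cv:
            g.add_edge(cu, cv)
    return g


def shuffle_node_labels(net: nx.Graph, seed: int) -> nx.Graph:
    """Uniform random relabelling of the nodes; topology is untouched."""
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    return nx.relabel_nodes(net, mapping, copy=True)


def export_gml(net: nx.Graph, path) -> None:
    """Write GML; node labels are stringified so the file round-trips."""
    g = nx.relabel_nodes(net, {v: str(v) for v in net.nodes()}, copy=True)
    nx.write_gml(g, path)


def import_gml(path) -> nx.Graph:
    return nx.read_gml(path)
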