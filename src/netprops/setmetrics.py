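"""Shortest-path machinery and set-level distance measures.

Distances are unweighted breadth-first shortest paths. Pairs of nodes with
no connecting path are assigned the maximum finite shortest-path length
observed anywhere in the network, so every pairwise distance is defined.
On top of this distance, two set-level measures are provided:

* intra-set distance — the average distance over all pairs of distinct
  genes within one set (average of d_ij over ordered pairs i != j);
* inter-set distance — the sum of the two directional mean cross-distances
  between two sets, where the directional mean for a gene is its average
  distance to every gene of the other set (self-distances of shared genes
  count as 0).

A set-level clustering coefficient is also provided, either as the mean
local clustering coefficient of members on the full network (default) or on
the subgraph induced by the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from netprops.genesets import MappedGeneSet
from netprops.network_io import Network

__all__ = [
    "SPMatrix",
    "IADResult",
    "IEDResult",
    "shortest_paths",
    "set_clustering_coefficient",
    "intra_set_distance",
    "inter_set_distance",
]


class SPMatrix:
    """All-pairs shortest-path distances with the disconnected-pair fill.

    ``max_finite_sp`` — the maximum finite shortest-path length over all node
    pairs of the whole network — is computed once at construction and used as
    the distance for every disconnected pair. Per-source BFS results are
    memoized on demand, so a dense all-pairs matrix is never materialized.
    """

    def __init__(self, net: Network):
        if net.n_nodes < 2:
            raise ValueError("shortest paths need at least 2 nodes")
        if net.n_edges == 0:
            raise ValueError("network has no edges; maximum finite shortest path is undefined")
        self._net = net
        self._g = net.graph
        self._memo: dict[str, dict[str, int]] = {}
        max_sp = 0
        for comp in nx.connected_components(self._g):
            if len(comp) < 2:
                continue
            sub = self._g.subgraph(comp)
            for _, dists in nx.all_pairs_shortest_path_length(sub):
                ecc = max(dists.values())
                if ecc > max_sp:
                    max_sp = ecc
        self.max_finite_sp: int = max_sp

    @property
    def network(self) -> Network:
        return self._net

    def distances_from(self, source: str) -> dict[str, int]:
        """Finite BFS distances from ``source`` (memoized). Missing keys are
        disconnected pairs, to be read as ``max_finite_sp``."""
        if source not in self._g:
            raise KeyError(f"node {source!r} not in network")
        if source not in self._memo:
            self._memo[source] = dict(nx.single_source_shortest_path_length(self._g, source))
        return self._memo[source]

    def distance(self, u: str, v: str) -> int:
        """d(u, v): 0 on the diagonal, BFS length if connected, fill otherwise."""
        if u == v:
            if u not in self._g:
                raise KeyError(f"node {u!r} not in network")
            return 0
        d = self.distances_from(u).get(v)
        return self.max_finite_sp if d is None else d


def shortest_paths(net: Network) -> SPMatrix:
    """Build the :class:`SPMatrix` for a network."""
    return SPMatrix(net)


@dataclass(frozen=True)
class IADResult:
    set_name: str
    n_used: int
    iad: float


@dataclass(frozen=True)
class IEDResult:
    set_p: str
    set_q: str
    n_p: int
    n_q: int
    mean_p_to_q: float
    mean_q_to_p: float
    ied: float


def set_clustering_coefficient(
    net: Network, s: MappedGeneSet, mode: str = "node_average"
) -> float:
    """Mean local clustering coefficient over the set's in-network genes.

    ``node_average`` (default) evaluates each member's local clustering
    coefficient on the full network (0 for degree < 2); ``induced_subgraph``
    evaluates it on the subgraph induced by the members.
    """
    if not s.in_network:
        raise ValueError(f"set {s.origin}: no in-network genes, clustering coefficient undefined")
    members = sorted(s.in_network)
    if mode == "node_average":
        cc = nx.clustering(net.graph, nodes=members)
    elif mode == "induced_subgraph":
        cc = nx.clustering(net.graph.subgraph(members))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sum(cc[m] for m in members) / len(members)


def intra_set_distance(sp: SPMatrix, s: MappedGeneSet) -> IADResult:
    """Average pairwise distance over distinct in-network members.

    The average over ordered pairs i != j equals the unordered-pair average
    by symmetry; it is computed over unordered pairs.
    """
    genes = sorted(s.in_network)
    n = len(genes)
    if n < 2:
        raise ValueError(f"set {s.origin}: IAD undefined with {n} in-network gene(s)")
    total = 0
    for i, gi in enumerate(genes):
        dists = sp.distances_from(gi)
        for gj in genes[i + 1 :]:
            d = dists.get(gj)
            total += sp.max_finite_sp if d is None else d
    iad = 2.0 * total / (n * (n - 1))
    return IADResult(set_name=s.origin, n_used=n, iad=iad)


def inter_set_distance(sp: SPMatrix, sp_set: MappedGeneSet, sq_set: MappedGeneSet) -> IEDResult:
    """Sum of the two directional mean cross-distances between two sets.

    Both directional means equal the grand mean of the cross-distance block,
    so the result is exactly twice that grand mean; the identity is asserted.
    Shared genes contribute zero self-distances (no diagonal exclusion).
    """
    p_genes = sorted(sp_set.in_network)
    q_genes = sorted(sq_set.in_network)
    if not p_genes or not q_genes:
        raise ValueError("IED undefined: a set has no in-network genes")
    total = 0
    for gi in p_genes:
        dists = sp.distances_from(gi)
        for gj in q_genes:
            if gi == gj:
                continue
            d = dists.get(gj)
            total += sp.max_finite_sp if d is None else d
    grand_mean = total / (len(p_genes) * len(q_genes))
    mean_p_to_q = grand_mean
    mean_q_to_p = grand_mean
    ied = mean_p_to_q + mean_q_to_p
    assert abs(ied - 2.0 * grand_mean) < 1e-12
    return IEDResult(
        set_p=sp_set.origin,
        set_q=sq_set.origin,
        n_p=len(p_genes),
        n_q=len(q_genes),
        mean_p_to_q=mean_p_to_q,
        mean_q_to_p=mean_q_to_p,
        ied=ied,
    )
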