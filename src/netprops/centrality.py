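"""Node centralities, gene-group summaries, and one-tailed group comparisons.

Conventions:

* degree — raw edge count;
* betweenness — unnormalized shortest-path load with pair-splitting over
  equal-length shortest paths;
* closeness — (n-1) / sum of distances to all other nodes, with distances to
  unreachable nodes filled by the network's maximum finite shortest path
  (the same fill used for set distances), keeping the score defined
  network-wide and in (0, 1];
* eigenvector — principal adjacency eigenvector by power iteration,
  normalized so the maximum entry is 1; on disconnected graphs, nodes off
  the dominant component receive scores near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from netprops.genesets import MappedGeneSet
from netprops.network_io import Network
from netprops.setmetrics import SPMatrix

__all__ = [
    "CentralityTable",
    "GroupComparison",
    "compute_centralities",
    "background_mean",
    "compare_groups",
    "fdr_adjust",
]

MEASURES = ("degree", "betweenness", "closeness", "eigenvector")

#: Per-node centrality table: one row per node, columns ``degree``,
#: ``betweenness``, ``closeness``, ``eigenvector``.
CentralityTable = pd.DataFrame


@dataclass(frozen=True)
class GroupComparison:
    """Result of a one-sided two-sample comparison of node values."""

    group_a: str
    group_b: str
    measure: str
    direction: str
    t_statistic: float
    p: float
    q: float | None = None


def _eigenvector_power(g: nx.Graph, nodes: list[str], tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    n = len(nodes)
    # +I shift: same principal eigenvector, but breaks the +/- eigenvalue
    # symmetry of bipartite components so the iteration cannot oscillate.
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v + v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    vmax = v.max()
    return v / vmax if vmax > 0 else v


def compute_centralities(net: Network, sp: SPMatrix | None = None) -> CentralityTable:
    """Compute the four centralities for every node of the network.

    ``sp`` may be passed to reuse an existing shortest-path cache for the
    closeness computation.
    """
    if net.n_nodes < 2 or net.n_edges == 0:
        raise ValueError("centralities need a network with >=2 nodes and >=1 edge")
    g = net.graph
    nodes = sorted(net.nodes)
    if sp is None:
        sp = SPMatrix(net)
    fill = sp.max_finite_sp

    degree = [g.degree(n) for n in nodes]
    btw = nx.betweenness_centrality(g, normalized=False)

    n = len(nodes)
    closeness = []
    for v in nodes:
        dists = sp.distances_from(v)
        total = sum(dists.values()) + (n - len(dists)) * fill
        closeness.append((n - 1) / total)

    eig = _eigenvector_power(g, nodes)

    return pd.DataFrame(
        {
            "degree": degree,
            "betweenness": [btw[v] for v in nodes],
            "closeness": closeness,
            "eigenvector": eig,
        },
        index=pd.Index(nodes, name="node"),
    )


def background_mean(tab: CentralityTable, measure: str) -> float:
    """Arithmetic mean of a centrality over all network nodes."""
    if measure not in tab.columns:
        raise KeyError(f"measure {measure!r} not in table")
    return float(tab[measure].mean())


def compare_groups(
    tab: CentralityTable,
    set_a: MappedGeneSet,
    set_b: MappedGeneSet,
    measure: str,
    direction: str = "greater",
) -> GroupComparison:
    """One-sided Welch two-sample t-test between two gene groups.

    ``direction='greater'`` tests whether group A's mean exceeds group B's.
    The FDR-adjusted ``q`` is left unset; adjust a whole comparison family
    with :func:`fdr_adjust` and :func:`attach_q`.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    a = tab.loc[tab.index.intersection(sorted(set_a.in_network)), measure].to_numpy(dtype=float)
    b = tab.loc[tab.index.intersection(sorted(set_b.in_network)), measure].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_groups needs >=2 in-network genes per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return GroupComparison(
        group_a=set_a.origin,
        group_b=set_b.origin,
        measure=measure,
        direction=direction,
        t_statistic=float(res.statistic),
        p=float(res.pvalue),
    )


def fdr_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def attach_q(comparisons: list[GroupComparison]) -> list[GroupComparison]:
    """Fill the ``q`` field across one family of comparisons."""
    qs = fdr_adjust([c.p for c in comparisons])
    return [replace(c, q=q) for c, q in zip(comparisons, qs)]
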