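"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and, where feasible,
library shortcuts) so each measure is checked against a second route.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(edges) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def floyd_warshall(nodes, edges) -> dict[tuple[str, str], float]:
    """All-pairs shortest paths by the classic triple loop (inf = no path)."""
    nodes = sorted(nodes)
    d = {(u, v): (0 if u == v else math.inf) for u in nodes for v in nodes}
    for a, b in edges:
        d[(a, b)] = 1
        d[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            dik = d[(i, k)]
            if dik is math.inf:
                continue
            for j in nodes:
                alt = dik + d[(k, j)]
                if alt < d[(i, j)]:
                    d[(i, j)] = alt
    return d


def fill_disconnected(d: dict) -> tuple[dict, int]:
    """Apply the max-finite-shortest-path fill; returns (filled, fill value)."""
    finite = [v for v in d.values() if v is not math.inf and v > 0]
    fill = max(finite) if finite else 0
    return ({k: (fill if v is math.inf else v) for k, v in d.items()}, int(fill))


def iad_bruteforce(dist: dict, genes) -> float:
    """Average of d_ij over all ordered pairs i != j, by double loop."""
    genes = sorted(genes)
    n = len(genes)
    total = sum(dist[(i, j)] for i in genes for j in genes if i != j)
    return total / (n * (n - 1))


def ied_bruteforce(dist: dict, p_genes, q_genes) -> float:
    """Sum of the two directional mean cross-distances, by double loop."""
    p_genes, q_genes = sorted(p_genes), sorted(q_genes)
    d_i = [sum(dist[(i, j)] for j in q_genes) / len(q_genes) for i in p_genes]
    d_j = [sum(dist[(i, j)] for i in p_genes) / len(p_genes) for j in q_genes]
    return sum(d_i) / len(p_genes) + sum(d_j) / len(q_genes)


def gdm_bruteforce(edges, assignment, retained, members, mode="incident"):
    """(e_intra, e_inter) counted straight off the edge list."""
    e_intra = e_inter = 0
    for a, b in edges:
        if mode == "induced":
            touching = a in members and b in members
        else:
            touching = a in members or b in members
        if not touching:
            continue
        if assignment[a] not in retained or assignment[b] not in retained:
            continue
        if assignment[a] == assignment[b]:
            e_intra += 1
        else:
            e_inter += 1
    return e_intra, e_inter


def betweenness_bruteforce(nodes, edges) -> dict[str, float]:
    """Unnormalized betweenness by exhaustive simple-path enumeration."""
    adj = adjacency(edges)
    nodes = sorted(nodes)

    def all_paths(s, t):
        stack = [(s, [s])]
        found = []
        while stack:
            v, path = stack.pop()
            if v == t:
                found.append(path)
                continue
            for w in adj.get(v, ()):
                if w not in path:
                    stack.append((w, path + [w]))
        return found

    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for p in sps:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sps)
    return bc


def local_clustering_bruteforce(edges, node) -> float:
    """Triangles over open triples for one node, counted directly."""
    adj = adjacency(edges)
    nbrs = sorted(adj.get(node, ()))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for u, v in combinations(nbrs, 2) if v in adj.get(u, ()))
    return 2.0 * links / (k * (k - 1))


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(pvalues)
    indexed = sorted(enumerate(pvalues), key=lambda t: t[1])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        idx, p = indexed[rank - 1]
        prev = min(prev, p * m / rank)
        adj[idx] = prev
    return adj


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via exact integer sums."""
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(n, K) + 1))
    return num / math.comb(N, n)


def ks_statistic_bruteforce(a, b, alternative) -> float:
    """Signed max ECDF difference by scanning every observed value."""
    a, b = sorted(a), sorted(b)
    best = 0.0
    for x in a + b:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        diff = fa - fb if alternative == "less" else fb - fa
        best = max(best, diff)
    return best


def set_partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_bruteforce(nodes, edges, blocks) -> float:
    m = len(edges)
    adj = adjacency(edges)
    deg = {v: len(adj.get(v, ())) for v in nodes}
    q = 0.0
    for block in blocks:
        bset = set(block)
        intra = sum(1 for a, b in edges if a in bset and b in bset)
        dsum = sum(deg[v] for v in block)
        q += intra / m - (dsum / (2 * m)) ** 2
    return q
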