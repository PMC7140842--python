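"""Module detection by greedy modularity maximization and the per-set
within/between-module edge statistic.

The detector is a deterministic multi-step greedy agglomerator: starting
from singleton communities, each sweep merges every pair of communities
that are each other's best positive-modularity-gain partner (ties broken
by the lexicographically smallest partner label), and stops when no merge
improves modularity. Modules below the retention size are kept in the
partition but excluded from the ``retained`` set. External partitions (e.g.
from another community-detection tool) can be imported from a two-column
TSV and used interchangeably.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from netprops.genesets import MappedGeneSet
from netprops.network_io import Network

__all__ = [
    "ModulePartition",
    "GDMResult",
    "detect_modules",
    "partition_modularity",
    "partition_from_assignment",
    "read_partition",
    "write_partition",
    "gdm",
]


@dataclass(frozen=True)
class ModulePartition:
    """Node -> module-id map plus the size-retention filter outcome."""

    assignment: dict[str, int]
    retained: frozenset[int]
    min_size: int
    modularity: float

    def module_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, module_id: int) -> frozenset[str]:
        return frozenset(n for n, m in self.assignment.items() if m == module_id)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = defaultdict(int)
        for m in self.assignment.values():
            out[m] += 1
        return dict(out)


@dataclass(frozen=True)
class GDMResult:
    set_name: str
    e_intra: int
    e_inter: int
    gdm: float | None
    mode: str


def partition_modularity(net: Network, assignment: dict[str, int]) -> float:
    """Newman modularity Q of a partition: within-module edge fraction minus
    its degree-based expectation."""
    m = net.n_edges
    if m == 0:
        return 0.0
    g = net.graph
    intra: dict[int, int] = defaultdict(int)
    deg: dict[int, int] = defaultdict(int)
    for a, b in net.edges:
        if assignment[a] == assignment[b]:
            intra[assignment[a]] += 1
    for n in net.nodes:
        deg[assignment[n]] += g.degree(n)
    q = 0.0
    for c in set(assignment.values()):
        q += intra.get(c, 0) / m - (deg.get(c, 0) / (2 * m)) ** 2
    return q


def detect_modules(net: Network, min_size: int = 30, seed: int | None = None) -> ModulePartition:
    """Deterministic multi-step greedy modularity maximization.

    ``seed`` is accepted for interface uniformity but unused: the algorithm
    is fully deterministic given the tie-break rule. Communities never
    bridge connected components (cross-component merges always have
    negative gain).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = net.graph
    m = net.n_edges
    if m == 0:
        assignment = {n: i for i, n in enumerate(sorted(net.nodes))}
        return ModulePartition(assignment, frozenset(), min_size, 0.0)

    # community label = lexicographically smallest member node
    members: dict[str, set[str]] = {n: {n} for n in net.nodes}
    deg: dict[str, int] = {n: g.degree(n) for n in net.nodes}
    between: dict[str, dict[str, int]] = {n: {} for n in net.nodes}
    for a, b in net.edges:
        between[a][b] = between[a].get(b, 0) + 1
        between[b][a] = between[b].get(a, 0) + 1

    two_m_sq = float(2 * m) ** 2
    while True:
        # best positive-gain partner per community (ties: lexicographically
        # smallest). Merging only mutual-best pairs keeps the sweep greedy
        # while preventing a community whose preferred partners are taken
        # from falling back to a poor merge; the lexicographically minimal
        # maximum-gain pair is always mutual, so progress is guaranteed.
        best: dict[str, tuple[float, str]] = {}
        for u, nbrs in between.items():
            for v, euv in sorted(nbrs.items()):
                gain = euv / m - deg[u] * deg[v] / two_m_sq
                if gain > 1e-15 and (u not in best or gain > best[u][0] + 1e-15):
                    best[u] = (gain, v)
        merges = sorted((u, v) for u, (_, v) in best.items() if u < v and best.get(v, (0, ""))[1] == u)
        if not merges:
            break
        for u, v in merges:  # u < v; merged label is u
            members[u] |= members.pop(v)
            deg[u] += deg.pop(v)
            vn = between.pop(v)
            un = between[u]
            un.pop(v, None)
            for w, evw in vn.items():
                if w == u:
                    continue
                un[w] = un.get(w, 0) + evw
                bw = between[w]
                bw.pop(v, None)
                bw[u] = un[w]

    comms = sorted(members.values(), key=lambda c: (-len(c), min(c)))
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    retained = frozenset(i for i, c in enumerate(comms) if len(c) >= min_size)
    q = partition_modularity(net, assignment)
    return ModulePartition(assignment, retained, min_size, q)


def partition_from_assignment(net: Network, assignment: dict[str, int], min_size: int = 30) -> ModulePartition:
    """Wrap an externally produced node -> module map (e.g. an imported
    partition) with the retention filter and a fresh Q computation."""
    missing = net.nodes - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} network nodes (e.g. {sorted(missing)[:3]})")
    sizes: dict[int, int] = defaultdict(int)
    for n in net.nodes:
        sizes[assignment[n]] += 1
    sub = {n: assignment[n] for n in net.nodes}
    retained = frozenset(mid for mid, s in sizes.items() if s >= min_size)
    return ModulePartition(sub, retained, min_size, partition_modularity(net, sub))


def read_partition(net: Network, path: str | Path, min_size: int = 30) -> ModulePartition:
    assignment: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: need node and module id")
            assignment[fields[0]] = int(fields[1])
    return partition_from_assignment(net, assignment, min_size=min_size)


def write_partition(part: ModulePartition, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for n in sorted(part.assignment):
            fh.write(f"{n}\t{part.assignment[n]}\n")


def gdm(
    net: Network,
    part: ModulePartition,
    s: MappedGeneSet,
    mode: str = "incident",
    count_outside_as_inter: bool = False,
) -> GDMResult:
    """Fraction of a set's qualifying edges that stay within one module.

    ``incident`` (default) classifies every network edge touching at least
    one set member; ``induced`` only edges with both endpoints in the set.
    By default edges with an endpoint outside the retained modules are
    excluded from both counts (set ``count_outside_as_inter`` to count them
    as between-module edges instead). When no edge qualifies the statistic
    is undefined and ``gdm`` is ``None``.
    """
    if mode not in ("incident", "induced"):
        raise ValueError(f"unknown mode {mode!r}")
    if not s.in_network:
        raise ValueError(f"set {s.origin}: no in-network genes")
    sset = s.in_network
    e_intra = 0
    e_inter = 0
    for a, b in net.edges:
        if mode == "induced":
            if a not in sset or b not in sset:
                continue
        elif a not in sset and b not in sset:
            continue
        a_in = part.assignment[a] in part.retained
        b_in = part.assignment[b] in part.retained
        if not (a_in and b_in):
            if count_outside_as_inter:
                e_inter += 1
            continue
        if part.assignment[a] == part.assignment[b]:
            e_intra += 1
        else:
            e_inter += 1
    denom = e_intra + e_inter
    value = e_intra / denom if denom > 0 else None
    return GDMResult(set_name=s.origin, e_intra=e_intra, e_inter=e_inter, gdm=value, mode=mode)
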