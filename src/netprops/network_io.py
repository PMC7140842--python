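"""Load, clean, and summarize undirected interaction networks from edge lists.

Edge lists are tab-separated files with two gene-symbol columns and an
optional numeric confidence score column. Cleaning removes self-loops,
collapses duplicate and reversed edges, and optionally drops edges whose
score falls strictly below a threshold (ties are kept). The whole network is
retained, including disconnected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = ["Network", "load_edge_list", "write_edge_list", "summarize_network"]


def _canon(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Network:
    """Undirected simple graph over gene symbols.

    Invariants: no self-loops, each undirected edge stored once in canonical
    (sorted) order, and every edge endpoint is a member of ``nodes``.
    ``nodes`` may include isolated symbols declared explicitly.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge ({a}, {b}) violates Network invariant")
            if a > b:
                raise ValueError(f"edge ({a}, {b}) not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) has endpoint outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def graph(self) -> nx.Graph:
        """networkx view of this network (cached; do not mutate)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        isolated: Iterable[str] = (),
        provenance: str = "",
    ) -> "Network":
        """Build a Network, dropping self-loops and collapsing duplicates."""
        canon = {_canon(a, b) for a, b in edges if a != b}
        nodes = {n for e in canon for n in e} | set(isolated)
        return cls(nodes=frozenset(nodes), edges=frozenset(canon), provenance=provenance)

    @classmethod
    def from_graph(cls, g: nx.Graph, provenance: str = "") -> "Network":
        return cls.from_edges(g.edges(), isolated=(n for n in g if g.degree(n) == 0), provenance=provenance)


def load_edge_list(
    path: str | Path,
    score_threshold: float | None = None,
    score_column: int = 2,
    node_file: str | Path | None = None,
) -> Network:
    """Parse a tab-separated edge list into a cleaned :class:`Network`.

    Parameters
    ----------
    path
        TSV file; ``#``-prefixed lines and blank lines are ignored. Each
        remaining line must carry at least two tab-separated fields
        (geneA, geneB[, score, ...]).
    score_threshold
        If given, edges with score strictly below the threshold are removed;
        edges scoring exactly the threshold are kept. The threshold is taken
        in the file's own scale (pass 600 for raw 0-1000 integer scores,
        0.6 for normalized scores) — no rescaling is applied.
    score_column
        0-based column index of the score (default 2, i.e. the third column).
    node_file
        Optional file listing one symbol per line; these are added as
        (possibly isolated) nodes.

    Raises
    ------
    ValueError
        If the file contains no edge lines ("no edges"), a line has fewer
        than two fields, or a score cannot be parsed when thresholding.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    saw_line = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            saw_line = True
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: need at least two tab-separated symbols")
            a, b = fields[0].strip(), fields[1].strip()
            if score_threshold is not None:
                if len(fields) <= score_column:
                    raise ValueError(f"{path}: line {lineno}: no score column at index {score_column}")
                try:
                    score = float(fields[score_column])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric score {fields[score_column]!r}"
                    ) from exc
                if score < score_threshold:
                    continue
            edges.append((a, b))
    if not saw_line:
        raise ValueError(f"{path}: no edges")

    isolated: list[str] = []
    if node_file is not None:
        with Path(node_file).open() as fh:
            isolated = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]

    filt = "" if score_threshold is None else f"; score>={score_threshold} (col {score_column})"
    return Network.from_edges(edges, isolated=isolated, provenance=f"{path.name}{filt}")


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the cleaned edge list as two-column TSV, sorted for determinism."""
    with Path(path).open("w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def summarize_network(net: Network) -> dict[str, int]:
    """Node count, edge count, and the maximum finite shortest-path length.

    ``max_finite_sp`` is the largest breadth-first distance over all connected
    node pairs (the longest finite shortest path anywhere in the network);
    0 if no pair is connected.
    """
    max_sp = 0
    g = net.graph
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            ecc = max(dists.values())
            if ecc > max_sp:
                max_sp = ecc
    return {"n_nodes": net.n_nodes, "n_edges": net.n_edges, "max_finite_sp": max_sp}
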