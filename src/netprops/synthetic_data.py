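"""Synthetic networks and planted gene sets for benchmarking and testing.

Two graph generators are provided: a planted-partition (stochastic block
model) graph with distinct within/between-block edge probabilities, and a
preferential-attachment (Barabasi-Albert) graph with a heavy-tailed degree
distribution. Gene sets can be planted with known structure — uniform
random, concentrated in chosen blocks, biased toward hubs, or compact
(a truncated BFS ball) — so every set-level measure has recoverable ground
truth. A miniature end-to-end study (network + gene sets + annotations +
run config) can be emitted for integration testing and documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import yaml

from netprops.genesets import GeneSet, write_gmt
from netprops.network_io import Network, write_edge_list

__all__ = [
    "SyntheticSpec",
    "PlantedSet",
    "generate_network",
    "plant_gene_set",
    "make_miniature_study",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network draw."""

    generator: str  # planted_partition | preferential_attachment
    n_nodes: int
    seed: int
    block_sizes: tuple[int, ...] = ()
    p_in: float = 0.0
    p_out: float = 0.0
    m_attach: int = 0

    def __post_init__(self) -> None:
        if self.generator == "planted_partition":
            if not self.block_sizes or sum(self.block_sizes) != self.n_nodes:
                raise ValueError("block_sizes must sum to n_nodes")
            if not (0.0 <= self.p_out <= self.p_in <= 1.0):
                raise ValueError("need 0 <= p_out <= p_in <= 1")
        elif self.generator == "preferential_attachment":
            if not (1 <= self.m_attach < self.n_nodes):
                raise ValueError("need 1 <= m_attach < n_nodes")
        else:
            raise ValueError(f"unknown generator {self.generator!r}")


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with a record of how it was constructed."""

    mode: str  # uniform | module_concentrated | hub_biased | compact
    size: int
    genes: frozenset[str]
    truth: dict = field(compare=False, default_factory=dict)

    def gene_set(self, name: str) -> GeneSet:
        return GeneSet(name=name, genes=self.genes, description=self.mode)


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(spec: SyntheticSpec) -> tuple[Network, dict[str, int]]:
    """Draw a network; returns it with the ground-truth block assignment
    (every node in block 0 for the preferential-attachment generator)."""
    if spec.generator == "planted_partition":
        k = len(spec.block_sizes)
        probs = [[spec.p_in if i == j else spec.p_out for j in range(k)] for i in range(k)]
        g = nx.stochastic_block_model(list(spec.block_sizes), probs, seed=spec.seed)
        truth_by_idx = {i: g.nodes[i]["block"] for i in g.nodes}
    else:
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.m_attach, seed=spec.seed)
        truth_by_idx = {i: 0 for i in g.nodes}
    mapping = {i: _node_name(i) for i in g.nodes}
    net = Network.from_edges(
        ((mapping[a], mapping[b]) for a, b in g.edges()),
        isolated=(mapping[i] for i in g.nodes if g.degree(i) == 0),
        provenance=f"synthetic:{spec.generator}(n={spec.n_nodes}, seed={spec.seed})",
    )
    return net, {mapping[i]: b for i, b in truth_by_idx.items()}


def plant_gene_set(
    net: Network,
    truth_partition: Mapping[str, int],
    mode: str,
    size: int,
    params: Mapping | None = None,
    seed: int | None = None,
) -> PlantedSet:
    """Sample a gene set of known construction from a network.

    modes and their params:
      uniform              — without-replacement uniform sample;
      module_concentrated  — ``target_blocks`` (list of block ids) and
                             ``rho``: fraction of members drawn from the
                             target blocks, remainder uniform elsewhere;
      hub_biased           — ``alpha``: sampling probability proportional to
                             degree**alpha (alpha=0 reduces to uniform);
      compact              — BFS ball grown from ``seed_node`` (random if
                             absent), truncated to ``size``.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    if size > len(nodes):
        raise ValueError(f"size {size} exceeds node pool {len(nodes)}")
    if size < 1:
        raise ValueError("size must be >= 1")

    if mode == "uniform":
        members = rng.choice(np.array(nodes, dtype=object), size=size, replace=False).tolist()
    elif mode == "module_concentrated":
        target = set(params["target_blocks"])
        rho = float(params.get("rho", 1.0))
        inside = [n for n in nodes if truth_partition.get(n) in target]
        outside = [n for n in nodes if truth_partition.get(n) not in target]
        n_in = min(round(rho * size), len(inside))
        n_out = size - n_in
        if n_out > len(outside):
            raise ValueError("pool too small outside target blocks")
        members = rng.choice(np.array(inside, dtype=object), size=n_in, replace=False).tolist()
        if n_out:
            members += rng.choice(np.array(outside, dtype=object), size=n_out, replace=False).tolist()
    elif mode == "hub_biased":
        alpha = float(params.get("alpha", 1.0))
        g = net.graph
        w = np.array([float(g.degree(n)) ** alpha if g.degree(n) > 0 or alpha == 0 else 0.0 for n in nodes])
        if np.count_nonzero(w) < size:
            raise ValueError("too few nodes with positive sampling weight")
        members = rng.choice(np.array(nodes, dtype=object), size=size, replace=False, p=w / w.sum()).tolist()
    elif mode == "compact":
        seed_node = params.get("seed_node") or str(rng.choice(np.array(nodes, dtype=object)))
        g = net.graph
        members = []
        # deterministic BFS order: sorted within each distance layer
        for _, layer in enumerate(nx.bfs_layers(g, seed_node)):
            for n in sorted(layer):
                members.append(n)
                if len(members) == size:
                    break
            if len(members) == size:
                break
        if len(members) < size:
            raise ValueError(f"component of {seed_node!r} smaller than requested size {size}")
        params["seed_node"] = seed_node
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return PlantedSet(
        mode=mode,
        size=size,
        genes=frozenset(members),
        truth={"mode": mode, "params": params, "seed": seed},
    )


def make_miniature_study(out_dir: str | Path, seed: int = 0, null_b: int = 50) -> dict[str, Path]:
    """Emit a complete miniature study the pipeline can run end to end.

    Writes a planted-partition network, nine module-concentrated "prognostic"
    sets, four contrast sets (two hub-biased, one uniform, one compact), a
    gene universe with off-network symbols, a small alias table, an
    annotation table with planted enriched terms, and a ready-to-run YAML
    config. Returns the path of every artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    spec = SyntheticSpec(
        generator="planted_partition",
        n_nodes=240,
        block_sizes=(60, 60, 60, 60),
        p_in=0.12,
        p_out=0.01,
        seed=seed,
    )
    net, truth = generate_network(spec)

    sets: list[GeneSet] = []
    for i in range(9):
        ps = plant_gene_set(
            net, truth, "module_concentrated", size=30,
            params={"target_blocks": [i % 4], "rho": 0.9}, seed=int(rng.integers(2**31)),
        )
        sets.append(ps.gene_set(f"S{i + 1}"))
    sets.append(plant_gene_set(net, truth, "hub_biased", 25, {"alpha": 2.0}, int(rng.integers(2**31))).gene_set("CA"))
    sets.append(plant_gene_set(net, truth, "hub_biased", 25, {"alpha": 1.0}, int(rng.integers(2**31))).gene_set("MA"))
    sets.append(plant_gene_set(net, truth, "uniform", 25, None, int(rng.integers(2**31))).gene_set("ES"))
    sets.append(plant_gene_set(net, truth, "compact", 25, None, int(rng.integers(2**31))).gene_set("HK"))

    paths = {
        "network": out / "network.tsv",
        "sets": out / "sets.gmt",
        "universe": out / "universe.txt",
        "aliases": out / "aliases.tsv",
        "annotations": out / "annotations.tsv",
        "config": out / "run.yaml",
    }
    write_edge_list(net, paths["network"])
    write_gmt(sets, paths["sets"])

    # universe = network genes plus off-network symbols that map to nothing
    extra = [f"X{i:05d}" for i in range(40)]
    with paths["universe"].open("w") as fh:
        for sym in sorted(net.nodes) + extra:
            fh.write(sym + "\n")

    with paths["aliases"].open("w") as fh:
        for n in sorted(net.nodes)[:10]:
            fh.write(f"alias_{n}\t{n}\n")

    # annotation table: one planted term per block (enriched in the sets
    # concentrated there), plus random terms and IEA decoys
    nodes = sorted(net.nodes)
    with paths["annotations"].open("w") as fh:
        for b in range(4):
            block_nodes = [n for n in nodes if truth[n] == b]
            for g in block_nodes[:40]:
                fh.write(f"{g}\tT:BLOCK{b}\tblock {b} process\tEXP\n")
        for t in range(4):
            pick = rng.choice(np.array(nodes, dtype=object), size=35, replace=False)
            for g in sorted(pick.tolist()):
                fh.write(f"{g}\tT:RAND{t}\trandom process {t}\tEXP\n")
        decoy = rng.choice(np.array(nodes, dtype=object), size=40, replace=False)
        for g in sorted(decoy.tolist()):
            fh.write(f"{g}\tT:IEA0\telectronic process\tIEA\n")

    config = {
        "network": {"path": "network.tsv", "score_threshold": None, "score_column": 2},
        "gene_sets": "sets.gmt",
        "alias_table": "aliases.tsv",
        "universe": "universe.txt",
        "null": {"b": null_b, "set_size": 20, "universe": "file"},
        "modules": {"min_size": 30},
        "gdm_mode": "incident",
        "enrichment": {
            "annotations": "annotations.tsv",
            "min_term": 30,
            "max_term": 300,
            "excluded_evidence": ["IEA"],
            "q_threshold": 0.05,
        },
        "seed": int(seed),
    }
    with paths["config"].open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
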