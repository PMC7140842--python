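"""Gene-set loading (GMT), symbol normalization, merging, and network mapping."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from netprops.network_io import Network

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "MappedGeneSet",
    "parse_gmt",
    "write_gmt",
    "load_alias_table",
    "normalize_symbols",
    "merge_sets",
    "recurrence_count",
    "map_to_network",
]


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols (set semantics: no duplicates)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MappedGeneSet:
    """A gene set partitioned by membership in a particular network."""

    origin: str
    in_network: frozenset[str]
    dropped: frozenset[str]

    def __post_init__(self) -> None:
        if self.in_network & self.dropped:
            raise ValueError("in_network and dropped overlap")

    @property
    def n_used(self) -> int:
        return len(self.in_network)


def parse_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, then one gene per column).

    Within-line duplicate symbols are collapsed. Duplicate set names are an
    error, as are lines with fewer than three fields.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs name, description, and >=1 gene")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.genes)]) + "\n")


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Load a two-column alias -> official-symbol TSV.

    An alias mapped to two different official symbols is an error; repeated
    identical rows are tolerated.
    """
    path = Path(path)
    table: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: need alias and official symbol")
            alias, official = fields[0].strip(), fields[1].strip()
            if alias in table and table[alias] != official:
                raise ValueError(
                    f"{path}: line {lineno}: alias {alias!r} maps to both {table[alias]!r} and {official!r}"
                )
            table[alias] = official
    return table


def normalize_symbols(sets: list[GeneSet], alias_table: Mapping[str, str]) -> list[GeneSet]:
    """Replace aliased symbols by their official symbol in every set.

    Symbols absent from the alias table are kept verbatim (a count is
    logged); post-mapping duplicates collapse under set semantics, so the
    operation is idempotent.
    """
    out: list[GeneSet] = []
    for s in sets:
        mapped = frozenset(alias_table.get(g, g) for g in s.genes)
        unmapped = sum(1 for g in s.genes if g not in alias_table)
        if alias_table and unmapped:
            logger.warning("set %s: %d/%d symbols not in alias table, kept verbatim", s.name, unmapped, s.size)
        out.append(GeneSet(name=s.name, genes=mapped, description=s.description))
    return out


def merge_sets(sets: list[GeneSet], new_name: str) -> GeneSet:
    """Union of member genes across sets, deduplicated."""
    if not sets:
        raise ValueError("merge_sets needs at least one input set")
    genes: frozenset[str] = frozenset().union(*(s.genes for s in sets))
    return GeneSet(name=new_name, genes=genes, description=f"union of {len(sets)} sets")


def recurrence_count(sets: list[GeneSet], min_times: int) -> frozenset[str]:
    """Symbols that appear in at least ``min_times`` distinct input sets."""
    if min_times < 2:
        raise ValueError("min_times must be >= 2")
    counts: dict[str, int] = {}
    for s in sets:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= min_times)


def map_to_network(s: GeneSet, net: Network) -> MappedGeneSet:
    """Partition a gene set by membership in the network's node set.

    All downstream set-level measures operate on the in-network genes only;
    the dropped fraction is logged (and is a warning when nothing maps).
    """
    in_net = frozenset(g for g in s.genes if g in net.nodes)
    dropped = s.genes - in_net
    if not in_net:
        logger.warning("set %s: no genes present in network (%d dropped)", s.name, len(dropped))
    elif dropped:
        logger.info("set %s: %d/%d genes not in network, dropped", s.name, len(dropped), s.size)
    return MappedGeneSet(origin=s.name, in_network=in_net, dropped=dropped)
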