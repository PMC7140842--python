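"""Fisher-test functional enrichment with term-size and evidence filters.

Annotations are carried as a four-column TSV (gene, term id, term name,
evidence code). Loading drops excluded evidence codes first (default: the
electronically-inferred code IEA), restricts genes to the declared
background (typically the network's gene set), and then keeps only terms
whose within-background size lies in a closed interval (default [30, 300]).
Enrichment is a one-sided Fisher exact test per term with Benjamini-
Hochberg adjustment across all tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from netprops.centrality import fdr_adjust
from netprops.genesets import MappedGeneSet
from netprops.modules_gdm import ModulePartition

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "load_annotations",
    "fisher_enrichment",
    "modules_with_min_sets",
    "term_intersection",
    "convert_gaf",
]


@dataclass(frozen=True)
class AnnotationTable:
    """Deduplicated (gene, term) records surviving the paper-style filters."""

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str]
    background: frozenset[str]

    @property
    def term_sizes(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.term_to_genes.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float


def load_annotations(
    path: str | Path,
    background: Iterable[str],
    min_term: int = 30,
    max_term: int = 300,
    excluded_evidence: Iterable[str] = ("IEA",),
) -> AnnotationTable:
    """Load and filter a gene/term/name/evidence TSV.

    Filter order: excluded evidence codes dropped first, then genes outside
    the background, then terms whose within-background size falls outside
    the closed interval [min_term, max_term].
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background must be non-empty")
    excluded = set(excluded_evidence)
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: need gene, term id, term name, evidence")
            gene, term_id, term_name, evidence = (f.strip() for f in fields[:4])
            if evidence in excluded:
                continue
            if gene not in bg:
                continue
            term_genes.setdefault(term_id, set()).add(gene)
            term_names.setdefault(term_id, term_name)
    kept = {t: frozenset(g) for t, g in term_genes.items() if min_term <= len(g) <= max_term}
    gene_to_terms: dict[str, set[str]] = {}
    for t, genes in kept.items():
        for g in genes:
            gene_to_terms.setdefault(g, set()).add(t)
    return AnnotationTable(
        gene_to_terms={g: frozenset(t) for g, t in gene_to_terms.items()},
        term_to_genes=kept,
        term_names={t: term_names[t] for t in kept},
        background=bg,
    )


def fisher_enrichment(
    query: MappedGeneSet, ann: AnnotationTable, q_threshold: float = 0.05
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation test for every annotated term.

    Per term the 2x2 table is (k, n-k, K-k, N-K-n+k) with N the background
    size, n the query size within the background, K the term size, and k
    their overlap; p is the hypergeometric upper tail P(X >= k). q-values
    are Benjamini-Hochberg across all tested terms; only results with
    q < q_threshold are returned, sorted by ascending p (term id breaks
    ties). Pass ``q_threshold=1.01`` to obtain every tested term.
    """
    qgenes = query.in_network & ann.background
    if not qgenes:
        raise ValueError(f"query {query.origin}: no genes in background")
    n = len(qgenes)
    big_n = len(ann.background)
    terms = sorted(ann.term_to_genes)
    rows = []
    for t in terms:
        tg = ann.term_to_genes[t]
        k = len(qgenes & tg)
        big_k = len(tg)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((t, k, big_k, min(p, 1.0)))
    qs = fdr_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term_id=t, term_name=ann.term_names[t], k=k, n=n, K=big_k, N=big_n, p=p, q=q)
        for (t, k, big_k, p), q in zip(rows, qs)
        if q < q_threshold
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def modules_with_min_sets(
    part: ModulePartition,
    sets: Sequence[MappedGeneSet],
    min_sets: int = 2,
    min_genes_per_set: int = 1,
) -> list[tuple[int, list[str]]]:
    """Retained modules containing genes from at least ``min_sets`` distinct
    input sets (each contributing >= ``min_genes_per_set`` genes)."""
    out = []
    for mid in sorted(part.retained):
        members = part.members(mid)
        contributing = sorted(
            s.origin for s in sets if len(members & s.in_network) >= min_genes_per_set
        )
        if len(contributing) >= min_sets:
            out.append((mid, contributing))
    return out


def term_intersection(
    results_a: Sequence[EnrichmentResult], results_b: Sequence[EnrichmentResult]
) -> list[tuple[str, float]]:
    """Terms enriched in both result lists, scored by the larger of the two
    adjusted p-values, ascending."""
    qa = {r.term_id: r.q for r in results_a}
    qb = {r.term_id: r.q for r in results_b}
    common = [(t, max(qa[t], qb[t])) for t in qa.keys() & qb.keys()]
    common.sort(key=lambda x: (x[1], x[0]))
    return common


def convert_gaf(path_in: str | Path, path_out: str | Path) -> int:
    """Convert a GAF 2.x subset to the four-column annotation TSV.

    Uses the DB object symbol, GO id, and evidence columns; the term name
    column is filled with the GO id (GAF carries no term names). Ontology
    ancestor propagation is NOT applied. Returns the number of records
    written.
    """
    n = 0
    with Path(path_in).open() as src, Path(path_out).open("w") as dst:
        for raw in src:
            if raw.startswith("!") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 7:
                continue
            symbol, go_id, evidence = fields[2], fields[4], fields[6]
            dst.write(f"{symbol}\t{go_id}\t{go_id}\t{evidence}\n")
            n += 1
    return n
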