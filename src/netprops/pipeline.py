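"""End-to-end pipeline: from a declarative config to a reproducible report
bundle of per-stage TSVs plus a JSON manifest."""

from __future__ import annotations

import itertools
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

import netprops
from netprops import centrality as ct
from netprops import enrichment as en
from netprops import genesets as gs
from netprops import modules_gdm as mg
from netprops import network_io as nio
from netprops import nullstats as ns
from netprops import setmetrics as sm

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    network_path: Path
    gene_sets_path: Path
    score_threshold: float | None = None
    score_column: int = 2
    alias_table: Path | None = None
    universe: Path | None = None
    null_b: int = 1000
    null_set_size: int = 120
    null_universe: str = "file"  # file | network
    module_min_size: int = 30
    module_assignment: Path | None = None
    gdm_mode: str = "incident"
    annotations: Path | None = None
    min_term: int = 30
    max_term: int = 300
    excluded_evidence: tuple[str, ...] = ("IEA",)
    q_threshold: float = 0.05
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; errors name the offending field."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def resolve(p: str | None) -> Path | None:
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    net = raw.get("network") or {}
    if not net.get("path"):
        raise ValueError("config field network.path is required")
    if not raw.get("gene_sets"):
        raise ValueError("config field gene_sets is required")
    null = raw.get("null") or {}
    modules = raw.get("modules") or {}
    enr = raw.get("enrichment") or {}
    cfg = RunConfig(
        network_path=resolve(net["path"]),
        score_threshold=net.get("score_threshold"),
        score_column=int(net.get("score_column", 2)),
        gene_sets_path=resolve(raw["gene_sets"]),
        alias_table=resolve(raw.get("alias_table")),
        universe=resolve(raw.get("universe")),
        null_b=int(null.get("b", 1000)),
        null_set_size=int(null.get("set_size", 120)),
        null_universe=str(null.get("universe", "file")),
        module_min_size=int(modules.get("min_size", 30)),
        module_assignment=resolve(modules.get("assignment")),
        gdm_mode=str(raw.get("gdm_mode", "incident")),
        annotations=resolve(enr.get("annotations")),
        min_term=int(enr.get("min_term", 30)),
        max_term=int(enr.get("max_term", 300)),
        excluded_evidence=tuple(enr.get("excluded_evidence", ["IEA"])),
        q_threshold=float(enr.get("q_threshold", 0.05)),
        seed=int(raw.get("seed", 0)),
    )
    for fieldname, p in [
        ("network.path", cfg.network_path),
        ("gene_sets", cfg.gene_sets_path),
        ("alias_table", cfg.alias_table),
        ("universe", cfg.universe),
        ("modules.assignment", cfg.module_assignment),
        ("enrichment.annotations", cfg.annotations),
    ]:
        if p is not None and not p.exists():
            raise FileNotFoundError(f"config field {fieldname}: path {p} does not exist")
    if cfg.null_b < 1 or cfg.null_set_size < 2:
        raise ValueError("config fields null.b and null.set_size must be >= 1 and >= 2")
    if cfg.null_universe not in ("file", "network"):
        raise ValueError("config field null.universe must be 'file' or 'network'")
    if cfg.gdm_mode not in ("incident", "induced"):
        raise ValueError("config field gdm_mode must be 'incident' or 'induced'")
    return cfg


def _write_tsv(df: pandas.DataFrame, path: Path, float_fmt: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the manifest.

    Stages: network load/summary, gene-set mapping, centralities and group
    comparisons, set metrics (clustering coefficient + intra-set distance)
    and the pairwise inter-set distance matrix, module detection and the
    per-set module statistic, random-set nulls with KS and permutation
    tests, and (if annotations are configured) per-set enrichment plus the
    shared-module / term-intersection analysis. Deterministic given seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "netprops", "version": netprops.__version__},
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(cfg).items()},
        "stages": {},
        "failure_stage": None,
    }
    stage = "network"
    try:
        net = nio.load_edge_list(cfg.network_path, score_threshold=cfg.score_threshold, score_column=cfg.score_column)
        summary = nio.summarize_network(net)
        nio.write_edge_list(net, out / "cleaned_edges.tsv")
        with (out / "network_summary.tsv").open("w") as fh:
            for k, v in summary.items():
                fh.write(f"{k}\t{v}\n")
        manifest["stages"][stage] = summary
        logger.info("network: %(n_nodes)d nodes, %(n_edges)d edges", summary)

        stage = "genesets"
        sets = gs.parse_gmt(cfg.gene_sets_path)
        if cfg.alias_table is not None:
            sets = gs.normalize_symbols(sets, gs.load_alias_table(cfg.alias_table))
        mapped = [gs.map_to_network(s, net) for s in sets]
        mapped = [m for m in mapped if m.in_network]
        _write_tsv(
            pandas.DataFrame(
                [(m.origin, m.n_used + len(m.dropped), m.n_used, len(m.dropped)) for m in mapped],
                columns=["set", "n_total", "n_in_network", "n_dropped"],
            ),
            out / "sets_mapping.tsv",
        )
        manifest["stages"][stage] = {"n_sets": len(sets), "n_usable": len(mapped)}

        stage = "centrality"
        sp = sm.shortest_paths(net)
        tab = ct.compute_centralities(net, sp=sp)
        tab.reset_index().to_csv(out / "centralities.tsv", sep="\t", index=False, float_format="%.10g")
        comparisons = []
        eligible = [m for m in mapped if m.n_used >= 2]
        for (a, b), measure in itertools.product(itertools.combinations(eligible, 2), ct.MEASURES):
            comparisons.append(ct.compare_groups(tab, a, b, measure, direction="greater"))
        comparisons = ct.attach_q(comparisons)
        _write_tsv(
            pandas.DataFrame(
                [(c.group_a, c.group_b, c.measure, c.direction, c.t_statistic, c.p, c.q) for c in comparisons],
                columns=["group_a", "group_b", "measure", "direction", "t", "p", "q"],
            ),
            out / "comparisons.tsv",
        )
        manifest["stages"][stage] = {
            "background_means": {m: ct.background_mean(tab, m) for m in ct.MEASURES},
            "n_comparisons": len(comparisons),
        }

        stage = "setmetrics"
        rows = []
        for m in mapped:
            cc = sm.set_clustering_coefficient(net, m)
            iad = sm.intra_set_distance(sp, m).iad if m.n_used >= 2 else float("nan")
            rows.append((m.origin, m.n_used, len(m.dropped), cc, iad))
        _write_tsv(pandas.DataFrame(rows, columns=["set", "n_used", "n_dropped", "cc", "iad"]), out / "set_metrics.tsv")
        ied_rows = []
        for a, b in itertools.combinations(mapped, 2):
            r = sm.inter_set_distance(sp, a, b)
            ied_rows.append((r.set_p, r.set_q, r.n_p, r.n_q, r.mean_p_to_q, r.mean_q_to_p, r.ied))
        _write_tsv(
            pandas.DataFrame(
                ied_rows, columns=["set_p", "set_q", "n_p", "n_q", "mean_p_to_q", "mean_q_to_p", "ied"]
            ),
            out / "ied_matrix.tsv",
        )
        manifest["stages"][stage] = {"n_sets": len(rows), "n_pairs": len(ied_rows)}

        stage = "modules"
        if cfg.module_assignment is not None:
            part = mg.read_partition(net, cfg.module_assignment, min_size=cfg.module_min_size)
        else:
            part = mg.detect_modules(net, min_size=cfg.module_min_size, seed=cfg.seed)
        mg.write_partition(part, out / "modules.tsv")
        gdm_rows = []
        for m in mapped:
            r = mg.gdm(net, part, m, mode=cfg.gdm_mode)
            gdm_rows.append((r.set_name, r.mode, r.e_intra, r.e_inter, r.gdm))
        _write_tsv(pandas.DataFrame(gdm_rows, columns=["set", "mode", "e_intra", "e_inter", "gdm"]), out / "gdm.tsv")
        manifest["stages"][stage] = {
            "n_modules": len(part.module_ids()),
            "n_retained": len(part.retained),
            "modularity": part.modularity,
        }

        stage = "null"
        if cfg.null_universe == "file":
            if cfg.universe is None:
                raise ValueError("config field universe is required when null.universe='file'")
            with cfg.universe.open() as fh:
                universe = [ln.strip() for ln in fh if ln.strip()]
        else:
            universe = sorted(net.nodes)
        rand_sets = ns.sample_random_sets(universe, set_size=cfg.null_set_size, b=cfg.null_b, seed=cfg.seed)
        merged_ref = gs.map_to_network(gs.merge_sets(sets, "ALL"), net)
        null_rows, test_rows = [], []
        for measure in ("cc", "iad", "gdm", "ied"):
            null = ns.null_distribution(
                net, sp, part, rand_sets, measure,
                reference=merged_ref if measure == "ied" else None,
                gdm_mode=cfg.gdm_mode, seed=cfg.seed,
            )
            for i, v in enumerate(null.values):
                null_rows.append((measure, i, v))
            observed = {
                "cc": {r[0]: r[3] for r in rows},
                "iad": {r[0]: r[4] for r in rows if r[4] == r[4]},
                "gdm": {r[0]: r[4] for r in gdm_rows if r[4] is not None},
                "ied": {f"{a}|{b}": v for a, b, *_, v in ied_rows},
            }[measure]
            direction = {"cc": "greater", "iad": "less", "gdm": "greater", "ied": "less"}[measure]
            if observed:
                ks = ns.ks_one_sided(list(observed.values()), list(null.values), alternative=direction)
                test_rows.append(("ALL_SETS", measure, "ks_one_sided", direction, ks.statistic, ks.p))
            for name, v in observed.items():
                pr = ns.permutation_p(v, null, alternative=direction)
                test_rows.append((name, measure, "permutation", direction, v, pr.p))
            manifest["stages"].setdefault(stage, {})[measure] = {
                "b": null.b, "n_values": len(null.values), "n_dropped": null.n_dropped,
                "set_size": cfg.null_set_size,
            }
        _write_tsv(pandas.DataFrame(null_rows, columns=["measure", "replicate", "value"]), out / "null_values.tsv")
        _write_tsv(
            pandas.DataFrame(test_rows, columns=["set", "measure", "method", "alternative", "statistic", "p"]),
            out / "null_tests.tsv",
        )

        stage = "enrichment"
        if cfg.annotations is not None:
            ann = en.load_annotations(
                cfg.annotations, background=net.nodes, min_term=cfg.min_term,
                max_term=cfg.max_term, excluded_evidence=cfg.excluded_evidence,
            )
            enr_rows = []
            for m in mapped:
                for r in en.fisher_enrichment(m, ann, q_threshold=cfg.q_threshold):
                    enr_rows.append((m.origin, r.term_id, r.term_name, r.k, r.n, r.K, r.N, r.p, r.q))
            _write_tsv(
                pandas.DataFrame(enr_rows, columns=["set", "term_id", "term_name", "k", "n", "K", "N", "p", "q"]),
                out / "enrichment.tsv",
            )
            shared = en.modules_with_min_sets(part, mapped, min_sets=2)
            with (out / "shared_modules.tsv").open("w") as fh:
                for mid, names in shared:
                    fh.write(f"{mid}\t{','.join(names)}\n")
            inter_rows = []
            module_enr = {}
            for mid, _names in shared:
                mm = gs.MappedGeneSet(origin=f"module_{mid}", in_network=part.members(mid), dropped=frozenset())
                module_enr[mid] = en.fisher_enrichment(mm, ann, q_threshold=cfg.q_threshold)
            for (ma, ra), (mb, rb) in itertools.combinations(module_enr.items(), 2):
                for term, combined in en.term_intersection(ra, rb):
                    inter_rows.append((f"module_{ma}", f"module_{mb}", term, combined))
            _write_tsv(
                pandas.DataFrame(inter_rows, columns=["module_a", "module_b", "term_id", "combined_p"]),
                out / "intersections.tsv",
            )
            manifest["stages"][stage] = {
                "n_terms": len(ann.term_to_genes),
                "n_enriched_rows": len(enr_rows),
                "n_shared_modules": len(shared),
            }
        else:
            manifest["stages"][stage] = "skipped (no annotations configured)"
    except Exception as exc:
        manifest["failure_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
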