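# netprops

Topological analysis of gene sets in protein–protein interaction networks.

Given an undirected interactome (tab-separated edge list, optionally with a
confidence score column) and named gene sets (GMT), `netprops` computes:

* **node centralities** — degree, unnormalized betweenness, closeness (with a
  max-finite-shortest-path fill for unreachable pairs), and max-normalized
  eigenvector centrality — plus one-tailed Welch t-test comparisons between
  gene groups with Benjamini–Hochberg FDR adjustment;
* **set-level distance measures** — intra-set distance (mean shortest-path
  distance over all pairs of distinct genes in a set) and inter-set distance
  (sum of the two directional mean cross-distances between two sets), using
  the convention that disconnected node pairs are assigned the network's
  maximum finite shortest-path length;
* **set clustering coefficient** — mean local clustering coefficient of
  members, on the full network or on the induced subgraph;
* **module statistics** — deterministic greedy modularity-based module
  detection with a minimum-size retention filter (default ≥ 30 genes),
  external partition import, and a per-set within/between-module edge
  fraction (`incident` and `induced` counting modes);
* **null testing** — random gene sets sampled from a declared universe
  (default 1000 draws of 120 genes), one-sided two-sample KS tests, and
  permutation p-values with add-one smoothing;
* **functional enrichment** — one-sided Fisher exact tests against the
  network background with term-size filtering (default 30–300 genes within
  background), evidence-code exclusion (default IEA), FDR control, and a
  shared-module / term-intersection analysis (combined p = the larger of the
  two adjusted p-values);
* **synthetic benchmarks** — planted-partition and preferential-attachment
  generators with uniform, module-concentrated, hub-biased, and compact
  planted gene sets, so every measure has recoverable ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (brute-force
formula oracles, convention and filter checks, planted-structure recovery,
and null-calibration checks).

## CLI

Generate a self-contained synthetic study and run the whole pipeline on it:

```sh
netprops synth --out fixtures/ --seed 1
netprops run --config fixtures/run.yaml --out report/
```

The report bundle contains per-stage TSVs (cleaned edge list, network
summary, centralities, group comparisons, per-set metrics, pairwise
inter-set distances, module assignment, per-set module statistics, null
values and tests, enrichment, shared modules, term intersections) and a
`manifest.json` echoing versions, seeds, parameters, and dropped-gene
counts. Re-running with the same config and seed reproduces every numeric
output byte-for-byte.

Each stage is also exposed individually — `load-network`, `set-metrics`,
`modules`, `gdm`, `null`, `enrich` — e.g.:

```sh
netprops load-network string_links.tsv cleaned.tsv --score-threshold 600 --summary summary.tsv
netprops modules --network cleaned.tsv --min-size 30 --out modules.tsv
netprops null --network cleaned.tsv --gmt sets.gmt --measure iad --b 1000 --set-size 120 --seed 7 --out tests.tsv
```

Score thresholds are interpreted in the file's own scale (pass `600` for raw
0–1000 integer scores, `0.6` for normalized ones); edges scoring exactly the
threshold are kept.

## Library use

```python
from netprops import (
    load_edge_list, parse_gmt, map_to_network, shortest_paths,
    intra_set_distance, detect_modules, gdm,
)

net = load_edge_list("edges.tsv", score_threshold=0.6)
sets = parse_gmt("sets.gmt")
sp = shortest_paths(net)
mapped = map_to_network(sets[0], net)
print(intra_set_distance(sp, mapped))
part = detect_modules(net, min_size=30)
print(gdm(net, part, mapped))
```
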