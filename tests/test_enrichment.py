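import numpy as np
import pytest

from netprops.enrichment import (
    EnrichmentResult,
    convert_gaf,
    fisher_enrichment,
    load_annotations,
    modules_with_min_sets,
    term_intersection,
)
from netprops.genesets import MappedGeneSet
from netprops.modules_gdm import partition_from_assignment
from netprops.network_io import Network

from tests.oracles import hypergeom_upper_tail


def write_annotations(tmp_path, rows, name="ann.tsv"):
    p = tmp_path / name
    p.write_text("".join("\t".join(r) + "\n" for r in rows))
    return p


def mk_query(genes, name="Q"):
    return MappedGeneSet(origin=name, in_network=frozenset(genes), dropped=frozenset())


class TestLoadAnnotations:
    def test_term_size_boundaries_inclusive(self, tmp_path):
        bg = [f"g{i}" for i in range(400)]
        rows = []
        for size, tid in [(29, "T29"), (30, "T30"), (300, "T300"), (301, "T301")]:
            rows += [(f"g{i}", tid, tid, "EXP") for i in range(size)]
        p = write_annotations(tmp_path, rows)
        ann = load_annotations(p, background=bg)
        assert set(ann.term_to_genes) == {"T30", "T300"}
        assert ann.term_sizes == {"T30": 30, "T300": 300}

    def test_iea_dropped_regardless_of_size(self, tmp_path):
        bg = [f"g{i}" for i in range(100)]
        rows = [(f"g{i}", "T", "name", "IEA") for i in range(50)]
        ann = load_annotations(write_annotations(tmp_path, rows), background=bg, min_term=1, max_term=100)
        assert ann.term_to_genes == {}

    def test_gene_outside_background_ignored_in_sizes(self, tmp_path):
        bg = [f"g{i}" for i in range(10)]
        rows = [(f"g{i}", "T", "n", "EXP") for i in range(5)] + [("offbg", "T", "n", "EXP")]
        ann = load_annotations(write_annotations(tmp_path, rows), background=bg, min_term=1, max_term=10)
        assert ann.term_sizes == {"T": 5}

    def test_duplicate_records_collapse(self, tmp_path):
        bg = ["a", "b", "c"]
        rows = [("a", "T", "n", "EXP"), ("a", "T", "n", "IDA"), ("b", "T", "n", "EXP")]
        ann = load_annotations(write_annotations(tmp_path, rows), background=bg, min_term=1, max_term=5)
        assert ann.term_sizes == {"T": 2}

    def test_malformed_record_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tT\tname\tEXP\nonly\tthree\tfields\n")
        with pytest.raises(ValueError, match="line 2"):
            load_annotations(p, background=["a"])

    def test_empty_background_rejected(self, tmp_path):
        p = write_annotations(tmp_path, [("a", "T", "n", "EXP")])
        with pytest.raises(ValueError):
            load_annotations(p, background=[])


class TestFisherEnrichment:
    def make_table(self, tmp_path, big_n, term_sets):
        bg = [f"g{i}" for i in range(big_n)]
        rows = []
        for tid, members in term_sets.items():
            rows += [(g, tid, tid, "EXP") for g in members]
        ann = load_annotations(write_annotations(tmp_path, rows), background=bg, min_term=1, max_term=big_n)
        return bg, ann

    def test_p_matches_hypergeometric_tail(self, tmp_path):
        big_n, n, big_k, k = 1000, 100, 30, 10
        bg = [f"g{i}" for i in range(big_n)]
        term = [f"g{i}" for i in range(big_k)]  # first k genes shared with query
        query = mk_query([f"g{i}" for i in range(k)] + [f"g{i}" for i in range(500, 500 + n - k)])
        rows = [(g, "T", "T", "EXP") for g in term]
        ann = load_annotations(write_annotations(tmp_path, rows), background=bg, min_term=1, max_term=big_n)
        res = fisher_enrichment(query, ann, q_threshold=1.01)
        assert len(res) == 1
        assert (res[0].k, res[0].n, res[0].K, res[0].N) == (k, n, big_k, big_n)
        assert res[0].p == pytest.approx(hypergeom_upper_tail(k, big_n, big_k, n), rel=1e-9)

    def test_zero_overlap_p_is_one_and_never_reported(self, tmp_path):
        bg, ann = self.make_table(tmp_path, 50, {"T": [f"g{i}" for i in range(10)]})
        query = mk_query([f"g{i}" for i in range(40, 50)])
        res = fisher_enrichment(query, ann, q_threshold=1.01)
        assert res[0].k == 0
        assert res[0].p >= 0.5
        assert fisher_enrichment(query, ann, q_threshold=0.05) == []

    def test_query_equals_background_degenerate(self, tmp_path):
        bg, ann = self.make_table(tmp_path, 30, {"T": [f"g{i}" for i in range(8)]})
        res = fisher_enrichment(mk_query(bg), ann, q_threshold=1.01)
        assert res[0].k == res[0].K
        assert res[0].p == pytest.approx(1.0)

    def test_empty_query_rejected(self, tmp_path):
        bg, ann = self.make_table(tmp_path, 20, {"T": [f"g{i}" for i in range(5)]})
        with pytest.raises(ValueError):
            fisher_enrichment(mk_query(["nothere"]), ann)

    def test_removing_query_gene_never_decreases_p(self, tmp_path):
        rng = np.random.default_rng(7)
        bg = [f"g{i}" for i in range(60)]
        term = rng.choice(bg, size=20, replace=False).tolist()
        query_genes = rng.choice(bg, size=15, replace=False).tolist()
        in_term = [g for g in query_genes if g in term]
        if not in_term:
            pytest.skip("no overlap drawn")
        bg2, ann = self.make_table(tmp_path, 60, {"T": term})
        p_full = fisher_enrichment(mk_query(query_genes), ann, q_threshold=1.01)[0].p
        reduced = [g for g in query_genes if g != in_term[0]]
        p_red = fisher_enrichment(mk_query(reduced), ann, q_threshold=1.01)[0].p
        assert p_red >= p_full - 1e-12

    def test_q_monotone_in_p_ranking(self, tmp_path):
        rng = np.random.default_rng(11)
        bg = [f"g{i}" for i in range(80)]
        terms = {f"T{t}": rng.choice(bg, size=15, replace=False).tolist() for t in range(6)}
        bg2, ann = self.make_table(tmp_path, 80, terms)
        query = mk_query(rng.choice(bg, size=20, replace=False).tolist())
        res = fisher_enrichment(query, ann, q_threshold=1.01)
        for a, b in zip(res, res[1:]):
            assert b.q >= a.q - 1e-12  # sorted by p; q non-decreasing along ranking


class TestModulesWithMinSets:
    def make_part(self):
        edges = [(f"m{mod}_{i}", f"m{mod}_{i+1}") for mod in range(3) for i in range(4)]
        net = Network.from_edges(edges)
        assignment = {n: int(n[1]) for n in net.nodes}
        return net, partition_from_assignment(net, assignment, min_size=2)

    def test_module_with_two_sets_reported(self):
        net, part = self.make_part()
        s1 = mk_query(["m0_0", "m0_1"], "S1")
        s3 = mk_query(["m0_2"], "S3")
        assert modules_with_min_sets(part, [s1, s3]) == [(0, ["S1", "S3"])]

    def test_single_set_module_not_reported(self):
        net, part = self.make_part()
        s2 = mk_query(["m1_0", "m1_1"], "S2")
        assert modules_with_min_sets(part, [s2]) == []

    def test_min_genes_per_set(self):
        net, part = self.make_part()
        s1 = mk_query(["m0_0", "m0_1"], "S1")
        s2 = mk_query(["m0_2"], "S2")
        assert modules_with_min_sets(part, [s1, s2], min_genes_per_set=2) == []


class TestTermIntersection:
    def mk(self, tid, q):
        return EnrichmentResult(tid, tid, 5, 10, 20, 100, q / 2, q)

    def test_common_terms(self):
        a = [self.mk("T1", 0.01), self.mk("T2", 0.01), self.mk("T3", 0.02)]
        b = [self.mk("T2", 0.04), self.mk("T3", 0.01), self.mk("T4", 0.01)]
        out = term_intersection(a, b)
        assert [t for t, _ in out] == ["T3", "T2"]

    def test_combined_p_is_larger_of_two(self):
        out = term_intersection([self.mk("T2", 0.01)], [self.mk("T2", 0.04)])
        assert out == [("T2", 0.04)]

    def test_disjoint_empty(self):
        assert term_intersection([self.mk("T1", 0.01)], [self.mk("T9", 0.01)]) == []


class TestConvertGaf:
    def test_subset_conversion(self, tmp_path):
        gaf = tmp_path / "in.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            "UniProtKB\tP04637\tTP53\t\tGO:0006915\tPMID:1\tIDA\t\tP\t\t\t\t\t\t\t\t\n"
            "UniProtKB\tP38398\tBRCA1\t\tGO:0006281\tPMID:2\tIEA\t\tP\t\t\t\t\t\t\t\t\n"
        )
        out = tmp_path / "out.tsv"
        assert convert_gaf(gaf, out) == 2
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["TP53", "GO:0006915", "GO:0006915", "IDA"]
        assert lines[1].endswith("IEA")
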