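import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_genes
from oracles import bh_qvalues, hypergeom_tail
from neighborscan.genome_io import AnnotationSet, GeneRecord
from neighborscan.neighborhood_enrichment import (
    ContingencyTable2x2,
    EnrichmentTest,
    UntestableTermError,
    build_contingency,
    call_neighborhoods,
    fdr_correct,
    fisher_exact_greater,
    scan_enrichment,
    summarize_species,
)
from neighborscan.window_scan import GenomicWindow, make_windows


class TestBuildContingency:
    def make_window(self, gene_ids):
        return GenomicWindow(0, "chr1", 0, 1000, list(gene_ids))

    def test_counting(self):
        universe = [f"g{i}" for i in range(1000)]
        term_genes = universe[:100]           # 100 genes with T genome-wide
        window = self.make_window(universe[92:142])  # 50 genes, 8 with T
        ann = AnnotationSet([(g, "T") for g in term_genes])
        t = build_contingency(window, "T", ann, universe)
        assert (t.a, t.b, t.c, t.d) == (8, 42, 92, 858)

    def test_zero_in_window(self):
        universe = [f"g{i}" for i in range(500)]
        ann = AnnotationSet([(g, "T") for g in universe[-10:]])
        window = self.make_window(universe[:40])
        t = build_contingency(window, "T", ann, universe)
        assert (t.a, t.b, t.c, t.d) == (0, 40, 10, 450)

    def test_untestable_term(self):
        universe = ["g0", "g1"]
        ann = AnnotationSet([("g9", "T")])  # annotates nothing in universe
        with pytest.raises(UntestableTermError):
            build_contingency(self.make_window(["g0"]), "T", ann, universe)


class TestFisherExactGreater:
    def test_matches_bigint_oracle_on_example(self):
        t = ContingencyTable2x2(8, 42, 92, 858)
        assert fisher_exact_greater(t) == pytest.approx(
            hypergeom_tail(8, 42, 92, 858), rel=1e-12)

    def test_a_zero_gives_one(self):
        assert fisher_exact_greater(ContingencyTable2x2(0, 40, 10, 450)) == 1.0

    def test_degenerate_margins(self):
        assert fisher_exact_greater(ContingencyTable2x2(5, 0, 0, 0)) == 1.0

    def test_random_tables_vs_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b == 0 or a + c == 0:
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            assert fisher_exact_greater(t) == pytest.approx(
                hypergeom_tail(*map(int, (a, b, c, d))), rel=1e-10)


class TestFdrCorrect:
    @staticmethod
    def make_tests(pvals):
        w = GenomicWindow(0, "chr1", 0, 10, [])
        return [EnrichmentTest(w, f"T{i}", ContingencyTable2x2(0, 0, 0, 1), p)
                for i, p in enumerate(pvals)]

    def test_bh_formula(self):
        out = fdr_correct(self.make_tests([0.01, 0.02, 0.03, 0.04]))
        assert [t.q for t in out] == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        (t,) = fdr_correct(self.make_tests([0.3]))
        assert t.q == pytest.approx(0.3)

    def test_all_ones(self):
        out = fdr_correct(self.make_tests([1.0, 1.0, 1.0]))
        assert all(t.q == 1.0 and not t.significant for t in out)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            fdr_correct(self.make_tests([0.5, 1.5]))
        with pytest.raises(ValueError):
            fdr_correct(self.make_tests([0.0]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_matches_direct_formula_and_order_invariant(self, pvals, rnd):
        qs = [t.q for t in fdr_correct(self.make_tests(pvals))]
        assert qs == pytest.approx(bh_qvalues(pvals), rel=1e-12)
        shuffled = pvals[:]
        rnd.shuffle(shuffled)
        qmap = dict(zip(shuffled, (t.q for t in fdr_correct(self.make_tests(shuffled)))))
        for p, q in zip(pvals, qs):
            assert qmap[p] == pytest.approx(q)
        # monotone in p
        pairs = sorted(zip(pvals, qs))
        assert all(q1 <= q2 + 1e-15 for (_, q1), (_, q2) in zip(pairs, pairs[1:]))


class TestScanEnrichment:
    def setup_method(self):
        self.genes = make_genes(np.arange(500, 40_500, 1000))  # 40 genes
        pairs = [(g.gene_id, "T1") for g in self.genes[:8]]
        pairs += [(g.gene_id, "T2") for g in self.genes[::5]]
        pairs += [(g.gene_id, "T3") for g in self.genes[:3]]  # below min_term_genes
        pairs += [(g.gene_id, "T4") for g in self.genes]      # keeps all annotated
        self.ann = AnnotationSet(pairs)
        self.windows = make_windows(self.genes, 10_000, 5_000)

    def test_cartesian_count_and_min_term_filter(self):
        tests = scan_enrichment(self.windows, self.ann, min_term_genes=5)
        terms = {t.term_id for t in tests}
        assert terms == {"T1", "T2", "T4"}  # T3 has only 3 genes
        assert len(tests) == len(self.windows) * 3

    def test_identical_windows_identical_p(self):
        tests = scan_enrichment(self.windows, self.ann)
        by_genes = {}
        for t in tests:
            by_genes.setdefault((tuple(t.window.gene_ids), t.term_id), set()).add(t.p)
        assert all(len(ps) == 1 for ps in by_genes.values())


class TestCallNeighborhoods:
    def make_sig(self, term, chrom, start, end, q):
        w = GenomicWindow(0, chrom, start, end, [])
        t = EnrichmentTest(w, term, ContingencyTable2x2(1, 1, 1, 1), q, q=q,
                           significant=True)
        return t

    def setup_method(self):
        self.genes = make_genes(np.arange(500, 60_500, 1000))
        self.ann = AnnotationSet([(g.gene_id, "T") for g in self.genes[:30]]
                                 + [(g.gene_id, "U") for g in self.genes])

    def test_overlapping_windows_merge(self):
        tests = [self.make_sig("T", "chr1", 0, 40_000, 1e-4),
                 self.make_sig("T", "chr1", 20_000, 60_000, 1e-5)]
        (n,) = call_neighborhoods(tests, self.genes, self.ann, "sp")
        assert (n.start, n.end, n.best_q) == (0, 60_000, 1e-5)

    def test_terms_kept_separate(self):
        tests = [self.make_sig("T", "chr1", 0, 40_000, 1e-4),
                 self.make_sig("U", "chr1", 0, 40_000, 1e-4)]
        ns = call_neighborhoods(tests, self.genes, self.ann, "sp")
        assert sorted(n.term_id for n in ns) == ["T", "U"]

    def test_distant_windows_stay_separate(self):
        tests = [self.make_sig("T", "chr1", 0, 10_000, 1e-4),
                 self.make_sig("T", "chr1", 50_000, 60_000, 1e-4)]
        ns = call_neighborhoods(tests, self.genes, self.ann, "sp")
        assert len(ns) == 2

    def test_no_same_term_overlaps(self, default_bundle):
        from neighborscan.window_scan import choose_window_size

        b = default_bundle
        ws = make_windows(b.genes, choose_window_size(b.genes))
        tests = fdr_correct(scan_enrichment(ws, b.annotations))
        ns = call_neighborhoods(tests, b.genes, b.annotations, "sp")
        for i, n1 in enumerate(ns):
            for n2 in ns[i + 1:]:
                if (n1.term_id, n1.chrom) == (n2.term_id, n2.chrom):
                    assert n1.end <= n2.start or n2.end <= n1.start

    def test_members_vs_all_genes_and_density(self):
        tests = [self.make_sig("T", "chr1", 0, 30_000, 1e-4)]
        (n,) = call_neighborhoods(tests, self.genes, self.ann, "sp")
        assert len(n.all_gene_ids) == 30   # every gene in span
        assert len(n.member_gene_ids) == 30  # first 30 genes carry T
        assert set(n.member_gene_ids) <= set(n.all_gene_ids)
        assert n.gene_density == pytest.approx(30 / 0.03)


class TestSummarizeSpecies:
    def test_union_semantics(self):
        genes = make_genes(np.arange(500, 100_500, 1000))  # 100 genes
        ann = AnnotationSet([(g.gene_id, "T") for g in genes])
        from neighborscan.neighborhood_enrichment import Neighborhood

        n1 = Neighborhood("sp", "T", "chr1", 0, 2000, ["g1", "g2"], ["g1", "g2"], 0.01)
        n2 = Neighborhood("sp", "T", "chr1", 5000, 7000, ["g2", "g3"], ["g2", "g3"], 0.01)
        s = summarize_species([n1, n2], genes, ann)
        assert s.pct_genes_in_neighborhoods == pytest.approx(3.0)

    def test_density_mean(self):
        genes = make_genes(np.arange(500, 60_500, 1000))
        ann = AnnotationSet([(g.gene_id, "T") for g in genes])
        from neighborscan.neighborhood_enrichment import Neighborhood

        n = Neighborhood("sp", "T", "chr1", 0, 600_000, ["g0"],
                         [f"g{i}" for i in range(60)], 0.01, gene_density=100.0)
        s = summarize_species([n], genes, ann)
        assert s.mean_gene_density == pytest.approx(100.0)

    def test_no_neighborhoods(self):
        genes = make_genes([500, 1500])
        ann = AnnotationSet([(g.gene_id, "T") for g in genes])
        s = summarize_species([], genes, ann)
        assert s.pct_genes_in_neighborhoods == 0.0
        assert s.mean_gene_density is None

    def test_zero_annotated_errors(self):
        genes = make_genes([500])
        with pytest.raises(ValueError):
            summarize_species([], genes, AnnotationSet([("other", "T")]))
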