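"""Set-algebra classification, gene annotation, regulatory domains, and
gene-set enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from fairedyn.core import GeneModel, GenomicInterval
from fairedyn.dynamics import (
    ClassificationRule,
    absent_from,
    build_regulatory_domains,
    classify_peaks,
    fig3_rules,
    fig5_rules,
    gene_overlap_sets,
    geneset_enrichment,
    nearest_gene,
    overlap_fraction,
    present_in,
)
from fairedyn.simulate import CONDITIONS, DECOY_CONDITIONS, truth_peak_sets

from oracles import oracle_classify


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestOverlapAlgebra:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (iv(100, 200), iv(150, 250), 0.5),
            (iv(100, 200), iv(100, 200), 1.0),
            (iv(100, 200), iv(300, 400), 0.0),
            (iv(100, 200), iv(100, 200, chrom="chr2"), 0.0),
        ],
    )
    def test_fraction_of_query(self, a, b, expected):
        assert overlap_fraction(a, b) == expected

    def test_asymmetry(self):
        a, b = iv(100, 200), iv(100, 400)
        assert overlap_fraction(a, b) == 1.0
        assert overlap_fraction(b, a) == pytest.approx(1 / 3)

    def test_presence_boundary_inclusive_at_25pct(self):
        peak = iv(0, 200)
        assert present_in(peak, [iv(150, 300)]) is True  # exactly 50/200
        assert present_in(peak, [iv(151, 300)]) is False  # 49/200
        assert present_in(peak, []) is False

    def test_absence_boundary_excludes_exact_10pct(self):
        peak = iv(0, 200)
        assert absent_from(peak, [[iv(180, 300)]]) is False  # exactly 20/200 = 10%
        assert absent_from(peak, [[iv(190, 300)]]) is True  # 5%
        assert absent_from(peak, []) is True  # vacuous


class TestClassification:
    def test_matches_quadratic_oracle(self, called_peak_sets):
        condition_peaks = {c: called_peak_sets[c].peaks for c in CONDITIONS}
        decoy_peaks = [called_peak_sets[d].peaks for d in DECOY_CONDITIONS]
        for rules in (fig3_rules(), fig5_rules()):
            result = classify_peaks(condition_peaks, decoy_peaks, rules)
            candidates = [cp.peak for cp in result.peaks]
            expected = oracle_classify(candidates, condition_peaks, decoy_peaks, rules)
            assert [cp.class_name for cp in result.peaks] == expected

    def test_default_rules_mutually_exclusive_on_truth_patterns(self, truth):
        """No noise-free truth peak matches two rules of the five-class set."""
        condition_sets, decoy_sets = truth_peak_sets(truth)
        result = classify_peaks(condition_sets, list(decoy_sets.values()), fig3_rules())
        assert result.n_multi_match == 0

    def test_full_recovery_on_noise_free_truth(self, truth):
        condition_sets, decoy_sets = truth_peak_sets(truth)
        label_of = {
            (t.interval.chrom, t.interval.start, t.interval.end): t.class_label
            for t in truth
        }
        result = classify_peaks(condition_sets, list(decoy_sets.values()), fig3_rules())
        dynamic = {"Epidermal", "ThreeD", "Stable", "IntactBarrier", "BarrierDeficient"}
        n_checked = 0
        for cp in result.peaks:
            truth_label = label_of[(cp.peak.chrom, cp.peak.start, cp.peak.end)]
            if truth_label in dynamic:
                assert cp.class_name == truth_label
                n_checked += 1
        assert n_checked == 150

    def test_recovery_from_called_peaks(self, truth, called_peak_sets):
        """>=90% of dynamic truth peaks get their class from called peaks,
        despite boundary jitter."""
        result = classify_peaks(
            {c: called_peak_sets[c] for c in CONDITIONS},
            [called_peak_sets[d] for d in DECOY_CONDITIONS],
            fig3_rules(),
        )
        classes_over_truth = {}
        for cp in result.peaks:
            for t in truth:
                if cp.peak.overlaps(t.interval):
                    classes_over_truth.setdefault(id(t), set()).add(cp.class_name)
        dynamic = [t for t in truth if t.class_label in
                   ("Epidermal", "ThreeD", "Stable", "IntactBarrier", "BarrierDeficient")]
        recovered = sum(
            1 for t in dynamic if t.class_label in classes_over_truth.get(id(t), set())
        )
        assert recovered / len(dynamic) >= 0.90

    def test_peak_only_in_keratinocyte_unclassified(self):
        peak = iv(1000, 1200)
        sets = {"Keratinocyte": [peak], "ESS": [], "Graft": [], "TapeStrip": []}
        for rules in (fig3_rules(), fig5_rules()):
            result = classify_peaks(sets, [], rules)
            assert result.peaks[0].class_name == "Unclassified"

    def test_housekeeping_needs_three_decoys(self):
        peak = iv(1000, 1200)
        sets = {c: [peak] for c in CONDITIONS}
        result = classify_peaks(sets, [[peak], [peak]], fig5_rules())
        assert result.peaks[0].class_name == "Unclassified"  # only 2 decoys
        result = classify_peaks(sets, [[peak], [peak], [peak]], fig5_rules())
        assert result.peaks[0].class_name == "Housekeeping"

    def test_unknown_label_rejected(self):
        rule = ClassificationRule("X", ("Nonexistent",), ())
        with pytest.raises(ValueError, match="unknown label"):
            classify_peaks({"ESS": []}, [], [rule])

    def test_conflicting_rule_fields_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ClassificationRule("X", ("ESS",), ("ESS",))


class TestNearestGene:
    def genes(self):
        return [
            GeneModel("gA", "chr1", 1000, "+", iv(500, 2000)),
            GeneModel("gB", "chr1", 3000, "-", iv(2500, 4000)),
        ]

    def test_peak_on_tss_distance_zero(self):
        rec = nearest_gene(iv(900, 1100), self.genes())
        assert rec.gene_id == "gA" and rec.distance == 0

    def test_signed_distance_by_strand(self):
        # center 1200, 200 bp downstream of gA's + strand TSS
        assert nearest_gene(iv(1100, 1300), self.genes()).distance == 200
        # center 3200 is upstream of gB's - strand TSS at 3000
        rec = nearest_gene(iv(3100, 3300), self.genes())
        assert rec.gene_id == "gB" and rec.distance == -200

    def test_equidistant_tie_flagged_smaller_coordinate(self):
        rec = nearest_gene(iv(1900, 2100), self.genes())  # center 2000
        assert rec.gene_id == "gA" and rec.tie is True

    def test_chromosome_without_genes_unassigned(self):
        rec = nearest_gene(iv(0, 100, chrom="chr9"), self.genes())
        assert rec.gene_id is None and rec.distance is None


class TestGeneOverlap:
    def test_identical_lists_all_common(self):
        out = gene_overlap_sets({"a": ["x", "y"], "b": ["x", "y"]})
        assert out["region_counts"][frozenset({"a", "b"})] == 2
        assert out["uncommon"] == {"a": set(), "b": set()}

    def test_disjoint_lists_center_zero(self):
        out = gene_overlap_sets({"a": ["x"], "b": ["y"]})
        assert frozenset({"a", "b"}) not in out["region_counts"]

    def test_uncommon_removes_shared_core(self):
        out = gene_overlap_sets({"a": ["x", "y"], "b": ["y", "z"]})
        assert out["common"] == {"y"}
        assert out["uncommon"] == {"a": {"x"}, "b": {"z"}}


class TestRegulatoryDomains:
    SIZES = {"chr1": 10_000_000}

    def test_isolated_gene_full_extension(self):
        g = GeneModel("g", "chr1", 5_000_000, "+", iv(4_999_000, 5_010_000))
        (dom,) = build_regulatory_domains([g], self.SIZES)
        assert (dom.basal.start, dom.basal.end) == (4_995_000, 5_001_000)
        assert (dom.extended.start, dom.extended.end) == (4_000_000, 6_000_000)

    def test_neighbor_truncates_at_basal_boundary(self):
        g1 = GeneModel("g1", "chr1", 1_000_000, "+", iv(999_000, 1_002_000))
        g2 = GeneModel("g2", "chr1", 1_020_000, "+", iv(1_019_000, 1_022_000))
        doms = {d.gene_id: d for d in build_regulatory_domains([g1, g2], self.SIZES)}
        # upstream gene's extension stops at the downstream gene's basal start
        assert doms["g1"].extended.end == doms["g2"].basal.start
        assert doms["g2"].extended.start == doms["g1"].basal.end

    def test_chromosome_start_clips_basal(self):
        g = GeneModel("g", "chr1", 2000, "+", iv(1000, 4000))
        (dom,) = build_regulatory_domains([g], self.SIZES)
        assert dom.basal.start == 0

    def test_no_extended_domain_invades_foreign_basal(self):
        rng = np.random.default_rng(8)
        genes = []
        for i, tss in enumerate(sorted(rng.integers(50_000, 9_950_000, size=20))):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"g{i}", "chr1", int(tss), strand,
                          iv(int(tss) - 100, int(tss) + 100))
            )
        doms = build_regulatory_domains(genes, self.SIZES)
        for d in doms:
            for other in doms:
                if other.gene_id == d.gene_id:
                    continue
                # extension may touch but not cover any part of a foreign basal
                inter = d.extended.overlap_length(other.basal)
                own_basal_inter = d.basal.overlap_length(other.basal)
                assert inter <= own_basal_inter  # only unavoidable basal-basal overlap


class TestGenesetEnrichment:
    def test_exact_probability_when_foreground_is_the_set(self):
        k = 30
        genes = [f"g{i}" for i in range(2 * k)]
        universe = set(genes)
        fg = set(genes[:k])
        df = geneset_enrichment(fg, universe, {"s": fg}, min_set=30)
        expected = 1 / math.comb(2 * k, k)
        assert df.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_foreground_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(50)}
        s = {f"g{i}" for i in range(50, 100)}
        df = geneset_enrichment(fg, universe, {"s": s}, min_set=30)
        assert df.loc[0, "p_value"] == 1.0

    def test_small_sets_dropped(self):
        universe = {f"g{i}" for i in range(100)}
        small = {f"g{i}" for i in range(29)}
        df = geneset_enrichment(set(), universe, {"small": small}, min_set=30)
        assert df.empty

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            geneset_enrichment({"x"}, {"y"}, {}, min_set=1)

    def test_null_pvalues_approximately_uniform(self):
        """Uniform random foregrounds yield ~uniform hypergeometric p-values."""
        rng = np.random.default_rng(17)
        genes = np.array([f"g{i}" for i in range(10_000)])
        gene_set = set(genes[:5000])
        universe = set(genes)
        pvals = []
        for _ in range(1000):
            fg = set(rng.choice(genes, size=1000, replace=False))
            df = geneset_enrichment(fg, universe, {"s": gene_set}, min_set=30)
            pvals.append(df.loc[0, "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3
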