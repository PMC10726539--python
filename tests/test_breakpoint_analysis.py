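"""Microhomology, depth profiles, breakpoint context, exon contrast, kinases."""

import itertools

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy import stats

from fusionval.breakpoint_analysis import (amplification_summary,
                                           annotate_breakpoint_context,
                                           classify_kinase_fusion,
                                           common_prefix_length,
                                           context_chisquare, depth_profile,
                                           exon_expression_contrast,
                                           gene_class_lengths,
                                           microhomology_at_breakpoint,
                                           microhomology_test,
                                           simulate_control_breakpoints,
                                           tagged_exons)
from fusionval.io_formats import FusionCall, Junction, reverse_complement
from fusionval.wgs_validation import global_depth

from test_wgs_validation import write_sam


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.faidx(str(path))
    return path


class TestMicrohomology:
    def test_flanks_sharing_five_bases_are_microhomologous(self, tmp_path):
        pad = "T" * 50
        # lost flank of the 5' partner after position 50: ACGTAG...
        # retained 3' flank from position 51:            ACGTAC...
        fa = write_fasta(tmp_path / "g.fa", {
            "a": pad + "ACGTAGGGGGGGGGGGGGGGGGGGG",
            "b": pad + "ACGTACCCCCCCCCCCCCCCCCCCC"})
        res = microhomology_at_breakpoint(fa, ("a", 50, "+"), ("b", 51, "+"))
        assert res.homology_len == 5
        assert res.label == "microhomologous"

    def test_first_base_mismatch_is_none(self, tmp_path):
        fa = write_fasta(tmp_path / "g.fa",
                         {"a": "T" * 50 + "A" * 25, "b": "T" * 50 + "C" * 25})
        res = microhomology_at_breakpoint(fa, ("a", 50, "+"), ("b", 51, "+"))
        assert res.homology_len == 0 and res.label == "none"

    def test_long_match_is_homologous(self, tmp_path):
        fa = write_fasta(tmp_path / "g.fa",
                         {"a": "T" * 50 + "ACGTACGTAC" + "G" * 20,
                          "b": "T" * 50 + "ACGTACGTAC" + "C" * 20})
        res = microhomology_at_breakpoint(fa, ("a", 50, "+"), ("b", 51, "+"))
        assert res.homology_len == 10 and res.label == "homologous"

    def test_matches_naive_prefix_oracle_on_random_flanks(self, tmp_path):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        seq_a = "".join(rng.choice(bases, 4000))
        seq_b = "".join(rng.choice(bases, 4000))
        fa = write_fasta(tmp_path / "g.fa", {"a": seq_a, "b": seq_b})
        for _ in range(200):
            p5 = int(rng.integers(100, 3800))
            p3 = int(rng.integers(100, 3800))
            res = microhomology_at_breakpoint(fa, ("a", p5, "+"),
                                              ("b", p3, "+"), max_checked=20)
            lost5 = seq_a[p5:p5 + 20]
            kept3 = seq_b[p3 - 1:p3 + 19]
            assert res.homology_len == common_prefix_length(lost5, kept3)

    def test_symmetric_under_reverse_complement_of_both_partners(
            self, tmp_path):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        seq_a = "".join(rng.choice(bases, 500))
        seq_b = "".join(rng.choice(bases, 500))
        fa = write_fasta(tmp_path / "fwd.fa", {"a": seq_a, "b": seq_b})
        fa_rc = write_fasta(tmp_path / "rc.fa",
                            {"a": reverse_complement(seq_a),
                             "b": reverse_complement(seq_b)})
        for _ in range(25):
            p5 = int(rng.integers(50, 450))
            p3 = int(rng.integers(50, 450))
            fwd = microhomology_at_breakpoint(fa, ("a", p5, "+"),
                                              ("b", p3, "+"))
            rc = microhomology_at_breakpoint(
                fa_rc, ("a", 501 - p5, "-"), ("b", 501 - p3, "-"))
            assert fwd.homology_len == rc.homology_len

    def test_planted_simulator_homology_recovered_exactly(
            self, small_reference):
        for t in small_reference["truths"]:
            res = microhomology_at_breakpoint(
                small_reference["fasta"], (t.chrom5, t.bp5, "+"),
                (t.chrom3, t.bp3, "+"))
            assert res.homology_len == t.microhomology_len


class TestControlBreakpoints:
    BP = (("chr1", 5000, "+"), ("chr2", 8000, "+"))

    def test_seeded_controls_are_reproducible(self):
        a = simulate_control_breakpoints(self.BP, 100, seed=4)
        b = simulate_control_breakpoints(self.BP, 100, seed=4)
        assert a == b and len(a) == 100

    def test_controls_stay_within_window_and_avoid_observed(self):
        controls = simulate_control_breakpoints(self.BP, 500, window=1000,
                                                seed=4)
        for (c5, p5, _), (c3, p3, _) in controls:
            assert abs(p5 - 5000) <= 1000 and abs(p3 - 8000) <= 1000
            assert (p5, p3) != (5000, 8000)

    def test_positions_are_uniform_by_ks(self):
        controls = simulate_control_breakpoints(self.BP, 10_000, window=1000,
                                                seed=4)
        p5 = np.array([c[0][1] for c in controls])
        ks = stats.kstest(p5, stats.uniform(loc=4000, scale=2001).cdf)
        assert ks.pvalue > 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_control_breakpoints(self.BP, 0, seed=1)


class TestMannWhitney:
    def test_strong_separation_gives_tiny_p(self):
        p = microhomology_test([5] * 50, [0] * 50)
        assert p < 1e-10

    def test_identical_samples_give_half(self):
        vals = list(range(20))
        assert microhomology_test(vals, vals) == pytest.approx(0.5, abs=0.05)

    def test_identical_constant_samples_give_one(self):
        assert microhomology_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_matches_exact_enumeration_at_small_n(self):
        rng = np.random.default_rng(12)
        obs = rng.random(6)
        ctl = rng.random(6)
        pooled = np.concatenate([obs, ctl])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:6].sum() - 6 * 7 / 2
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            u = ranks[list(idx)].sum() - 6 * 7 / 2
            count += u >= u_obs
            total += 1
        assert microhomology_test(obs, ctl) == pytest.approx(count / total,
                                                             abs=1e-9)


class TestDepthProfile:
    def test_uniform_coverage_gives_ratio_one(self, small_sim):
        g = global_depth(small_sim["bam"])
        # a position far from any planted fusion or gene
        prof = depth_profile(small_sim["bam"], ("chr1", 200_000),
                             retained_upstream=True, global_mean=g)
        assert prof.depth_ratio.mean() == pytest.approx(1.0, abs=0.15)
        assert len(prof.offsets) == 201

    def test_zero_coverage_region_gives_zero(self, tmp_path):
        reads = [("r0", "c1", 100, "100M", 0x63, "c1", 300, 60, None),
                 ("r0", "c1", 300, "100M", 0x93, "c1", 100, 60, None)]
        bam = write_sam(tmp_path / "z.sam", {"c1": 50_000}, reads)
        prof = depth_profile(bam, ("c1", 20_000), retained_upstream=True,
                             global_mean=5.0)
        assert (prof.depth_ratio == 0).all()

    def test_amplified_fusion_shows_plateau_and_drop(self, small_sim):
        g = global_depth(small_sim["bam"])
        amp3 = [t for t in small_sim["truths"]
                if t.amplification_factor == 3]
        assert amp3, "simulation lacks an amplified fusion"
        t = amp3[0]
        prof = depth_profile(small_sim["bam"], (t.chrom5, t.bp5),
                             retained_upstream=True, global_mean=g,
                             partner="5")
        retained, beyond = amplification_summary(prof)
        assert retained > 2.0
        assert beyond == pytest.approx(1.0, abs=0.35)

    def test_retained_side_is_negative_offsets_regardless_of_orientation(
            self, small_sim):
        g = global_depth(small_sim["bam"])
        t = small_sim["truths"][0]
        up = depth_profile(small_sim["bam"], (t.chrom5, t.bp5),
                           retained_upstream=True, global_mean=g)
        down = depth_profile(small_sim["bam"], (t.chrom5, t.bp5),
                             retained_upstream=False, global_mean=g)
        assert np.allclose(up.depth_ratio, down.depth_ratio[::-1])

    def test_nonpositive_global_mean_rejected(self, small_sim):
        with pytest.raises(ValueError):
            depth_profile(small_sim["bam"], ("chr1", 1000),
                          retained_upstream=True, global_mean=0.0)


class TestBreakpointContext:
    def test_priority_classes(self, toy_annotation):
        assert annotate_breakpoint_context(
            ("chr1", 2000), toy_annotation).region_class == "intron"
        assert annotate_breakpoint_context(
            ("chr1", 3100), toy_annotation).region_class == "CDS"
        assert annotate_breakpoint_context(
            ("chr1", 1100), toy_annotation).region_class == "UTR"
        assert annotate_breakpoint_context(
            ("chr1", 500), toy_annotation).region_class == "intergenic"

    def test_repeat_class_attached(self, toy_annotation):
        from intervaltree import IntervalTree
        tree = IntervalTree()
        tree.addi(1900, 2100, "L1")
        ctx = annotate_breakpoint_context(("chr1", 2000), toy_annotation,
                                          {"chr1": tree})
        assert ctx.region_class == "intron" and ctx.repeat_class == "L1"

    def test_chisquare_pvalues_uniform_under_the_null(self, toy_annotation):
        """Breakpoints drawn uniformly within the genes match the
        length-proportional expectation, so chi-square p-values are uniform."""
        genes = [toy_annotation["G1"], toy_annotation["G2"]]
        lengths = gene_class_lengths(genes)
        assert sum(lengths.values()) == sum(g.length for g in genes)
        rng = np.random.default_rng(3)
        spans = [(g.chrom, g.start, g.end) for g in genes]
        weights = np.array([e - s + 1 for _, s, e in spans], dtype=float)
        weights /= weights.sum()
        pvals = []
        for _ in range(100):
            contexts = []
            for _ in range(300):
                ci = rng.choice(len(spans), p=weights)
                chrom, s, e = spans[ci]
                pos = int(rng.integers(s, e + 1))
                contexts.append(
                    annotate_breakpoint_context((chrom, pos), toy_annotation))
            _, p, _ = context_chisquare(contexts, genes)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExonExpressionContrast:
    def exon_table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "exon_start", "exon_end",
                                           "expression"])

    def test_simple_fold_change(self, toy_annotation):
        # G1 '+': junction at 5000 tags exons 1-2 for the 5' side
        table = self.exon_table([
            ("G1", 1000, 1400, 10.0), ("G1", 3000, 3400, 10.0),
            ("G1", 8600, 9000, 2.0),
            ("G2", 20_000, 20_500, 1.0), ("G2", 24_000, 24_500, 1.0),
            ("G2", 29_500, 30_000, 1.0)])
        res = exon_expression_contrast(
            [("G1", 5000, "G2", 24_300)], toy_annotation, table)
        assert res["5"]["per_gene"]["fold"].iloc[0] == pytest.approx(5.0)

    def test_all_exons_equal_gives_fold_one(self, toy_annotation):
        table = self.exon_table([
            ("G1", 1000, 1400, 3.0), ("G1", 3000, 3400, 3.0),
            ("G1", 8600, 9000, 3.0),
            ("G2", 20_000, 20_500, 3.0), ("G2", 24_000, 24_500, 3.0),
            ("G2", 29_500, 30_000, 3.0)])
        res = exon_expression_contrast(
            [("G1", 5000, "G2", 24_300)], toy_annotation, table)
        assert res["5"]["mean_fold"] == pytest.approx(1.0)
        assert res["5"]["pvalue"] == pytest.approx(1.0)

    def test_planted_3prime_upregulation_recovered(self, small_reference):
        from fusionval.simulate import simulate_exon_expression
        ref = small_reference["reference"]
        truths = small_reference["truths"]
        table = simulate_exon_expression(ref, truths, fold3=5.0, seed=6)
        fusions = [(t.gene5, t.bp5, t.gene3, t.bp3) for t in truths]
        res = exon_expression_contrast(fusions, ref.annotation, table)
        assert res["3"]["geometric_mean_fold"] == pytest.approx(5.0, rel=0.2)
        assert res["3"]["pvalue"] < 0.01

    def test_no_eligible_genes_rejected(self, toy_annotation):
        table = self.exon_table([("G1", 1000, 1400, 1.0)])
        with pytest.raises(ValueError, match="no eligible genes"):
            exon_expression_contrast([("G1", 100_000, "G2", 100_000)],
                                     toy_annotation, table)

    def test_tagged_exons_are_strand_aware(self, toy_annotation):
        # G2 is minus strand: for the 3' side the retained exons lie at
        # genomic coordinates below the junction
        tags = tagged_exons(toy_annotation["G2"], 24_300, "3")
        assert tags == [True, False, False]
        tags5 = tagged_exons(toy_annotation["G2"], 24_300, "5")
        assert tags5 == [False, False, True]


class TestKinaseClassification:
    def call(self, effect, j3pos, gene3="G1"):
        return FusionCall(sample_id="s", gene5="G2", gene3=gene3,
                          junction5=Junction("chr1", 24_000, "-"),
                          junction3=Junction("chr1", j3pos, "+"),
                          predicted_effect=effect)

    def test_in_frame_with_kinase_partner(self, toy_annotation):
        assert classify_kinase_fusion(self.call("in-frame", 5000),
                                      toy_annotation) == "in_frame_kinase"

    def test_promoter_swap_requires_junction_upstream_of_cds(
            self, toy_annotation):
        # G1 kinase CDS starts at 1200
        assert classify_kinase_fusion(
            self.call("out-of-frame", 1100),
            toy_annotation) == "promoter_swap_kinase"
        assert classify_kinase_fusion(
            self.call("out-of-frame", 5000), toy_annotation) == "none"

    def test_no_kinase_partner_is_none(self, toy_annotation):
        call = FusionCall(sample_id="s", gene5="G2", gene3="G2",
                          junction5=Junction("chr1", 29_000, "-"),
                          junction3=Junction("chr1", 21_000, "-"),
                          predicted_effect="in-frame")
        assert classify_kinase_fusion(call, toy_annotation) == "none"

    def test_unknown_partner_is_none(self, toy_annotation):
        assert classify_kinase_fusion(
            self.call("in-frame", 5000, gene3="NOPE"),
            toy_annotation) == "none"
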