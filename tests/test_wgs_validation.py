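"""WGS validation pipeline: regions, discordant pairs, breakpoints, scans."""

import math

import numpy as np
import pysam
import pytest

from fusionval.io_formats import FusionCall, GeneAnnotation, GeneModel, Junction
from fusionval.wgs_validation import (Region, SearchRegionPair,
                                      ValidationConfig, ValidationResult,
                                      crosstab_with_external,
                                      define_search_regions,
                                      extract_discordant_pairs,
                                      find_breakpoints, global_depth,
                                      prepare_alignments, shannon_diversity,
                                      subsample_validate, summarize_validation,
                                      unbiased_discordant_scan,
                                      validate_calls, validate_fusion)


def make_call(gene5, gene3, j5, j3, sample="s"):
    return FusionCall(sample_id=sample, gene5=gene5, gene3=gene3,
                      junction5=Junction(*j5), junction3=Junction(*j3))


def write_sam(path, lengths, reads):
    """reads: (name, chrom, pos1, cigar, flags, mate_chrom, mate_pos1, mapq,
    seq or None)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in lengths.items()]})
    tids = {c: i for i, c in enumerate(lengths)}
    segs = []
    for name, chrom, pos, cigar, flags, mchrom, mpos, mapq, seq in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flags
        a.reference_id = tids[chrom]
        a.reference_start = pos - 1
        a.mapping_quality = mapq
        a.cigarstring = cigar
        length = sum(n for op, n in a.cigartuples if op in (0, 1, 4))
        a.query_sequence = seq if seq is not None else "A" * length
        a.query_qualities = [35] * length
        a.next_reference_id = tids[mchrom]
        a.next_reference_start = mpos - 1
        segs.append(a)
    segs.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for s in segs:
            out.write(s)
    return prepare_alignments(path)


@pytest.fixture()
def plus_pair_annotation():
    g5 = GeneModel(gene_id="GA", symbol="GA", chrom="c1", start=1000,
                   end=9000, strand="+", exons=[(1000, 9000)])
    g3 = GeneModel(gene_id="GB", symbol="GB", chrom="c2", start=1000,
                   end=9000, strand="+", exons=[(1000, 9000)])
    return GeneAnnotation([g5, g3])


class TestSearchRegions:
    def test_plus_strand_regions_follow_the_retained_side_rule(
            self, plus_pair_annotation):
        call = make_call("GA", "GB", ("c1", 5000, "+"), ("c2", 5000, "+"))
        pair = define_search_regions(call, plus_pair_annotation)
        assert pair.region5 == Region("c1", 1000, 6000)
        assert pair.region3 == Region("c2", 4000, 9000)

    def test_region_clipped_at_chromosome_start(self, plus_pair_annotation):
        ann = GeneAnnotation([GeneModel(
            gene_id="GA", symbol="GA", chrom="c1", start=500, end=9000,
            strand="+", exons=[(500, 9000)]),
            plus_pair_annotation["GB"]])
        call = make_call("GB", "GA", ("c2", 5000, "+"), ("c1", 600, "+"))
        pair = define_search_regions(call, ann)
        assert pair.region3.start == 1  # 600 - 1000 clipped

    def test_minus_strand_flips_the_retained_side(self):
        ann = GeneAnnotation([
            GeneModel(gene_id="GA", symbol="GA", chrom="c1", start=1000,
                      end=9000, strand="-", exons=[(1000, 9000)]),
            GeneModel(gene_id="GB", symbol="GB", chrom="c2", start=1000,
                      end=9000, strand="-", exons=[(1000, 9000)])])
        call = make_call("GA", "GB", ("c1", 5000, "-"), ("c2", 5000, "-"))
        pair = define_search_regions(call, ann)
        assert pair.region5 == Region("c1", 4000, 9000)
        assert pair.region3 == Region("c2", 1000, 6000)

    def test_junction_far_outside_gene_warns_and_centers(
            self, plus_pair_annotation):
        call = make_call("GA", "GB", ("c1", 50_000, "+"), ("c2", 5000, "+"))
        with pytest.warns(UserWarning, match="outside gene"):
            pair = define_search_regions(call, plus_pair_annotation)
        assert pair.region5 == Region("c1", 49_000, 51_000)

    def test_unknown_symbol_raises(self, plus_pair_annotation):
        call = make_call("NOPE", "GB", ("c1", 5000, "+"), ("c2", 5000, "+"))
        with pytest.raises(KeyError, match="NOPE"):
            define_search_regions(call, plus_pair_annotation)


class TestDiscordantPairs:
    LENGTHS = {"c1": 20_000, "c2": 20_000}
    REGIONS = SearchRegionPair(Region("c1", 1000, 6000),
                               Region("c2", 4000, 9000))

    def cross_pairs(self, n, mapq=60, flags1=0x41, flags2=0x81):
        reads = []
        for i in range(n):
            p5, p3 = 2000 + 10 * i, 5000 + 10 * i
            reads.append((f"d{i}", "c1", p5, "100M", flags1 | 0x20,
                          "c2", p3, mapq, None))
            reads.append((f"d{i}", "c2", p3, "100M", flags2 | 0x10,
                          "c1", p5, mapq, None))
        return reads

    def test_planted_cross_region_pairs_are_recovered(self, tmp_path):
        bam = write_sam(tmp_path / "a.sam", self.LENGTHS, self.cross_pairs(5))
        pairs = extract_discordant_pairs(bam, self.REGIONS)
        assert sorted(p.read_name for p in pairs) == [f"d{i}" for i in range(5)]
        assert all(2000 <= p.pos5 <= 2040 for p in pairs)

    def test_low_mapq_pairs_are_filtered(self, tmp_path):
        bam = write_sam(tmp_path / "b.sam", self.LENGTHS,
                        self.cross_pairs(5, mapq=5))
        assert extract_discordant_pairs(bam, self.REGIONS) == []

    def test_proper_pairs_between_overlapping_regions_are_excluded(
            self, tmp_path):
        regions = SearchRegionPair(Region("c1", 1000, 6000),
                                   Region("c1", 5500, 9000))
        reads = [("p0", "c1", 5400, "100M", 0x63, "c1", 5700, 60, None),
                 ("p0", "c1", 5700, "100M", 0x93, "c1", 5400, 60, None)]
        bam = write_sam(tmp_path / "c.sam", {"c1": 20_000}, reads)
        assert extract_discordant_pairs(bam, regions) == []

    def test_duplicate_coordinate_pairs_collapse_to_one(self, tmp_path):
        reads = []
        for i in range(3):  # same coordinates, different names
            reads.append((f"d{i}", "c1", 2000, "100M", 0x61, "c2", 5000, 60,
                          None))
            reads.append((f"d{i}", "c2", 5000, "100M", 0x91, "c1", 2000, 60,
                          None))
        bam = write_sam(tmp_path / "d.sam", self.LENGTHS, reads)
        assert len(extract_discordant_pairs(bam, self.REGIONS)) == 1


class TestBreakpoints:
    def _truth_setup(self, small_sim):
        truth = small_sim["truths"][0]
        ann = small_sim["reference"].annotation
        call = make_call(truth.gene5, truth.gene3,
                         (truth.chrom5, truth.bp5, "+"),
                         (truth.chrom3, truth.bp3, "+"))
        return truth, ann, call

    def test_planted_junction_is_recovered_exactly(self, small_sim):
        truth, ann, call = self._truth_setup(small_sim)
        regions = define_search_regions(call, ann)
        pairs = extract_discordant_pairs(small_sim["bam"], regions)
        assert len(pairs) >= 3
        bps = find_breakpoints(small_sim["bam"], pairs, regions,
                               small_sim["paths"]["fasta"])
        assert bps, "no breakpoint found for a planted fusion"
        top = bps[0]
        assert top.bp5 == (truth.chrom5, truth.bp5)
        assert top.bp3 == (truth.chrom3, truth.bp3)
        assert top.support >= 2

    def test_no_discordant_pairs_gives_empty_list(self, small_sim):
        truth, ann, call = self._truth_setup(small_sim)
        regions = define_search_regions(call, ann)
        assert find_breakpoints(small_sim["bam"], [], regions,
                                small_sim["paths"]["fasta"]) == []

    def test_clip_evidence_suppressed_falls_back_to_validated(
            self, small_sim):
        truth, ann, call = self._truth_setup(small_sim)
        cfg = ValidationConfig(min_clip_len=5000)  # no clip can qualify
        res = validate_fusion(call, small_sim["bam"],
                              small_sim["paths"]["fasta"], ann, cfg)
        assert res.status == "validated" and res.breakpoints == []

    def test_random_clip_sequence_is_rejected(self, tmp_path,
                                              small_reference):
        # discordant pair plus one soft-clipped read whose clip is random
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 30))
        ref = small_reference["reference"]
        reads = [("d0", "chr1", 2000, "100M", 0x61, "chr2", 5000, 60, None),
                 ("d0", "chr2", 5000, "100M", 0x91, "chr1", 2000, 60, None),
                 ("c0", "chr1", 2100, "70M30S", 0x61, "chr2", 5000, 60,
                  ref.sequence("chr1", 2100, 2169) + junk),
                 ("c0", "chr2", 5100, "100M", 0x91, "chr1", 2100, 60, None)]
        bam = write_sam(tmp_path / "r.sam",
                        {c: len(s) for c, s in ref.seqs.items()}, reads)
        regions = SearchRegionPair(Region("chr1", 1000, 6000),
                                   Region("chr2", 4000, 9000))
        pairs = extract_discordant_pairs(bam, regions)
        assert len(pairs) == 2
        bps = find_breakpoints(bam, pairs, regions, small_reference["fasta"])
        assert bps == []


class TestValidateFusion:
    def test_planted_fusions_validate_with_breakpoints(self, small_sim):
        ann = small_sim["reference"].annotation
        results = validate_calls(small_sim["true_calls"], small_sim["bam"],
                                 small_sim["paths"]["fasta"], ann)
        assert all(r.status == "validated_with_breakpoint" for r in results)
        truth = {(t.gene5, t.gene3): t for t in small_sim["truths"]}
        for r in results:
            t = truth[(r.call.gene5, r.call.gene3)]
            top = r.breakpoints[0]
            assert abs(top.bp5[1] - t.bp5) <= 1
            assert abs(top.bp3[1] - t.bp3) <= 1

    def test_decoy_gene_pairs_do_not_validate(self, small_sim):
        ann = small_sim["reference"].annotation
        results = validate_calls(small_sim["decoy_calls"][:8],
                                 small_sim["bam"],
                                 small_sim["paths"]["fasta"], ann)
        assert all(r.status == "not_validated" for r in results)

    def test_raising_thresholds_never_increases_validations(self, small_sim):
        ann = small_sim["reference"].annotation
        fasta = small_sim["paths"]["fasta"]
        calls = small_sim["true_calls"]

        def n_validated(cfg):
            res = validate_calls(calls, small_sim["bam"], fasta, ann, cfg)
            return sum(r.validated for r in res)

        base = n_validated(ValidationConfig())
        assert n_validated(ValidationConfig(min_mapq=80)) <= base
        assert n_validated(ValidationConfig(min_discordant_pairs=10**6)) <= base


class TestDepthAndSubsampling:
    def test_global_depth_matches_simulated_coverage(self, small_sim):
        depth = global_depth(small_sim["bam"])
        expect = small_sim["config"].base_depth
        assert depth == pytest.approx(expect, rel=0.10)

    def test_empty_alignment_file_gives_zero_with_warning(self, tmp_path):
        bam = write_sam(tmp_path / "e.sam", {"c1": 1000}, [])
        with pytest.warns(UserWarning, match="no mapped reads"):
            assert global_depth(bam) == 0.0

    def test_invalid_fraction_rejected(self, small_sim):
        ann = small_sim["reference"].annotation
        with pytest.raises(ValueError, match="fraction"):
            subsample_validate(small_sim["true_calls"][:1], small_sim["bam"],
                               small_sim["paths"]["fasta"], ann,
                               fractions=(0.0,))

    def test_retention_is_deterministic_and_monotone(self, small_sim):
        ann = small_sim["reference"].annotation
        args = (small_sim["true_calls"], small_sim["bam"],
                small_sim["paths"]["fasta"], ann)
        r1 = subsample_validate(*args, fractions=(0.25, 0.75, 1.0), seed=123)
        r2 = subsample_validate(*args, fractions=(0.25, 0.75, 1.0), seed=123)
        assert r1 == r2
        assert r1[1.0] == 1.0
        ordered = [r1[f] for f in sorted(r1)]
        assert ordered == sorted(ordered)


class TestUnbiasedScan:
    def test_only_planted_cross_gene_pairs_are_counted(self, small_sim):
        counts = unbiased_discordant_scan(small_sim["bam"],
                                          small_sim["reference"].annotation)
        planted = {frozenset((t.gene5, t.gene3))
                   for t in small_sim["truths"]}
        assert set(counts) == planted
        assert all(v >= 3 for v in counts.values())

    def test_proper_pairs_and_intra_gene_pairs_ignored(self, tmp_path,
                                                       toy_annotation):
        reads = [
            # proper pair inside G1
            ("p0", "chr1", 1100, "100M", 0x63, "chr1", 1400, 60, None),
            ("p0", "chr1", 1400, "100M", 0x93, "chr1", 1100, 60, None),
            # discordant but both mates inside G1
            ("d0", "chr1", 1100, "100M", 0x61, "chr1", 8000, 60, None),
            ("d0", "chr1", 8000, "100M", 0x91, "chr1", 1100, 60, None),
        ]
        bam = write_sam(tmp_path / "scan.sam", {"chr1": 50_000}, reads)
        assert unbiased_discordant_scan(bam, toy_annotation) == {}


class TestShannonDiversity:
    def test_single_category_is_zero(self):
        assert shannon_diversity([17]) == 0.0

    def test_uniform_ten_categories_is_ln_ten(self):
        assert shannon_diversity([4] * 10) == pytest.approx(math.log(10))

    def test_matches_direct_formula_on_random_counts(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=30)
        counts[0] = 3  # ensure positive total
        p = counts[counts > 0] / counts.sum()
        expect = -(p * np.log(p)).sum()
        assert shannon_diversity(counts) == pytest.approx(expect)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([0, 0])


class TestSummaries:
    def test_cohort_counts_give_72_percent(self):
        s = summarize_validation(4237, 3049)
        assert s.percent_with_breakpoint == 72

    def test_zero_validated_is_zero_percent(self):
        assert summarize_validation(0, 0).percent_with_breakpoint == 0

    def test_all_with_breakpoints_is_100_percent(self):
        assert summarize_validation(7, 7).percent_with_breakpoint == 100

    def test_result_list_summary(self, small_sim):
        ann = small_sim["reference"].annotation
        results = validate_calls(
            small_sim["true_calls"] + small_sim["decoy_calls"][:5],
            small_sim["bam"], small_sim["paths"]["fasta"], ann)
        s = summarize_validation(results)
        assert s.n_validated == len(small_sim["truths"])
        assert s.n_with_breakpoint == s.n_validated
        assert s.percent_with_breakpoint == 100


class TestCrosstab:
    @staticmethod
    def synth(n, ours, theirs, start=0):
        return ([((f"s{start + i}", frozenset(("A", "B"))), ours)
                 for i in range(n)],
                {(f"s{start + i}", frozenset(("A", "B"))): theirs
                 for i in range(n)})

    def test_published_cells_give_40_percent(self):
        results, labels = [], {}
        start = 0
        for n, ours, theirs in ((161, True, True), (244, True, False),
                                (22, False, True), (158, False, False)):
            r, l = self.synth(n, ours, theirs, start)
            results += r
            labels.update(l)
            start += n
        ct = crosstab_with_external(results, labels)
        assert ct.cells == ((161, 244), (22, 158))
        assert ct.percent_externally_validated == 40

    def test_empty_external_set_gives_empty_crosstab(self):
        results, _ = self.synth(5, True, True)
        ct = crosstab_with_external(results, {})
        assert ct.cells == ((0, 0), (0, 0))
        assert ct.percent_externally_validated == 0

    def test_identical_labelings_have_empty_off_diagonal(self):
        res_a, lab_a = self.synth(4, True, True, 0)
        res_b, lab_b = self.synth(3, False, False, 10)
        ct = crosstab_with_external(res_a + res_b, {**lab_a, **lab_b})
        assert ct.cells == ((4, 0), (0, 3))
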