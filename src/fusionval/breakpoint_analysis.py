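"""Mechanism analyses at validated genomic breakpoints.

Covers junction microhomology against randomized control breakpoints (a
signature of microhomology-mediated / alternative end-joining), relative
sequencing-depth profiles around breakpoints (amplification signatures),
genomic-context annotation of breakpoint positions, exon-level expression
contrasts inside vs outside the fusion, and kinase fusion classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .io_formats import FusionCall, GeneAnnotation, fetch_sequence
from .wgs_validation import _open_bam

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Microhomology
# ---------------------------------------------------------------------------

@dataclass
class MicrohomologyResult:
    homology_len: int
    label: str  # none (0) / microhomologous (1-5) / homologous (>5)
    max_checked: int = 20
    truncated: bool = False


def _label(h: int) -> str:
    if h == 0:
        return "none"
    if h <= 5:
        return "microhomologous"
    return "homologous"


def _flank(fasta, chrom, pos, strand, length, downstream: bool):
    """Sequence of ``length`` bases adjacent to ``pos`` in transcript
    orientation, read 5'->3' away from/toward as specified; truncated at
    chromosome bounds."""
    chrom_len = fasta.get_reference_length(chrom)
    if strand == "+":
        if downstream:
            start, end = pos + 1, pos + length
        else:
            start, end = pos - length, pos - 1
    else:
        if downstream:
            start, end = pos - length, pos - 1
        else:
            start, end = pos + 1, pos + length
    truncated = False
    if start < 1:
        start, truncated = 1, True
    if end > chrom_len:
        end, truncated = chrom_len, True
    if start > end:
        return "", True
    return fetch_sequence(fasta, chrom, start, end, strand), truncated


def common_prefix_length(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def microhomology_at_breakpoint(reference, bp5, bp3,
                                max_checked: int = 20) -> MicrohomologyResult:
    """Junction microhomology between the two partner flanks.

    ``bp5``/``bp3`` are (chrom, pos, strand) with ``bp5.pos`` the last
    retained base of the 5' partner and ``bp3.pos`` the first retained base
    of the 3' partner, both 1-based.  The sequence the 5' partner loses
    immediately past its breakpoint is compared base-by-base with the
    retained 3' partner sequence from its breakpoint (both in transcript
    orientation); the length of the exact common prefix is the homology.
    With homology h the junction position is ambiguous within h bases - the
    hallmark of microhomology-mediated joining.
    """
    own = False
    if not isinstance(reference, pysam.FastaFile):
        reference = pysam.FastaFile(str(reference))
        own = True
    try:
        c5, p5, s5 = bp5
        c3, p3, s3 = bp3
        lost5, t1 = _flank(reference, c5, p5, s5, max_checked,
                           downstream=True)
        # retained 3' flank starts AT bp3
        if s3 == "+":
            start, end = p3, p3 + max_checked - 1
        else:
            start, end = p3 - max_checked + 1, p3
        chrom_len = reference.get_reference_length(c3)
        t2 = False
        if start < 1:
            start, t2 = 1, True
        if end > chrom_len:
            end, t2 = chrom_len, True
        kept3 = fetch_sequence(reference, c3, start, end, s3)
    finally:
        if own:
            reference.close()
    h = common_prefix_length(lost5, kept3)
    return MicrohomologyResult(homology_len=h, label=_label(h),
                               max_checked=max_checked,
                               truncated=t1 or t2)


def simulate_control_breakpoints(bp_pair, n_controls: int, window: int = 1000,
                                 seed: int = 0,
                                 chrom_lengths: Mapping[str, int] | None = None
                                 ) -> list[tuple]:
    """Random control breakpoint pairs within ``window`` of the observed pair.

    Both partners are shifted independently and uniformly within +/-window
    (clipped to chromosome bounds); a control never equals the observed
    pair.  Seeded and reproducible.
    """
    if window <= 0 or n_controls < 1:
        raise ValueError("window and n_controls must be positive")
    rng = np.random.default_rng(seed)
    (c5, p5, s5), (c3, p3, s3) = bp_pair
    out = []

    def bounds(chrom, pos):
        lo, hi = max(1, pos - window), pos + window
        if chrom_lengths and chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[chrom])
        return lo, hi

    lo5, hi5 = bounds(c5, p5)
    lo3, hi3 = bounds(c3, p3)
    while len(out) < n_controls:
        q5 = int(rng.integers(lo5, hi5 + 1))
        q3 = int(rng.integers(lo3, hi3 + 1))
        if q5 == p5 and q3 == p3:
            continue
        out.append(((c5, q5, s5), (c3, q3, s3)))
    return out


def microhomology_test(observed_lengths: Sequence[int],
                       control_lengths: Sequence[int]) -> float:
    """One-sided Mann-Whitney U p-value (observed > control), tie-corrected.

    Two identical constant samples carry no rank information; p = 1 by
    convention.
    """
    obs = np.asarray(observed_lengths, dtype=float)
    ctl = np.asarray(control_lengths, dtype=float)
    if obs.size == 0 or ctl.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([obs, ctl])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(obs, ctl, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    partner: str           # "5" or "3"
    offsets: np.ndarray    # negative = fusion-retained side
    depth_ratio: np.ndarray
    truncated: bool = False


def depth_profile(alignments, bp, retained_upstream: bool, global_mean: float,
                  partner: str = "5", flank: int = 100) -> DepthProfile:
    """Per-base depth around a breakpoint as a ratio to the global mean.

    Offsets run -flank..+flank with the fusion-retained side mapped to
    negative offsets regardless of strand or partner, so amplification of
    the fused segment appears as an elevated plateau on the left and a drop
    past the breakpoint.  ``retained_upstream`` says whether the retained
    side lies at lower genomic coordinates.
    """
    if global_mean <= 0:
        raise ValueError("global_mean must be positive")
    chrom, pos = bp[0], bp[1]
    bam, own = _open_bam(alignments)
    try:
        chrom_len = dict(zip(bam.references, bam.lengths))[chrom]
        start = max(1, pos - flank)
        end = min(chrom_len, pos + flank)
        truncated = (start != pos - flank) or (end != pos + flank)
        cov = bam.count_coverage(chrom, start - 1, end, quality_threshold=0)
        depth = np.asarray(cov, dtype=np.int64).sum(axis=0).astype(float)
    finally:
        if own:
            bam.close()
    genomic_offsets = np.arange(start, end + 1) - pos
    offsets = genomic_offsets if retained_upstream else -genomic_offsets
    order = np.argsort(offsets)
    return DepthProfile(partner=partner, offsets=offsets[order],
                        depth_ratio=depth[order] / global_mean,
                        truncated=truncated)


def amplification_summary(profile: DepthProfile, read_length: int = 100
                          ) -> tuple[float, float]:
    """(retained-side plateau mean, beyond-breakpoint mean) depth ratios.

    Junction-crossing reads are soft-clipped at the breakpoint, so aligned
    coverage tapers within about half a read length of the junction even at
    constant copy number; the copy-number plateau is therefore measured at
    offsets <= -read_length/2, and the lost side over all positive offsets.
    """
    retained = profile.depth_ratio[profile.offsets <= -(read_length // 2)]
    beyond = profile.depth_ratio[profile.offsets > 0]
    return float(retained.mean()), float(beyond.mean())


# ---------------------------------------------------------------------------
# Breakpoint genomic context
# ---------------------------------------------------------------------------

@dataclass
class BreakpointContext:
    region_class: str      # intron / CDS / UTR / intergenic
    repeat_class: str | None = None


def annotate_breakpoint_context(bp, annotation: GeneAnnotation,
                                repeats: Mapping | None = None
                                ) -> BreakpointContext:
    """Classify a breakpoint position: CDS > UTR > intron within a gene,
    intergenic otherwise; repeat class from the repeat track when hit."""
    chrom, pos = bp[0], bp[1]
    repeat_class = None
    if repeats:
        tree = repeats.get(chrom)
        if tree is not None:
            hits = tree.at(pos)
            if hits:
                repeat_class = sorted(iv.data for iv in hits)[0]
    genes = annotation.genes_at(chrom, pos)
    if not genes:
        return BreakpointContext("intergenic", repeat_class)
    best = "intron"
    for gene in genes:
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        if not in_exon:
            continue
        if (gene.cds_start is not None
                and gene.cds_start <= pos <= gene.cds_end):
            return BreakpointContext("CDS", repeat_class)
        best = "UTR"
    return BreakpointContext(best, repeat_class)


def gene_class_lengths(genes) -> dict[str, int]:
    """Total genomic length of CDS / UTR / intron across the given genes."""
    totals = {"CDS": 0, "UTR": 0, "intron": 0}
    for g in genes:
        exon_len = sum(e - s + 1 for s, e in g.exons)
        cds_len = 0
        if g.cds_start is not None:
            for s, e in g.exons:
                cds_len += max(0, min(e, g.cds_end) - max(s, g.cds_start) + 1)
        totals["CDS"] += cds_len
        totals["UTR"] += exon_len - cds_len
        totals["intron"] += g.length - exon_len
    return totals


def context_chisquare(contexts: Sequence[BreakpointContext],
                      fusion_genes) -> tuple[float, float, pd.DataFrame]:
    """Chi-square of breakpoint class counts vs length-expected proportions.

    Expectations are proportional to the total genomic length of each class
    within the fused genes (the breakpoints are constrained to the fusion
    search regions, so genome-wide lengths would be the wrong null).
    Intergenic breakpoints are outside the gene-length model and excluded.
    """
    classes = ("CDS", "UTR", "intron")
    observed = np.array([sum(c.region_class == cls for c in contexts)
                         for cls in classes], dtype=float)
    lengths = gene_class_lengths(fusion_genes)
    weights = np.array([lengths[c] for c in classes], dtype=float)
    if observed.sum() == 0 or weights.sum() == 0:
        raise ValueError("no classifiable breakpoints or zero-length classes")
    expected = weights / weights.sum() * observed.sum()
    chi2, p = stats.chisquare(observed, expected)
    table = pd.DataFrame({"observed": observed, "expected": expected},
                         index=list(classes))
    return float(chi2), float(p), table


# ---------------------------------------------------------------------------
# Exon expression contrast
# ---------------------------------------------------------------------------

def tagged_exons(gene, bp: int, side: str) -> list[bool]:
    """Which exons of ``gene`` are retained in the fusion transcript.

    For the 5' partner the exons transcribed before the junction are
    retained; for the 3' partner those after it (strand-aware).
    """
    out = []
    for s, e in gene.exons:
        if gene.strand == "+":
            retained = (e <= bp) if side == "5" else (s >= bp)
        else:
            retained = (s >= bp) if side == "5" else (e <= bp)
        out.append(retained)
    return out


def exon_expression_contrast(fusions: Sequence, annotation: GeneAnnotation,
                             exon_expression: pd.DataFrame,
                             epsilon: float = 0.01) -> dict[str, dict]:
    """In-fusion vs out-of-fusion exon expression per partner side.

    ``fusions`` is a sequence of (gene5, bp5, gene3, bp3) tuples (or
    objects with those attributes); ``exon_expression`` is a long table
    with columns gene, exon_start, exon_end, expression.  Per gene the fold
    change is mean(tagged exons)/mean(untagged exons) with an epsilon
    guard; genes lacking either exon class are skipped (logged).  Across
    genes, a one-sample t-test of the per-gene log2 fold changes against 0
    is reported separately for 5' and 3' partners.
    """
    expr = exon_expression.set_index(
        ["gene", "exon_start", "exon_end"])["expression"]
    results: dict[str, dict] = {}
    for side in ("5", "3"):
        folds, genes_used = [], []
        for fus in fusions:
            if isinstance(fus, tuple):
                g5, bp5, g3, bp3 = fus
            else:
                g5, bp5, g3, bp3 = fus.gene5, fus.bp5, fus.gene3, fus.bp3
            sym, bp = (g5, bp5) if side == "5" else (g3, bp3)
            gene = annotation.get(sym)
            if gene is None:
                logger.warning("gene %s absent from annotation; skipped", sym)
                continue
            tags = tagged_exons(gene, bp, side)
            tagged_vals, untagged_vals = [], []
            for (s, e), tag in zip(gene.exons, tags):
                key = (sym, s, e)
                if key not in expr.index:
                    continue
                (tagged_vals if tag else untagged_vals).append(
                    float(expr.loc[key]))
            if not tagged_vals or not untagged_vals:
                logger.info("gene %s lacks tagged or untagged exons; skipped",
                            sym)
                continue
            fold = float(np.mean(tagged_vals)
                         / max(np.mean(untagged_vals), epsilon))
            folds.append(fold)
            genes_used.append(sym)
        if not folds:
            raise ValueError(f"no eligible genes for side {side}")
        log_folds = np.log2(folds)
        if np.allclose(log_folds, log_folds[0]):
            pvalue = 1.0 if np.allclose(log_folds, 0.0) else 0.0
        else:
            pvalue = float(stats.ttest_1samp(log_folds, 0.0).pvalue)
        results[side] = {
            "per_gene": pd.DataFrame({"gene": genes_used, "fold": folds}),
            "mean_fold": float(np.mean(folds)),
            "geometric_mean_fold": float(2 ** np.mean(log_folds)),
            "pvalue": pvalue,
        }
    return results


# ---------------------------------------------------------------------------
# Kinase fusions
# ---------------------------------------------------------------------------

def classify_kinase_fusion(call: FusionCall, annotation: GeneAnnotation
                           ) -> str:
    """Classify a fusion as in-frame kinase, kinase promoter swap, or none.

    In-frame fusions with a kinase on either side keep an intact or
    chimeric kinase coding sequence; a promoter swap places the intact 3'
    kinase CDS under the 5' partner's promoter, which requires the 3'
    junction at or upstream of the kinase CDS start.
    """
    g5 = annotation.get(call.gene5)
    g3 = annotation.get(call.gene3)
    if g5 is None or g3 is None:
        logger.warning("unknown partner in %s-%s; classified none",
                       call.gene5, call.gene3)
        return "none"
    if call.predicted_effect == "in-frame" and (g5.is_kinase or g3.is_kinase):
        return "in_frame_kinase"
    if g3.is_kinase and g3.cds_start is not None:
        j = call.junction3.pos
        upstream_of_cds = (j <= g3.cds_start if g3.strand == "+"
                           else j >= g3.cds_end)
        if upstream_of_cds:
            return "promoter_swap_kinase"
    return "none"
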