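"""DNA-level validation of fusion transcripts in WGS alignments.

For every fusion call a search region is defined on each partner gene from
the observed fusion junction and the gene bounds.  Discordant read pairs
bridging the two regions validate the fusion; genomic breakpoints are then
localized from high-quality soft-clipped read ends near the discordant
reads, whose clipped segments are locally aligned against the opposite
partner's region.  The module also houses the unbiased discordant scan,
global depth and subsampling harness, and the summary reports.
"""

from __future__ import annotations

import dataclasses
import logging
import tempfile
import warnings
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import Align

from .io_formats import (FusionCall, GeneAnnotation, fetch_sequence,
                         reverse_complement)

logger = logging.getLogger(__name__)


@dataclass
class ValidationConfig:
    min_mapq: int = 20
    min_discordant_pairs: int = 1
    min_clip_len: int = 12
    min_clip_baseq: float = 20.0
    clip_search_window: int = 1000
    min_align_identity: float = 0.9
    min_align_len: int = 12
    breakpoint_cluster_radius: int = 5
    region_padding: int = 1000
    depth_stride: int = 100
    subsample_fractions: tuple = (0.25, 0.50, 0.75)
    subsample_seed: int = 123
    match_score: float = 1.0
    mismatch_score: float = -4.0
    open_gap_score: float = -6.0
    extend_gap_score: float = -1.0

    def __post_init__(self):
        if not 0.0 < self.min_align_identity <= 1.0:
            raise ValueError("min_align_identity must be in (0, 1]")
        for name in ("min_mapq", "min_discordant_pairs", "min_clip_len",
                     "clip_search_window", "min_align_len",
                     "breakpoint_cluster_radius", "region_padding",
                     "depth_stride"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SearchRegionPair:
    region5: Region
    region3: Region


@dataclass(frozen=True)
class DiscordantPair:
    read_name: str
    pos5: int
    pos3: int
    mapq5: int
    mapq3: int
    orient5: str
    orient3: str


@dataclass
class BreakpointPair:
    bp5: tuple  # (chrom, pos)
    bp3: tuple
    support: int
    clip_side5: str = "right"
    clip_side3: str = "left"


@dataclass
class ValidationResult:
    call: FusionCall
    n_discordant: int
    breakpoints: list = field(default_factory=list)
    status: str = "not_validated"
    error: str | None = None

    @property
    def validated(self) -> bool:
        return self.status in ("validated", "validated_with_breakpoint")

    @property
    def key(self) -> tuple:
        return (self.call.sample_id, self.call.partner_key)


# ---------------------------------------------------------------------------
# Alignment file handling
# ---------------------------------------------------------------------------

def prepare_alignments(alignments, work_dir=None) -> Path:
    """Return a coordinate-sorted, indexed BAM for ``alignments``.

    Accepts a SAM or BAM path.  SAM input (or unindexed BAM) is sorted and
    indexed into a sibling ``.fv.bam`` file (or ``work_dir`` when given);
    re-used if already present and newer than the source.
    """
    src = Path(alignments)
    if src.suffix == ".bam":
        for idx in (src.with_suffix(".bam.bai"), src.with_suffix(".bai")):
            if idx.exists():
                return src
        pysam.index(str(src))
        return src
    out_dir = Path(work_dir) if work_dir else src.parent
    bam = out_dir / (src.name + ".fv.bam")
    if not (bam.exists() and bam.stat().st_mtime >= src.stat().st_mtime
            and Path(str(bam) + ".bai").exists()):
        pysam.sort("-o", str(bam), str(src))
        pysam.index(str(bam))
    return bam


def _open_bam(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    return pysam.AlignmentFile(str(prepare_alignments(alignments))), True


def chromosome_lengths(alignments) -> dict[str, int]:
    bam, own = _open_bam(alignments)
    try:
        return dict(zip(bam.references, bam.lengths))
    finally:
        if own:
            bam.close()


# ---------------------------------------------------------------------------
# Search regions
# ---------------------------------------------------------------------------

def define_search_regions(call: FusionCall, annotation: GeneAnnotation,
                          config: ValidationConfig | None = None,
                          chrom_lengths: Mapping[str, int] | None = None
                          ) -> SearchRegionPair:
    """Search region per partner: from the gene boundary on the retained
    (transcribed) side of the junction to the junction plus padding past it.

    For a plus-strand 5' partner the retained side is upstream, so the
    region runs [gene start, junction + padding]; the 3' partner mirrors
    this.  A junction outside the gene (beyond padding) triggers a warning
    and a region centered on the junction.  Regions are clipped to
    chromosome bounds when lengths are provided.
    """
    config = config or ValidationConfig()
    pad = config.region_padding
    regions = []
    for which, symbol, junction in (("5", call.gene5, call.junction5),
                                    ("3", call.gene3, call.junction3)):
        gene = annotation.get(symbol)
        if gene is None:
            raise KeyError(f"unknown gene symbol {symbol!r}")
        j = junction.pos
        if j < gene.start - pad or j > gene.end + pad:
            warnings.warn(
                f"junction {junction.chrom}:{j} outside gene {symbol} "
                f"[{gene.start}, {gene.end}] +/- padding; centering region "
                "on the junction")
            start, end = j - pad, j + pad
        else:
            retained_upstream = (gene.strand == "+") == (which == "5")
            if retained_upstream:
                start, end = min(gene.start, j), j + pad
            else:
                start, end = j - pad, max(gene.end, j)
        start = max(1, start)
        if chrom_lengths and junction.chrom in chrom_lengths:
            end = min(end, chrom_lengths[junction.chrom])
            start = min(start, end)
        regions.append(Region(junction.chrom, start, end))
    return SearchRegionPair(region5=regions[0], region3=regions[1])


# ---------------------------------------------------------------------------
# Discordant pairs
# ---------------------------------------------------------------------------

def _read_passes_qc(read, min_mapq: int) -> bool:
    return not (read.is_unmapped or read.mate_is_unmapped
                or read.is_secondary or read.is_supplementary
                or read.is_duplicate) and read.mapping_quality >= min_mapq


def _fetch_region_reads(bam, region: Region, min_mapq: int) -> dict:
    """QC-passing reads whose leftmost position lies inside the region,
    keyed by (name, mate-index)."""
    out = {}
    if region.chrom not in bam.references:
        return out
    for read in bam.fetch(region.chrom, max(0, region.start - 1), region.end):
        if not _read_passes_qc(read, min_mapq):
            continue
        pos = read.reference_start + 1
        if not (region.start <= pos <= region.end):
            continue
        out[(read.query_name, 1 if read.is_read1 else 2)] = read
    return out


def extract_discordant_pairs(alignments, regions: SearchRegionPair,
                             config: ValidationConfig | None = None
                             ) -> list[DiscordantPair]:
    """Read pairs with one mate in each partner region, both passing QC.

    Properly paired reads (concordant insert on the same chromosome) are
    excluded, as are duplicates, secondary/supplementary records and pairs
    below ``min_mapq`` on either mate.  A pair bridging overlapping regions
    is counted once; without duplicate marking, pairs with identical
    (pos5, pos3, orientation) are collapsed to one.
    """
    config = config or ValidationConfig()
    bam, own = _open_bam(alignments)
    try:
        reads5 = _fetch_region_reads(bam, regions.region5, config.min_mapq)
        reads3 = _fetch_region_reads(bam, regions.region3, config.min_mapq)
    finally:
        if own:
            bam.close()

    pairs = []
    seen_names = set()
    for (name, mate_idx), r5 in reads5.items():
        other = (name, 2 if mate_idx == 1 else 1)
        r3 = reads3.get(other)
        if r3 is None or name in seen_names:
            continue
        if r5.is_proper_pair or r3.is_proper_pair:
            continue
        seen_names.add(name)
        pairs.append(DiscordantPair(
            read_name=name,
            pos5=r5.reference_start + 1, pos3=r3.reference_start + 1,
            mapq5=r5.mapping_quality, mapq3=r3.mapping_quality,
            orient5="-" if r5.is_reverse else "+",
            orient3="-" if r3.is_reverse else "+"))

    # collapse optical/PCR duplicates when the file carries no dup marking
    unique = {}
    for p in pairs:
        key = (p.pos5, p.pos3, p.orient5, p.orient3)
        unique.setdefault(key, p)
    return sorted(unique.values(), key=lambda p: (p.pos5, p.pos3, p.read_name))


# ---------------------------------------------------------------------------
# Breakpoints from soft-clipped reads
# ---------------------------------------------------------------------------

def _make_aligner(config: ValidationConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.open_gap_score
    aligner.extend_gap_score = config.extend_gap_score
    return aligner


def _best_local_alignment(aligner, target: str, query: str):
    """Best local alignment of query against target in either orientation.

    Returns (score, target_start_1based, target_end_1based, n_matches,
    aligned_query_len, orientation) or None.  Ties prefer plus orientation.
    """
    best = None
    for orient, q in (("+", query), ("-", reverse_complement(query))):
        if not q:
            continue
        alns = aligner.align(target, q)
        try:
            aln = alns[0]
        except (IndexError, ValueError):
            continue
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            continue
        matches = 0
        qlen = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            qlen += qe - qs
            for a, b in zip(target[ts:te], q[qs:qe]):
                if a == b:
                    matches += 1
        entry = (aln.score, int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]),
                 matches, qlen, orient)
        if best is None or entry[0] > best[0]:
            best = entry
    return best


def _soft_clips(read, min_len: int, min_baseq: float):
    """Yield (side, clip_seq, boundary_pos_1based) for qualifying clips."""
    cig = read.cigartuples
    if not cig:
        return
    quals = read.query_qualities
    seq = read.query_sequence
    if seq is None:
        return
    if cig[0][0] == 4 and cig[0][1] >= min_len:
        clen = cig[0][1]
        if quals is None or np.mean(quals[:clen]) >= min_baseq:
            yield "left", seq[:clen], read.reference_start + 1
    if cig[-1][0] == 4 and cig[-1][1] >= min_len:
        clen = cig[-1][1]
        if quals is None or np.mean(quals[-clen:]) >= min_baseq:
            yield "right", seq[-clen:], read.reference_end


def find_breakpoints(alignments, discordant_pairs: Sequence[DiscordantPair],
                     regions: SearchRegionPair, reference,
                     config: ValidationConfig | None = None
                     ) -> list[BreakpointPair]:
    """Localize genomic breakpoints from soft-clipped reads near the
    discordant pairs.

    Soft-clipped ends (>= ``min_clip_len`` nt, mean base quality >=
    ``min_clip_baseq``) within ``clip_search_window`` of any discordant
    mate are locally aligned against the opposite partner's region sequence
    in both orientations (better score wins, ties toward plus).  A clip
    passing identity/length thresholds yields a candidate breakpoint at the
    clip boundary on its own partner and at the junction-adjacent end of
    the alignment on the other partner.  Candidates within
    ``breakpoint_cluster_radius`` are merged; the representative position is
    the support-weighted mode (ties toward the smaller coordinate).
    Returned sorted by support, descending.
    """
    config = config or ValidationConfig()
    if not discordant_pairs:
        return []
    aligner = _make_aligner(config)

    fasta_own = False
    if not isinstance(reference, pysam.FastaFile):
        reference = pysam.FastaFile(str(reference))
        fasta_own = True
    bam, bam_own = _open_bam(alignments)
    try:
        region_seq = {}
        for tag, region in (("5", regions.region5), ("3", regions.region3)):
            if region.chrom not in reference.references:
                raise KeyError(f"chromosome {region.chrom!r} missing from "
                               "reference")
            region_seq[tag] = fetch_sequence(
                reference, region.chrom, region.start, region.end)

        candidates = []  # (bp5_pos, bp3_pos)
        for tag, region, partner in (("5", regions.region5, "3"),
                                     ("3", regions.region3, "5")):
            anchor_pos = sorted({p.pos5 if tag == "5" else p.pos3
                                 for p in discordant_pairs})
            if not anchor_pos:
                continue
            windows = _merge_windows(anchor_pos, config.clip_search_window,
                                     region)
            partner_region = regions.region3 if partner == "3" else regions.region5
            seen = set()
            for wstart, wend in windows:
                for read in bam.fetch(region.chrom, wstart - 1, wend):
                    key = (read.query_name, read.flag, read.reference_start)
                    if key in seen:
                        continue
                    seen.add(key)
                    if (read.is_unmapped or read.is_secondary
                            or read.is_supplementary or read.is_duplicate
                            or read.mapping_quality < config.min_mapq):
                        continue
                    for side, clip_seq, boundary in _soft_clips(
                            read, config.min_clip_len, config.min_clip_baseq):
                        hit = _best_local_alignment(
                            aligner, region_seq[partner], clip_seq)
                        if hit is None:
                            continue
                        score, t1, t2, matches, qlen, orient = hit
                        if qlen < config.min_align_len:
                            continue
                        if matches / qlen < config.min_align_identity:
                            continue
                        # junction-adjacent end of the clip alignment on the
                        # partner: first clipped base for right clips, last
                        # for left clips (swapped in reverse orientation)
                        if (side == "right") == (orient == "+"):
                            partner_pos = partner_region.start + t1 - 1
                        else:
                            partner_pos = partner_region.start + t2 - 1
                        if tag == "5":
                            candidates.append((boundary, partner_pos))
                        else:
                            candidates.append((partner_pos, boundary))
    finally:
        if bam_own:
            bam.close()
        if fasta_own:
            reference.close()

    clusters = _cluster_candidates(candidates, config.breakpoint_cluster_radius)
    out = []
    for members in clusters:
        bp5 = _weighted_mode(m[0] for m in members)
        bp3 = _weighted_mode(m[1] for m in members)
        out.append(BreakpointPair(
            bp5=(regions.region5.chrom, bp5),
            bp3=(regions.region3.chrom, bp3),
            support=len(members)))
    out.sort(key=lambda b: (-b.support, b.bp5[1], b.bp3[1]))
    return out


def _merge_windows(positions, window, region: Region):
    intervals = []
    for p in positions:
        s = max(region.start, p - window)
        e = min(region.end, p + window)
        if intervals and s <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((s, e))
    return intervals


def _cluster_candidates(candidates, radius):
    """Greedy single-linkage clustering of (bp5, bp3) candidates."""
    remaining = sorted(candidates)
    clusters = []
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        changed = True
        while changed:
            changed = False
            keep = []
            for c in remaining:
                if any(abs(c[0] - m[0]) <= radius and abs(c[1] - m[1]) <= radius
                       for m in members):
                    members.append(c)
                    changed = True
                else:
                    keep.append(c)
            remaining = keep
        clusters.append(members)
    return clusters


def _weighted_mode(values) -> int:
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def validate_fusion(call: FusionCall, alignments, reference,
                    annotation: GeneAnnotation,
                    config: ValidationConfig | None = None
                    ) -> ValidationResult:
    """Validate one fusion call: regions -> discordant pairs -> breakpoints."""
    config = config or ValidationConfig()
    regions = define_search_regions(call, annotation, config,
                                    chromosome_lengths(alignments))
    pairs = extract_discordant_pairs(alignments, regions, config)
    if len(pairs) < config.min_discordant_pairs:
        return ValidationResult(call=call, n_discordant=len(pairs),
                                status="not_validated")
    bps = find_breakpoints(alignments, pairs, regions, reference, config)
    status = "validated_with_breakpoint" if bps else "validated"
    return ValidationResult(call=call, n_discordant=len(pairs),
                            breakpoints=bps, status=status)


def validate_calls(calls: Iterable[FusionCall], alignments, reference,
                   annotation: GeneAnnotation,
                   config: ValidationConfig | None = None
                   ) -> list[ValidationResult]:
    """Batch validation; per-fusion failures are recorded and the batch
    continues."""
    results = []
    for call in calls:
        try:
            results.append(validate_fusion(call, alignments, reference,
                                           annotation, config))
        except Exception as exc:  # noqa: BLE001 - per-fusion isolation
            logger.warning("validation failed for %s-%s: %s",
                           call.gene5, call.gene3, exc)
            results.append(ValidationResult(call=call, n_discordant=0,
                                            status="not_validated",
                                            error=str(exc)))
    return results


# ---------------------------------------------------------------------------
# Depth, subsampling, scans, summaries
# ---------------------------------------------------------------------------

def global_depth(alignments, stride: int = 100) -> float:
    """Mean depth over positions 1, 1+stride, ... pooled across chromosomes."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    bam, own = _open_bam(alignments)
    try:
        if bam.mapped == 0:
            warnings.warn("alignment file contains no mapped reads")
            return 0.0
        sampled = []
        for chrom, length in zip(bam.references, bam.lengths):
            cov = bam.count_coverage(chrom, 0, length, quality_threshold=0)
            total = np.asarray(cov, dtype=np.int64).sum(axis=0)
            sampled.append(total[::stride])
        return float(np.concatenate(sampled).mean())
    finally:
        if own:
            bam.close()


def subsample_reads(alignments, fraction: float, seed: int, out_bam) -> Path:
    """Read-name-level downsampling: both mates kept or dropped together."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    bam, own = _open_bam(alignments)
    try:
        with pysam.AlignmentFile(str(out_bam), "wb", template=bam) as out:
            for read in bam.fetch():
                h = zlib.crc32(f"{seed}:{read.query_name}".encode())
                if h / 2 ** 32 < fraction:
                    out.write(read)
    finally:
        if own:
            bam.close()
    pysam.index(str(out_bam))
    return Path(out_bam)


def subsample_validate(calls: Sequence[FusionCall], alignments, reference,
                       annotation: GeneAnnotation,
                       fractions: Sequence[float] | None = None,
                       seed: int | None = None,
                       config: ValidationConfig | None = None,
                       work_dir=None) -> dict[float, float]:
    """Retention of full-coverage validated fusions after read subsampling.

    For each fraction the alignments are downsampled at the read-name level
    (before any other filtering), the validation pipeline is re-run, and the
    proportion of originally-validated fusions still validated is reported.
    """
    config = config or ValidationConfig()
    fractions = tuple(fractions if fractions is not None
                      else config.subsample_fractions)
    seed = config.subsample_seed if seed is None else seed
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")

    full = validate_calls(calls, alignments, reference, annotation, config)
    baseline = {r.key for r in full if r.validated}
    retention = {}
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        for f in sorted(fractions):
            sub = subsample_reads(alignments, f, seed,
                                  Path(tmp) / f"sub_{f:.2f}.bam")
            res = validate_calls(calls, sub, reference, annotation, config)
            still = {r.key for r in res if r.validated}
            retention[f] = (len(baseline & still) / len(baseline)
                            if baseline else float("nan"))
    return retention


def unbiased_discordant_scan(alignments, annotation: GeneAnnotation,
                             config: ValidationConfig | None = None
                             ) -> Counter:
    """Counts of QC-passing discordant pairs per unordered gene pair.

    Scans every read once; a pair contributes when its two mates fall in
    two different annotated genes (intra-gene pairs are ignored).  The mate
    mapping quality is taken from the MQ tag when present.
    """
    config = config or ValidationConfig()
    counts: Counter = Counter()
    bam, own = _open_bam(alignments)
    try:
        for read in bam.fetch():
            if (read.is_unmapped or read.mate_is_unmapped or read.is_secondary
                    or read.is_supplementary or read.is_duplicate
                    or read.is_proper_pair
                    or read.mapping_quality < config.min_mapq):
                continue
            self_key = (read.reference_id, read.reference_start,
                        1 if read.is_read1 else 2)
            mate_key = (read.next_reference_id, read.next_reference_start,
                        2 if read.is_read1 else 1)
            if self_key > mate_key:  # count each pair exactly once
                continue
            if read.has_tag("MQ") and read.get_tag("MQ") < config.min_mapq:
                continue
            genes_a = annotation.genes_at(read.reference_name,
                                          read.reference_start + 1)
            genes_b = annotation.genes_at(read.next_reference_name,
                                          read.next_reference_start + 1)
            if not genes_a or not genes_b:
                continue
            syms_a = {g.symbol for g in genes_a}
            syms_b = {g.symbol for g in genes_b}
            if syms_a & syms_b:
                continue  # both mates in (or overlapping) the same gene
            pair = frozenset((genes_a[0].symbol, genes_b[0].symbol))
            counts[pair] += 1
    finally:
        if own:
            bam.close()
    return counts


def shannon_diversity(counts) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i (natural-log units)."""
    if isinstance(counts, Mapping):
        values = np.asarray(list(counts.values()), dtype=float)
    else:
        values = np.asarray(list(counts), dtype=float)
    if values.size == 0 or (values < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    total = values.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class ValidationSummary:
    n_results: int
    n_validated: int
    n_with_breakpoint: int
    percent_with_breakpoint: int  # of validated, rounded for display
    per_sample_mean_validated: float = float("nan")


def summarize_validation(results, n_with_breakpoint: int | None = None
                         ) -> ValidationSummary:
    """Summary counts; ``percent_with_breakpoint`` is relative to validated
    fusions, rounded to the nearest integer for display.

    Accepts either a list of :class:`ValidationResult` or a pair of counts
    ``summarize_validation(n_validated, n_with_breakpoint)``.
    """
    if n_with_breakpoint is not None:
        n_validated = int(results)
        nb = int(n_with_breakpoint)
        pct = int(round(100.0 * nb / n_validated)) if n_validated else 0
        return ValidationSummary(n_results=n_validated,
                                 n_validated=n_validated,
                                 n_with_breakpoint=nb,
                                 percent_with_breakpoint=pct)
    results = list(results)
    validated = [r for r in results if r.validated]
    with_bp = [r for r in validated if r.breakpoints]
    pct = (int(round(100.0 * len(with_bp) / len(validated)))
           if validated else 0)
    by_sample = defaultdict(int)
    for r in validated:
        by_sample[r.call.sample_id] += 1
    mean_per_sample = (float(np.mean(list(by_sample.values())))
                       if by_sample else 0.0)
    return ValidationSummary(
        n_results=len(results), n_validated=len(validated),
        n_with_breakpoint=len(with_bp), percent_with_breakpoint=pct,
        per_sample_mean_validated=mean_per_sample)


@dataclass
class CrosstabResult:
    cells: tuple  # ((v_v, v_n), (n_v, n_n)) pipeline x external
    percent_externally_validated: int  # of pipeline-validated overlap fusions


def crosstab_with_external(pipeline_results,
                           external_labels: Mapping) -> CrosstabResult:
    """2x2 crosstab of pipeline validation status vs an external label set.

    ``external_labels`` maps join keys (sample, unordered partner pair) to
    the external validated flag; only fusions present there (the overlap
    set) are tabulated.  ``percent_externally_validated`` =
    100 * cell11 / (cell11 + cell12), rounded.
    """
    cells = [[0, 0], [0, 0]]
    for item in pipeline_results:
        if isinstance(item, ValidationResult):
            key, ours = item.key, item.validated
        else:  # (key, validated) pair
            key, ours = item
        if key not in external_labels:
            continue
        theirs = bool(external_labels[key])
        cells[0 if ours else 1][0 if theirs else 1] += 1
    row = cells[0][0] + cells[0][1]
    pct = int(round(100.0 * cells[0][0] / row)) if row else 0
    return CrosstabResult(cells=tuple(tuple(r) for r in cells),
                          percent_externally_validated=pct)


def write_validation_tsv(results: Sequence[ValidationResult], path) -> None:
    """One row per fusion: sample, partners, support and best breakpoint."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgene5\tgene3\tn_discordant\tbp5\tbp3\t"
                 "support\tstatus\n")
        for r in results:
            if r.breakpoints:
                top = r.breakpoints[0]
                bp5 = f"{top.bp5[0]}:{top.bp5[1]}"
                bp3 = f"{top.bp3[0]}:{top.bp3[1]}"
                support = str(top.support)
            else:
                bp5 = bp3 = support = "NA"
            fh.write("\t".join([r.call.sample_id, r.call.gene5, r.call.gene3,
                                str(r.n_discordant), bp5, bp3, support,
                                r.status]) + "\n")
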