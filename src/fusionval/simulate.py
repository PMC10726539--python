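"""Synthetic fusion dataset generator.

Builds a small multi-chromosome reference with exon/intron gene models,
plants intra- and interchromosomal fusions with configurable junction
microhomology and segmental amplification, emits paired-end WGS reads as SAM
(concordant background pairs, junction-straddling discordant pairs, and
junction-crossing soft-clipped reads), and writes caller-style TSVs for the
true fusions plus decoy false positives with realistic feature contrasts.

Reads are emitted pre-"aligned": SAM coordinates are computed analytically
from the planted junctions, keeping the test loop hermetic and deterministic.
Every artefact is a pure function of :class:`SimulationConfig` (seed
included).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .io_formats import (FusionCall, GeneAnnotation, GeneModel, Junction,
                         write_arriba_tsv, write_fusioncatcher_tsv)
from .prefilter import DEFAULT_BANNED_TAGS


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple = (3, 8)
    n_true_fusions: int = 10
    fraction_intrachromosomal: float = 0.7
    microhomology_max: int = 8          # planted lengths cycle over 0..max
    amplification_factors: tuple = (3, 2, 1)  # cycled over intrachromosomal fusions
    base_depth: float = 30.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    n_decoy_calls: int = 90
    base_quality: int = 35
    retained_segment_len: tuple = (2000, 3000)
    seed: int = 1

    def __post_init__(self):
        if not 0.0 <= self.fraction_intrachromosomal <= 1.0:
            raise ValueError("fraction_intrachromosomal must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "n_true_fusions", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedReference:
    """In-memory reference: editable sequences + gene models + repeats."""

    seqs: dict            # chrom -> bytearray of ACGT (0-based)
    genes: list           # list[GeneModel]
    repeats: list         # list of (chrom, start, end) 1-based inclusive
    mirna_hosts: set = field(default_factory=set)
    snorna_hosts: set = field(default_factory=set)
    cosmic: set = field(default_factory=set)
    kinases: set = field(default_factory=set)

    @property
    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.genes)

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive fetch from the in-memory sequence."""
        return self.seqs[chrom][start - 1:end].decode()

    def write_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for chrom in sorted(self.seqs):
                fh.write(f">{chrom}\n")
                seq = self.seqs[chrom].decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        pysam.faidx(str(path))

    def write_gtf(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                         f'gene_biotype "{g.biotype}";')
                fh.write("\t".join([g.chrom, "sim", "gene", str(g.start),
                                    str(g.end), ".", g.strand, ".", attrs])
                         + "\n")
                for s, e in g.exons:
                    fh.write("\t".join([g.chrom, "sim", "exon", str(s), str(e),
                                        ".", g.strand, ".", attrs]) + "\n")
                if g.cds_start is not None:
                    for s, e in g.exons:
                        cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                        if cs <= ce:
                            fh.write("\t".join(
                                [g.chrom, "sim", "CDS", str(cs), str(ce), ".",
                                 g.strand, "0", attrs]) + "\n")

    def write_repeats_bed(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for chrom, start, end in self.repeats:
                # BED is 0-based half-open
                fh.write(f"{chrom}\t{start - 1}\t{end}\trepeat\n")


@dataclass
class FusionTruth:
    gene5: str
    gene3: str
    chrom5: str
    bp5: int              # last retained base of the 5' partner (1-based)
    chrom3: str
    bp3: int              # first retained base of the 3' partner (1-based)
    intrachromosomal: bool
    microhomology_len: int
    amplification_factor: int
    seg5_start: int       # retained 5' segment = [seg5_start, bp5]
    seg3_end: int         # retained 3' segment = [bp3, seg3_end]
    label: bool = True

    @property
    def derivative_name(self) -> str:
        return f"der_{self.gene5}_{self.gene3}"


_BASES = b"ACGT"


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Random reference with non-overlapping genes and a repeat track.

    Gene bodies are tiled along each chromosome with >= ~4 kb intergenic
    gaps (so a concordant fragment can never bridge two genes' search
    regions), each with 3-8 exons and a CDS spanning the interior of the
    transcript.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    seqs = {}
    genes = []
    repeats = []
    per_chrom = config.n_genes // config.n_chromosomes
    extra = config.n_genes - per_chrom * config.n_chromosomes
    gene_idx = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        seqs[chrom] = bytearray(
            bytes(_BASES[b] for b in rng.integers(0, 4, size=L)))
        n_here = per_chrom + (1 if ci < extra else 0)
        pos = int(rng.integers(4000, 8000))
        for _ in range(n_here):
            glen = int(rng.integers(8000, 16000))
            if pos + glen + 4000 > L:
                raise ValueError(
                    "genes do not fit chromosome; increase chrom_length or "
                    "reduce n_genes")
            start, end = pos, pos + glen - 1
            # 4 of 5 genes plus-strand, interleaved so no chromosome starves
            # the fusion partner pool
            strand = "-" if gene_idx % 5 == 4 else "+"
            k = int(rng.integers(config.exons_per_gene[0],
                                 config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(150, 400, size=k)
            total_intron = glen - int(exon_lens.sum())
            cuts = np.sort(rng.integers(0, total_intron + 1, size=k - 1))
            intron_lens = np.diff(np.concatenate([[0], cuts, [total_intron]]))
            exons = []
            p = start
            for ei in range(k):
                if ei > 0:
                    p += int(intron_lens[ei])
                exons.append((p, p + int(exon_lens[ei]) - 1))
                p = exons[-1][1] + 1
            exons[-1] = (exons[-1][0], end)
            first, last = exons[0], exons[-1]
            cds_start = (first[0] + first[1]) // 2
            cds_end = (last[0] + last[1]) // 2
            gene_idx += 1
            genes.append(GeneModel(
                gene_id=f"G{gene_idx:03d}", symbol=f"G{gene_idx:03d}",
                chrom=chrom, start=start, end=end, strand=strand,
                exons=exons, cds_start=cds_start, cds_end=cds_end))
            pos = end + 1 + int(rng.integers(4000, 8000))
        for _ in range(30):
            rstart = int(rng.integers(1, L - 1000))
            repeats.append((chrom, rstart, rstart + int(rng.integers(200, 1000))))
    symbols = [g.symbol for g in genes]
    ref = SimulatedReference(seqs=seqs, genes=genes, repeats=sorted(repeats))
    ref.cosmic = set(rng.choice(symbols, size=6, replace=False))
    ref.kinases = set(rng.choice(symbols, size=5, replace=False))
    ref.mirna_hosts = set(rng.choice(symbols, size=4, replace=False))
    ref.snorna_hosts = set(rng.choice(symbols, size=4, replace=False))
    for g in genes:
        g.in_cosmic = g.symbol in ref.cosmic
        g.is_kinase = g.symbol in ref.kinases
        g.is_mirna_host = g.symbol in ref.mirna_hosts
        g.is_snorna_host = g.symbol in ref.snorna_hosts
    return ref


def plant_fusions(ref: SimulatedReference, config: SimulationConfig
                  ) -> list[FusionTruth]:
    """Plant fusions into the reference; returns the truth table.

    The requested junction microhomology is physically written into the
    reference: the h bases of the 5' partner immediately *past* its
    breakpoint (the lost flank) are set equal to the first h retained bases
    of the 3' partner, with a forced mismatch at position h+1 so the planted
    homology is exact.  Only lost-flank bases are edited, so derivative
    sequences and retained-side reads are unaffected.

    Fusion partners are drawn from plus-strand genes; intrachromosomal pairs
    keep the 5' partner upstream of the 3' partner.
    """
    rng = np.random.default_rng(config.seed + 1)
    plus = [g for g in ref.genes if g.strand == "+"]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in plus:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    n_intra = int(round(config.fraction_intrachromosomal
                        * config.n_true_fusions))
    used: set[str] = set()
    truths: list[FusionTruth] = []
    chroms = sorted(by_chrom)
    amp_cycle = config.amplification_factors

    def pick(chrom_list, exclude):
        avail = [g for g in chrom_list if g.symbol not in exclude]
        return avail

    intra_i = 0
    # interchromosomal fusions drain one gene from each chromosome, so they
    # are allocated first and intra picks go to the best-stocked chromosome
    order = [False] * (config.n_true_fusions - n_intra) + [True] * n_intra
    for i, intra in zip(range(config.n_true_fusions), order):
        avail_by_chrom = {c: pick(by_chrom[c], used) for c in chroms}
        ranked = sorted(chroms, key=lambda c: -len(avail_by_chrom[c]))
        if intra:
            chrom = ranked[0]
            avail = avail_by_chrom[chrom]
            if len(avail) < 2:
                raise ValueError("not enough plus-strand genes for fusions")
            idx = sorted(rng.choice(len(avail), size=2, replace=False))
            g5, g3 = avail[idx[0]], avail[idx[1]]
            amp = amp_cycle[intra_i % len(amp_cycle)]
            intra_i += 1
        else:
            c5, c3 = ranked[0], ranked[1]
            a5, a3 = avail_by_chrom[c5], avail_by_chrom[c3]
            if not (a5 and a3):
                raise ValueError("not enough plus-strand genes for fusions")
            g5 = a5[int(rng.integers(0, len(a5)))]
            g3 = a3[int(rng.integers(0, len(a3)))]
            if rng.random() < 0.5:
                g5, g3 = g3, g5
            amp = 1
        used.update((g5.symbol, g3.symbol))

        bp5 = int(rng.integers(g5.start + 1500, g5.end - 1500))
        bp3 = int(rng.integers(g3.start + 1500, g3.end - 1500))
        h = i % (config.microhomology_max + 1)

        seq5, seq3 = ref.seqs[g5.chrom], ref.seqs[g3.chrom]
        # lost flank of the 5' partner copies the retained 3' flank for h bases
        for k in range(h):
            seq5[bp5 + k] = seq3[bp3 - 1 + k]
        # force a mismatch at h+1 so homology is exactly h
        if seq5[bp5 + h] == seq3[bp3 - 1 + h]:
            current = seq5[bp5 + h]
            seq5[bp5 + h] = next(b for b in _BASES if b != current)

        L5 = int(rng.integers(*config.retained_segment_len))
        L3 = int(rng.integers(*config.retained_segment_len))
        truths.append(FusionTruth(
            gene5=g5.symbol, gene3=g3.symbol,
            chrom5=g5.chrom, bp5=bp5, chrom3=g3.chrom, bp3=bp3,
            intrachromosomal=intra, microhomology_len=h,
            amplification_factor=int(amp),
            seg5_start=max(1, bp5 - L5 + 1),
            seg3_end=min(len(seq3), bp3 + L3 - 1)))
    return truths


def derivative_sequence(ref: SimulatedReference, t: FusionTruth) -> str:
    """Derivative contig: retained 5' segment + retained 3' segment."""
    return (ref.sequence(t.chrom5, t.seg5_start, t.bp5)
            + ref.sequence(t.chrom3, t.bp3, t.seg3_end))


def _mk_read(header, name, chrom_tid, pos0, cigar, seq, qual, flagbits,
             mate_tid, mate_pos0, tlen, mapq=60):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flagbits
    a.reference_id = chrom_tid
    a.reference_start = pos0
    a.mapping_quality = mapq
    a.cigartuples = cigar
    a.query_sequence = seq
    a.query_qualities = qual
    a.next_reference_id = mate_tid
    a.next_reference_start = mate_pos0
    a.template_length = tlen
    a.set_tag("MQ", mapq)
    return a


def simulate_wgs_reads(ref: SimulatedReference, truths: list[FusionTruth],
                       config: SimulationConfig, out_sam) -> None:
    """Write a coordinate-sorted SAM of paired-end reads.

    Background reads tile every chromosome at ``base_depth``.  Each planted
    fusion contributes derivative reads at ``(a-1) x base_depth`` for
    amplification factor a >= 2 (so the retained side totals a x the genome
    average) or ``0.5 x base_depth`` for unamplified fusions (one rearranged
    allele).  Derivative fragments straddling the junction become discordant
    pairs; reads crossing the junction are soft-clipped at the breakpoint
    with the clipped bases taken from the partner locus.
    """
    rng = np.random.default_rng(config.seed + 2)
    rl = config.read_length
    chroms = sorted(ref.seqs)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(ref.seqs[c])} for c in chroms],
    })
    tid = {c: i for i, c in enumerate(chroms)}
    qual = [config.base_quality] * rl
    reads = []
    counter = 0

    def frag_lengths(n):
        f = rng.normal(config.insert_mean, config.insert_sd, size=n)
        return np.clip(f, 2 * rl + 10, config.insert_mean + 6 * config.insert_sd
                       ).astype(int)

    # background: concordant proper pairs on every chromosome
    for chrom in chroms:
        seq = ref.seqs[chrom].decode()
        L = len(seq)
        n_frag = int(config.base_depth * L / (2 * rl))
        frags = frag_lengths(n_frag)
        starts = rng.integers(0, L - frags)
        for s, f in zip(starts.tolist(), frags.tolist()):
            counter += 1
            name = f"bg{counter}"
            p1, p2 = s, s + f - rl
            t = tid[chrom]
            reads.append(_mk_read(header, name, t, p1, [(0, rl)],
                                  seq[p1:p1 + rl], qual, 0x63, t, p2, f))
            reads.append(_mk_read(header, name, t, p2, [(0, rl)],
                                  seq[p2:p2 + rl], qual, 0x93, t, p1, -f))

    # derivative reads per fusion
    for t in truths:
        dseq = derivative_sequence(ref, t)
        dlen = len(dseq)
        J = t.bp5 - t.seg5_start + 1  # derivative bases < J are 5'-side
        amp = t.amplification_factor
        depth = config.base_depth * (amp - 1 if amp >= 2 else 0.5)
        n_frag = int(depth * dlen / (2 * rl))
        frags = frag_lengths(n_frag)
        frags = np.minimum(frags, dlen)
        starts = rng.integers(0, dlen - frags + 1)
        t5, t3 = tid[t.chrom5], tid[t.chrom3]

        def map_read(a):
            b = a + rl
            if b <= J:
                return t5, t.seg5_start - 1 + a, [(0, rl)], True
            if a >= J:
                return t3, t.bp3 - 1 + (a - J), [(0, rl)], False
            left, right = J - a, b - J
            if left >= right:
                return (t5, t.seg5_start - 1 + a,
                        [(0, left), (4, right)], True)
            return t3, t.bp3 - 1, [(4, left), (0, right)], False

        for s, f in zip(starts.tolist(), frags.tolist()):
            counter += 1
            name = f"dv{counter}"
            a1, a2 = s, s + f - rl
            tid1, p1, cig1, side1_is5 = map_read(a1)
            tid2, p2, cig2, side2_is5 = map_read(a2)
            crossing1 = len(cig1) > 1
            crossing2 = len(cig2) > 1
            proper = (side1_is5 == side2_is5) and not (crossing1 or crossing2)
            base_flag = 0x1 | (0x2 if proper else 0)
            if tid1 == tid2:
                lo = min(p1, p2)
                hi = max(p1 + rl, p2 + rl)
                tl = hi - lo
                tl1, tl2 = (tl, -tl) if p1 <= p2 else (-tl, tl)
            else:
                tl1 = tl2 = 0
            reads.append(_mk_read(header, name, tid1, p1, cig1,
                                  dseq[a1:a1 + rl], qual,
                                  base_flag | 0x40 | 0x20, tid2, p2, tl1))
            reads.append(_mk_read(header, name, tid2, p2, cig2,
                                  dseq[a2:a2 + rl], qual,
                                  base_flag | 0x80 | 0x10, tid1, p1, tl2))

    reads.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as out:
        for r in reads:
            out.write(r)


# ---------------------------------------------------------------------------
# Caller-style output
# ---------------------------------------------------------------------------

def simulate_caller_output(ref: SimulatedReference, truths: list[FusionTruth],
                           config: SimulationConfig, sample_id: str = "sim1"
                           ) -> tuple[list[FusionCall], list[FusionCall]]:
    """Caller-style rows: true fusions plus decoy false positives.

    True rows draw stochastically larger read support (spanning pairs
    ~ 3 + Poisson(6)) and longer anchors (20-60 nt) than decoys (shifted
    geometric support, 13-25 nt anchors), and decoys are mostly
    interchromosomal; roughly a third of decoys carry a banned tag and a
    tenth share multi-mapping reads between partners, so pre-filtering has
    something to remove.  Returns (true_calls, decoy_calls).
    """
    rng = np.random.default_rng(config.seed + 3)
    banned = sorted(DEFAULT_BANNED_TAGS)
    ann = ref.annotation
    true_pairs = {frozenset((t.gene5, t.gene3)) for t in truths}
    fusion_genes = {g for p in true_pairs for g in p}

    true_calls = []
    for t in truths:
        effect = rng.choice(["in-frame", "out-of-frame", "UTR/intronic"],
                            p=[0.5, 0.3, 0.2])
        true_calls.append(FusionCall(
            sample_id=sample_id, gene5=t.gene5, gene3=t.gene3,
            junction5=Junction(t.chrom5, t.bp5, "+"),
            junction3=Junction(t.chrom3, t.bp3, "+"),
            spanning_pairs=int(3 + rng.poisson(6)),
            spanning_unique_reads=int(2 + rng.poisson(4)),
            longest_anchor=int(rng.integers(20, 61)),
            tags=set(),
            common_mapping_reads=0,
            predicted_effect=str(effect),
            confidence=str(rng.choice(["high", "medium", "low"],
                                      p=[0.6, 0.3, 0.1])),
        ))

    candidates = [g for g in ann.genes() if g.symbol not in fusion_genes]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in candidates:
        by_chrom.setdefault(g.chrom, []).append(g)
    decoys = []
    seen = set(true_pairs)
    while len(decoys) < config.n_decoy_calls:
        if rng.random() < 0.12 and any(len(v) >= 2 for v in by_chrom.values()):
            chrom = rng.choice([c for c, v in by_chrom.items() if len(v) >= 2])
            g5, g3 = rng.choice(by_chrom[chrom], size=2, replace=False)
        else:
            g5, g3 = rng.choice(candidates, size=2, replace=False)
        key = frozenset((g5.symbol, g3.symbol))
        if len(key) < 2 or key in seen:
            continue
        j5 = int(rng.integers(g5.start, g5.end + 1))
        j3 = int(rng.integers(g3.start, g3.end + 1))
        tags = set()
        if rng.random() < 0.35:
            tags.add(str(rng.choice(banned)))
        common = int(rng.integers(1, 4)) if rng.random() < 0.1 else 0
        decoys.append(FusionCall(
            sample_id=sample_id, gene5=g5.symbol, gene3=g3.symbol,
            junction5=Junction(g5.chrom, j5, g5.strand),
            junction3=Junction(g3.chrom, j3, g3.strand),
            spanning_pairs=int(rng.geometric(0.5)),
            spanning_unique_reads=int(rng.geometric(0.6)),
            longest_anchor=int(rng.integers(13, 26)),
            tags=tags,
            common_mapping_reads=common,
            predicted_effect=str(rng.choice(
                ["in-frame", "out-of-frame", "UTR/intronic", "unknown"],
                p=[0.15, 0.35, 0.2, 0.3])),
            confidence=str(rng.choice(["high", "medium", "low"],
                                      p=[0.1, 0.3, 0.6])),
        ))
    return true_calls, decoys


def simulate_expression(ref: SimulatedReference, truths: list[FusionTruth],
                        config: SimulationConfig, n_samples: int = 8
                        ) -> pd.DataFrame:
    """Per-gene FPKM table (genes x samples); fusion partner genes get a
     0.5x expression shift, mirroring the lower average expression of
    validated fusion partners."""
    rng = np.random.default_rng(config.seed + 4)
    genes = [g.symbol for g in ref.genes]
    fusion_genes = {t.gene5 for t in truths} | {t.gene3 for t in truths}
    base = rng.lognormal(mean=1.5, sigma=1.0, size=len(genes))
    rows = []
    for gi, sym in enumerate(genes):
        mu = base[gi] * (0.5 if sym in fusion_genes else 1.0)
        rows.append(mu * rng.lognormal(0.0, 0.3, size=n_samples))
    df = pd.DataFrame(rows, index=genes,
                      columns=[f"s{i + 1}" for i in range(n_samples)])
    df.index.name = "gene"
    return df


def simulate_exon_expression(ref: SimulatedReference,
                             truths: list[FusionTruth],
                             fold3: float = 5.0, fold5: float = 1.0,
                             noise_sd: float = 0.2, seed: int = 0
                             ) -> pd.DataFrame:
    """Exon-level expression for fusion partner genes.

    In-fusion exons of 3' partners are upregulated ``fold3``-fold relative to
    the gene's other exons (5' partners by ``fold5``); multiplicative
    log-normal noise on every exon.  Columns: gene, exon_start, exon_end,
    expression, side.
    """
    rng = np.random.default_rng(seed)
    ann = ref.annotation
    rows = []
    for t in truths:
        for side, sym, bp in (("5", t.gene5, t.bp5), ("3", t.gene3, t.bp3)):
            g = ann[sym]
            base = float(rng.lognormal(2.0, 0.3))
            fold = fold5 if side == "5" else fold3
            for s, e in g.exons:
                # retained exons: upstream of bp for the 5' partner,
                # downstream for the 3' partner (plus-strand geometry)
                retained = (e <= bp) if side == "5" else (s >= bp)
                mu = base * (fold if retained else 1.0)
                rows.append({
                    "gene": sym, "exon_start": s, "exon_end": e,
                    "expression": mu * float(rng.lognormal(0.0, noise_sd)),
                    "side": side})
    return pd.DataFrame(rows)


def simulate_feature_table(n_rows: int = 5000, pos_fraction: float = 0.01,
                           n_groups: int = 3, seed: int = 0) -> pd.DataFrame:
    """Labeled synthetic feature table for classifier benchmarks.

    True fusions stochastically dominate decoys in read support, anchor
    length and intrachromosomal fraction, have lower partner expression, and
    carry better caller confidence; no feature separates the classes on its
    own.  Columns include ``label`` (bool), ``group`` and ``sample_id``.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(n_rows * pos_fraction)))
    labels = np.zeros(n_rows, dtype=bool)
    labels[rng.choice(n_rows, size=n_pos, replace=False)] = True

    spanning = np.where(labels, 3 + rng.poisson(9, n_rows),
                        rng.geometric(0.5, n_rows))
    unique = np.maximum(0, (spanning * rng.uniform(0.5, 1.0, n_rows))
                        .astype(int))
    anchor = np.where(labels, rng.integers(20, 61, n_rows),
                      rng.integers(13, 26, n_rows))
    intra = rng.random(n_rows) < np.where(labels, 0.71, 0.12)
    distance = np.where(intra, rng.integers(10_000, 2_000_000, n_rows),
                        -1).astype(float)
    distance[~intra] = np.nan
    fpkm5 = rng.lognormal(np.where(labels, 1.0, 2.0), 1.0, n_rows)
    fpkm3 = rng.lognormal(np.where(labels, 1.0, 2.0), 1.0, n_rows)
    conf_levels = np.array(["high", "medium", "low"])
    conf_idx = np.array([
        rng.choice(3, p=[0.6, 0.3, 0.1] if lab else [0.1, 0.3, 0.6])
        for lab in labels])
    effect_levels = np.array(["in-frame", "out-of-frame", "UTR/intronic",
                              "unknown"])
    eff_idx = np.array([
        rng.choice(4, p=[0.45, 0.3, 0.15, 0.1] if lab else
                   [0.15, 0.35, 0.2, 0.3])
        for lab in labels])
    eps = 0.01
    df = pd.DataFrame({
        "spanning_pairs": spanning.astype(int),
        "spanning_unique_reads": unique,
        "longest_anchor": anchor.astype(int),
        "same_chromosome": intra,
        "genomic_distance": distance,
        "fpkm5": fpkm5, "fpkm3": fpkm3,
        "log_expr_ratio": np.log2((fpkm5 + eps) / (fpkm3 + eps)),
        "in_cosmic5": rng.random(n_rows) < 0.05,
        "in_cosmic3": rng.random(n_rows) < 0.05,
        "repeat_overlap5": rng.random(n_rows) < 0.3,
        "repeat_overlap3": rng.random(n_rows) < 0.3,
        "confidence": pd.Categorical(conf_levels[conf_idx],
                                     categories=list(conf_levels)),
        "predicted_effect": pd.Categorical(effect_levels[eff_idx],
                                           categories=list(effect_levels)),
        "label": labels,
        "group": [f"cancer{1 + i % n_groups}" for i in range(n_rows)],
        "sample_id": [f"s{rng.integers(1, 50):02d}" for _ in range(n_rows)],
    })
    return df


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, out_dir) -> dict:
    """Run the full generator and write every artefact under ``out_dir``.

    Writes genome.fa (+.fai), genes.gtf, repeats.bed, reads.sam,
    calls_fc.tsv, calls_arriba.tsv, truth.tsv, expression.tsv and the four
    gene-list files.  Returns a dict with paths and the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(config)
    truths = plant_fusions(ref, config)
    paths = {
        "fasta": out / "genome.fa", "gtf": out / "genes.gtf",
        "repeats": out / "repeats.bed", "sam": out / "reads.sam",
        "calls_fc": out / "calls_fc.tsv",
        "calls_arriba": out / "calls_arriba.tsv",
        "truth": out / "truth.tsv", "expression": out / "expression.tsv",
    }
    ref.write_fasta(paths["fasta"])
    ref.write_gtf(paths["gtf"])
    ref.write_repeats_bed(paths["repeats"])
    simulate_wgs_reads(ref, truths, config, paths["sam"])
    true_calls, decoys = simulate_caller_output(ref, truths, config)
    write_fusioncatcher_tsv(true_calls + decoys, paths["calls_fc"])
    write_arriba_tsv(true_calls + decoys, paths["calls_arriba"])
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(
        paths["truth"], sep="\t", index=False)
    simulate_expression(ref, truths, config).to_csv(
        paths["expression"], sep="\t")
    for name, genes in (("mirna_hosts", ref.mirna_hosts),
                        ("snorna_hosts", ref.snorna_hosts),
                        ("cosmic", ref.cosmic), ("kinases", ref.kinases)):
        paths[name] = out / f"{name}.txt"
        paths[name].write_text("\n".join(sorted(genes)) + "\n")
    return {"paths": paths, "reference": ref, "truths": truths,
            "true_calls": true_calls, "decoy_calls": decoys,
            "config": config}
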