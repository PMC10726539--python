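# Methods

This note documents the models and procedures implemented in `fusionval`,
the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## WGS validation pipeline

A fusion transcript call names two partner genes and a fusion junction on
each. Validation asks whether the matched WGS data contains a genomic
rearrangement joining the two loci.

**Search regions.** Each partner gets a region from the gene boundary on
the *retained* (transcribed-into-the-fusion) side of the junction to the
junction plus `region_padding` (default 1000 bp) past it. For a plus-strand
5' partner the retained side is upstream, so the region is
`[gene_start, junction + padding]`; strand and partner role flip the rule
symmetrically. A junction falling outside the gene ± padding (annotation
mismatches happen in real data) triggers a warning and a region centered on
the junction. Regions are clipped to chromosome bounds.

**Discordant pairs.** Read pairs with one mate's leftmost position in each
region qualify when both mates have MAPQ ≥ `min_mapq` (20) and neither is
unmapped, secondary, supplementary or duplicate-flagged. Properly paired
reads are excluded — the proper-pair flag is the aligner's own statement
that the insert is concordant, which also handles overlapping regions of
nearby partners. When the file carries no duplicate marking, pairs with
identical (pos5, pos3, orientation) are collapsed to one, a conservative
stand-in for PCR-duplicate removal. A fusion is *validated* when at least
`min_discordant_pairs` (default 1) such pairs exist.

**Breakpoints.** Within `clip_search_window` (1000 bp) of any discordant
mate, soft-clipped read ends with clip length ≥ `min_clip_len` (12 nt) and
mean clipped base quality ≥ `min_clip_baseq` (20) are candidate
junction-crossing reads. Each clipped segment is locally aligned
(match +1, mismatch −4, gap open −6, gap extend −1 — conventional
SV-calling scores) against the opposite partner's region sequence in both
orientations; the better score wins and ties go to plus. Alignments with
identity ≥ 0.9 over ≥ 12 aligned bases yield a breakpoint candidate: the
clip boundary on the read's own partner, and the junction-adjacent end of
the clip alignment on the other partner. Candidates within
`breakpoint_cluster_radius` (5 bp) merge; the representative position is
the support-weighted mode with ties toward the smaller coordinate, and
clusters are reported by support, descending. All thresholds live in
`ValidationConfig`.

**Depth and subsampling.** Global depth is the mean of per-base depth
sampled every `depth_stride` (100) bases, pooled over chromosomes.
Subsampling keeps or drops whole read pairs by hashing the read name with
the seed (default fractions 0.25/0.50/0.75, seed 123), before any other
filtering, then re-runs validation; retention is the fraction of
originally-validated fusions still validated.

**Unbiased scan and diversity.** Independently of any fusion call, every
QC-passing discordant pair whose mates fall in two different annotated
genes is counted per unordered gene pair, and the Shannon–Wiener index
H = −Σ pᵢ ln pᵢ summarizes how concentrated those counts are. Recurrent
artifact pairs produce low H; genuine rearrangement sets produce high H.

## Feature construction and classifier

Features deliberately use only what is available without WGS: chimeric
mRNA evidence (spanning pairs, unique spanning reads, longest anchor,
predicted reading-frame effect, remaining caller tags and a known-database
flag), expression (partner FPKMs and log₂((FPKM5 + ε)/(FPKM3 + ε)) with
ε = 0.01 so the ratio stays bounded at zero expression), and genomic
annotation (same-chromosome flag, genomic distance when intrachromosomal,
strand combination, gene lengths and exon counts, COSMIC and
miRNA/snoRNA-host status, repeat overlap within ±10 bp of the junction,
and caller confidence for Arriba-style input). Missing expression is an
explicit NaN, never a silent zero. Tag sets expand to per-tag indicator
columns; zero-variance columns are dropped and logged — the only
preprocessing, since gradient boosting handles categorical and missing
data natively.

Training tunes a LightGBM binary classifier over a seeded Latin-hypercube
sample (default 100 candidates) of num_leaves, max_depth, learning rate,
min_child_samples, feature/bagging fractions and positive-class weight —
a space-filling design that covers the space at a fixed budget. Each
candidate is scored by cross-validated PR-AUC and F1 at the working
threshold (default 0.2); the winner maximizes the rank-sum of the two with
PR-AUC deciding ties, matching the joint objective appropriate under ~1%
prevalence. Cross-validation is leave-one-group-out over cancer types by
default (10-fold as the alternative); folds use early stopping (patience
10 within 100 rounds) and the final model refits all rows at the mean
best iteration. Everything is deterministic given the seed
(single-threaded, deterministic LightGBM).

Two controls guard against self-deception. The permuted-label check
averages out-of-fold ROC-AUC over ten label permutations using fixed
default hyperparameters — tuning on permuted labels would re-introduce
selection noise, and the tuned winner's own out-of-fold score is biased
upward by the selection itself — and should sit at 0.5. Threshold
selection by Youden's J (sensitivity + specificity − 1, smallest
maximizing cut-point) is available for Arriba-style models. Classical
filters (high / high+medium confidence, ≥ 3 discordant mates, their
conjunction, in-frame only) run through the same metrics code; probability
metrics are reported only for the classifier, which is the only method
producing scores.

## Breakpoint mechanism analyses

**Microhomology.** With bp5 the last retained base of the 5' partner and
bp3 the first retained base of the 3' partner, homology is the exact
common prefix length (capped at 20 nt) of the sequence the 5' partner
*loses* immediately past bp5 and the *retained* 3' sequence from bp3, both
in transcript orientation. With homology h the junction is ambiguous
within h bases — the hallmark of microhomology-mediated end joining.
Bands: 0 none, 1–5 microhomologous, >5 homologous. Published descriptions
of flank comparison are ambiguous about which side of each breakpoint is
meant; this breakpoint-sliding definition is the self-consistent reading
(one retained flank, one lost flank) and is also what the simulator
plants. A pure reference-orientation comparison would differ only for
minus-strand partners. Controls are uniform draws within ±1 kb of each
observed breakpoint (both partners shifted independently, never equal to
the observed pair), 10 per breakpoint by default — enough to stabilize the
control distribution without dominating the rank-sum test, whose one-sided
(observed > control) tie-corrected p-value is reported. Two identical
constant samples return p = 1 by convention.

**Depth profiles.** Per-base depth over ±100 bp of a breakpoint, divided
by the global mean, with offsets flipped so the fusion-retained side is
always negative. Junction-crossing reads are soft-clipped at the
breakpoint, so aligned coverage tapers within about half a read length of
the junction even at constant copy number; the amplification summary
therefore estimates the retained-side plateau from offsets ≤ −read_length/2
and the lost side from all positive offsets.

**Genomic context.** A breakpoint inside a gene classifies CDS > UTR >
intron (exonic position inside/outside the CDS span); outside any gene,
intergenic. The cohort-level chi-square compares observed class counts
with expectations proportional to the total genomic length of each class
*within the fused genes* — observed breakpoints are constrained to the
fusion search regions, so genome-wide class lengths would be the wrong
null. Intergenic breakpoints fall outside that length model and are
excluded from the test.

**Exon expression.** Per fusion partner, exons retained in the fusion
(upstream of the junction for 5' partners, downstream for 3', strand
aware) are tagged; per gene the fold change is mean(tagged)/mean(untagged)
with the denominator floored at ε = 0.01, and a one-sample t-test of the
per-gene log₂ folds against 0 is reported separately for 5' and 3'
partners. Genes lacking either exon class are skipped and logged. The
geometric mean fold is reported alongside the arithmetic mean because it
is unbiased under multiplicative noise.

**Kinase fusions.** In-frame fusions with a kinase on either side keep a
(possibly chimeric) kinase coding sequence; a promoter swap requires the
3' partner to be a kinase with the 3' junction at or upstream of its CDS
start, so the intact kinase CDS comes under the 5' partner's promoter.

## Enrichment

Because the same gene recurs across fusion events, the partner list is a
sample *with replacement* from the expressed-gene universe (per-gene 95th
percentile FPKM ≥ 1, linear-interpolation percentile). For each gene set,
p_set is its unweighted share of the universe, k the list hits counting
multiplicity, and the p-value the upper binomial tail P(X ≥ k),
X ~ Binomial(n, p_set); multiplicity is not counted in p_set (the natural
reading of a with-replacement draw from the universe). Benjamini–Hochberg
correction applies across sets within each stratum (cancer type × partner
side).

## The simulator

The generator exists so that every stage has known ground truth: a
2 × 1 Mb genome (defaults) with 40 non-overlapping genes (3–8 exons, CDS
spanning the transcript interior, one in five genes minus-strand,
interleaved), a repeat track, 10 planted fusions (70% intrachromosomal,
matching the intrachromosomal excess of validated fusions; junction
microhomology cycling 0–8 nt, physically written into the reference by
editing the lost 5' flank; amplification factors cycling 3/2/1 over
intrachromosomal fusions), paired-end 2×100 bp reads at 30× with insert
350 ± 50, and caller-style tables where 10 true rows and 90 decoys differ
in read support (3 + Poisson(6) vs shifted geometric), anchor length
(20–60 vs 13–25 nt), intrachromosomal fraction (0.7 vs 0.12) and partner
expression (0.5× for fusion genes) — the direction of every contrast the
classifier exploits, with about a third of decoys carrying banned tags.

Reads are emitted pre-"aligned": coordinates, flags and soft-clips are
computed analytically from the planted junctions, which keeps the loop
hermetic and deterministic (base qualities constant Phred 35, MAPQ 60).
An amplification factor *a* adds derivative reads at (a−1) × base depth on
top of the unrearranged background, so the retained side totals a× the
genome average; unamplified fusions emit derivative reads at 0.5 × base
depth — one rearranged allele of a diploid locus — so junction evidence
always exists. Junction-crossing reads are soft-clipped on their
minority side, as a local aligner would place them.

What the simulator does *not* emulate: sequencing errors and quality
decay, PCR/optical duplicates, repetitive or low-complexity genomes
(sequence is i.i.d. random, so clip alignments are unambiguous),
multi-mapping, RNA-level artifacts (read-through chimeras, reverse-
transcription template switching), subclonal rearrangements, and real
inter-gene dependence of expression. Passing tests therefore demonstrate
the correctness of the mechanics — region logic, pair extraction, clip
alignment and clustering, statistics, training loop — not performance on
real tumor data, where caller artifacts and alignment ambiguity dominate.

## Problem sizes and numerical choices

The test suite runs reduced configurations (e.g. 2 × 220 kb genomes, 12
genes, 4 fusions at 20×) chosen to exercise every code path in seconds;
the acceptance checks run the full default simulation (2 × 1 Mb, 10
fusions at 30×), a 50-breakpoint planted cohort for the microhomology
contrast, and the 5000-row / 1%-positive / 3-group classifier benchmark.
Percentile computation uses linear interpolation; BH q-values come from
the standard step-up procedure; Mann–Whitney uses the tie-corrected
normal approximation (exact for small untied samples); breakpoint
clustering is greedy single-linkage, adequate at radius 5 bp. Alignment
of SAM input is converted on the fly to a sorted, indexed sibling BAM and
cached.

## Known limitations

Discordant-pair orientation consistency with the fusion's predicted strand
configuration is not enforced (the evidence requirement is the pair's
location, not its orientation); multiple distinct breakpoint pairs per
fusion are all retained with the top-supported one in summaries; the
FusionCatcher column set drifts across versions and is handled by an alias
map rather than strict schema; and the classifier's hyperparameter ranges
are sensible defaults, not a reproduction of any particular published
grid.
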