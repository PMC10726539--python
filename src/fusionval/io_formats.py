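"""Readers/writers for the formats the pipeline touches.

Caller output tables (FusionCatcher-style and Arriba-style TSV dialects) are
normalized into a single internal representation, :class:`FusionCall`.  Gene
models come from GTF, repeats from BED, sequence from an indexed FASTA.

All internal coordinates are 1-based inclusive, matching GTF and the caller
outputs; BED intervals are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

PREDICTED_EFFECTS = ("in-frame", "out-of-frame", "UTR/intronic", "unknown")
CONFIDENCE_LEVELS = ("high", "medium", "low", "none")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A malformed input table or annotation file."""


class RowError(FormatError):
    """A single unparseable row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Junction:
    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"junction position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class FusionCall:
    """One fusion transcript prediction from a caller output table."""

    sample_id: str
    gene5: str
    gene3: str
    junction5: Junction
    junction3: Junction
    spanning_pairs: int = 0
    spanning_unique_reads: int = 0
    longest_anchor: int = 0
    tags: set = field(default_factory=set)
    common_mapping_reads: int = 0
    predicted_effect: str = "unknown"
    confidence: str = "none"
    caller: str = "fusioncatcher-like"

    def __post_init__(self):
        for name in ("spanning_pairs", "spanning_unique_reads", "longest_anchor",
                     "common_mapping_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.predicted_effect not in PREDICTED_EFFECTS:
            raise ValueError(f"invalid predicted_effect {self.predicted_effect!r}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"invalid confidence {self.confidence!r}")

    @property
    def partner_key(self) -> frozenset:
        """Unordered partner-symbol pair (reciprocal calls compare equal)."""
        return frozenset((self.gene5, self.gene3))


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list = field(default_factory=list)  # list of (start, end) 1-based
    cds_start: int | None = None
    cds_end: int | None = None
    is_mirna_host: bool = False
    is_snorna_host: bool = False
    in_cosmic: bool = False
    is_kinase: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.symbol}: exon ({s},{e}) outside gene bounds")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"gene {self.symbol}: overlapping exons")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class GeneAnnotation:
    """Gene models indexed by symbol and by genomic interval."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.by_symbol: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.by_symbol[g.symbol] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end + 1, g)  # tree is half-open

    def __len__(self) -> int:
        return len(self.by_symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.by_symbol

    def get(self, symbol: str) -> GeneModel | None:
        return self.by_symbol.get(symbol)

    def __getitem__(self, symbol: str) -> GeneModel:
        try:
            return self.by_symbol[symbol]
        except KeyError:
            raise KeyError(f"unknown gene symbol {symbol!r}") from None

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda g: g.symbol)

    def genes(self) -> list[GeneModel]:
        return list(self.by_symbol.values())


# ---------------------------------------------------------------------------
# FusionCatcher-style dialect
# ---------------------------------------------------------------------------

#: canonical column -> accepted header aliases (column naming drifts across
#: FusionCatcher versions; extend via the ``aliases`` argument)
FUSIONCATCHER_ALIASES: Mapping[str, Sequence[str]] = {
    "gene5": ("Gene_1_symbol(5end_fusion_partner)", "gene_1_symbol", "gene5"),
    "gene3": ("Gene_2_symbol(3end_fusion_partner)", "gene_2_symbol", "gene3"),
    "junction5": ("Fusion_point_for_gene_1(5end_fusion_partner)",
                  "fusion_point_1", "junction5"),
    "junction3": ("Fusion_point_for_gene_2(3end_fusion_partner)",
                  "fusion_point_2", "junction3"),
    "spanning_pairs": ("Spanning_pairs",),
    "spanning_unique_reads": ("Spanning_unique_reads",),
    "longest_anchor": ("Longest_anchor_found", "longest_anchor"),
    "tags": ("Fusion_description", "description", "tags"),
    "common_mapping_reads": ("Counts_of_common_mapping_reads",
                             "common_mapping_reads"),
    "predicted_effect": ("Predicted_effect", "predicted_effect"),
}

_EFFECT_MAP = {
    "in-frame": "in-frame",
    "in_frame": "in-frame",
    "out-of-frame": "out-of-frame",
    "out_of_frame": "out-of-frame",
    "out-of-frame.": "out-of-frame",
    "stop-codon": "out-of-frame",
    "utr/intronic": "UTR/intronic",
    "utr": "UTR/intronic",
    "intronic": "UTR/intronic",
    "exonic(no-known-cds)": "UTR/intronic",
    ".": "unknown",
    "": "unknown",
    "unknown": "unknown",
}


def _resolve_columns(header: Sequence[str], aliases: Mapping[str, Sequence[str]],
                     required: Iterable[str]) -> dict[str, int]:
    lower = {h.strip().lower(): i for i, h in enumerate(header)}
    resolved = {}
    for canon, names in aliases.items():
        for name in names:
            idx = lower.get(name.lower())
            if idx is not None:
                resolved[canon] = idx
                break
    missing = [c for c in required if c not in resolved]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    return resolved


def _parse_coordinate(text: str, line: int) -> Junction:
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise RowError(f"unparseable coordinate {text!r}", line)
    chrom, pos_s, strand = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise RowError(f"unparseable coordinate {text!r}", line) from None
    try:
        return Junction(chrom, pos, strand)
    except ValueError as exc:
        raise RowError(str(exc), line) from None


def read_fusioncatcher_tsv(path, sample_id: str,
                           aliases: Mapping[str, Sequence[str]] | None = None
                           ) -> list[FusionCall]:
    """Parse a FusionCatcher-style TSV into :class:`FusionCall` records.

    The ``Fusion_description`` cell is split on commas into the tag set; tags
    are preserved verbatim (filtering decides what to do with them, parsing
    does not).
    """
    aliases = dict(FUSIONCATCHER_ALIASES, **(aliases or {}))
    required = ("gene5", "gene3", "junction5", "junction3", "spanning_pairs",
                "longest_anchor", "tags")
    calls = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = _resolve_columns(header, aliases, required)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields_ = raw.rstrip("\n").split("\t")

            def cell(canon, default=""):
                idx = cols.get(canon)
                if idx is None or idx >= len(fields_):
                    return default
                return fields_[idx]

            def int_cell(canon, default=0):
                text = cell(canon).strip()
                if not text or text == ".":
                    return default
                try:
                    return int(text)
                except ValueError:
                    raise RowError(
                        f"non-integer value {text!r} in column {canon}", lineno
                    ) from None

            tags = {t.strip() for t in cell("tags").split(",") if t.strip()}
            calls.append(FusionCall(
                sample_id=sample_id,
                gene5=cell("gene5").strip(),
                gene3=cell("gene3").strip(),
                junction5=_parse_coordinate(cell("junction5"), lineno),
                junction3=_parse_coordinate(cell("junction3"), lineno),
                spanning_pairs=int_cell("spanning_pairs"),
                spanning_unique_reads=int_cell("spanning_unique_reads"),
                longest_anchor=int_cell("longest_anchor"),
                tags=tags,
                common_mapping_reads=int_cell("common_mapping_reads"),
                predicted_effect=_EFFECT_MAP.get(
                    cell("predicted_effect").strip().lower(), "unknown"),
                confidence="none",
                caller="fusioncatcher-like",
            ))
    return calls


def write_fusioncatcher_tsv(calls: Iterable[FusionCall], path) -> None:
    cols = ["Gene_1_symbol(5end_fusion_partner)",
            "Gene_2_symbol(3end_fusion_partner)",
            "Fusion_point_for_gene_1(5end_fusion_partner)",
            "Fusion_point_for_gene_2(3end_fusion_partner)",
            "Spanning_pairs", "Spanning_unique_reads", "Longest_anchor_found",
            "Fusion_description", "Counts_of_common_mapping_reads",
            "Predicted_effect"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            j5, j3 = c.junction5, c.junction3
            fh.write("\t".join([
                c.gene5, c.gene3,
                f"{j5.chrom}:{j5.pos}:{j5.strand}",
                f"{j3.chrom}:{j3.pos}:{j3.strand}",
                str(c.spanning_pairs), str(c.spanning_unique_reads),
                str(c.longest_anchor), ",".join(sorted(c.tags)),
                str(c.common_mapping_reads), c.predicted_effect,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Arriba-style dialect
# ---------------------------------------------------------------------------

ARRIBA_ALIASES: Mapping[str, Sequence[str]] = {
    "gene1": ("#gene1", "gene1"),
    "gene2": ("gene2",),
    "strand1": ("strand1(gene/fusion)", "strand1"),
    "strand2": ("strand2(gene/fusion)", "strand2"),
    "breakpoint1": ("breakpoint1",),
    "breakpoint2": ("breakpoint2",),
    "confidence": ("confidence",),
    "discordant_mates": ("discordant_mates",),
    "split_reads": ("split_reads1", "split_reads"),
    "reading_frame": ("reading_frame",),
    "tags": ("tags", "filters"),
}

_FRAME_MAP = {
    "in-frame": "in-frame",
    "out-of-frame": "out-of-frame",
    "stop-codon": "out-of-frame",
    ".": "unknown",
    "": "unknown",
}


def _parse_arriba_breakpoint(text: str, strand_cell: str, line: int) -> Junction:
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise RowError(f"unparseable breakpoint {text!r}", line)
    chrom, pos_s = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise RowError(f"unparseable breakpoint {text!r}", line) from None
    # strand column is either "+" or "gene/fusion" e.g. "+/-"; the fusion
    # strand (second field) is the relevant orientation
    strand = strand_cell.strip().split("/")[-1]
    try:
        return Junction(chrom, pos, strand)
    except ValueError as exc:
        raise RowError(str(exc), line) from None


def read_arriba_tsv(path, sample_id: str,
                    aliases: Mapping[str, Sequence[str]] | None = None
                    ) -> list[FusionCall]:
    """Parse an Arriba-style TSV.

    Arriba's ``discordant_mates`` count is stored in ``spanning_pairs`` so
    that read-support filters apply uniformly across dialects; ``confidence``
    and ``reading_frame`` map onto the shared enums.
    """
    aliases = dict(ARRIBA_ALIASES, **(aliases or {}))
    required = ("gene1", "gene2", "breakpoint1", "breakpoint2", "confidence",
                "discordant_mates", "reading_frame")
    calls = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = _resolve_columns(header, aliases, required)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields_ = raw.rstrip("\n").split("\t")

            def cell(canon, default=""):
                idx = cols.get(canon)
                if idx is None or idx >= len(fields_):
                    return default
                return fields_[idx]

            conf = cell("confidence").strip().lower()
            if conf not in ("high", "medium", "low"):
                raise RowError(f"invalid confidence {conf!r}", lineno)
            try:
                mates = int(cell("discordant_mates") or 0)
                split = int(cell("split_reads") or 0)
            except ValueError:
                raise RowError("non-integer read count", lineno) from None
            tags = {t.strip() for t in cell("tags").split(",") if t.strip()}
            calls.append(FusionCall(
                sample_id=sample_id,
                gene5=cell("gene1").strip(),
                gene3=cell("gene2").strip(),
                junction5=_parse_arriba_breakpoint(
                    cell("breakpoint1"), cell("strand1", "+"), lineno),
                junction3=_parse_arriba_breakpoint(
                    cell("breakpoint2"), cell("strand2", "+"), lineno),
                spanning_pairs=mates,
                spanning_unique_reads=split,
                longest_anchor=0,
                tags=tags,
                predicted_effect=_FRAME_MAP.get(
                    cell("reading_frame").strip().lower(), "unknown"),
                confidence=conf,
                caller="arriba-like",
            ))
    return calls


def write_arriba_tsv(calls: Iterable[FusionCall], path) -> None:
    cols = ["#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
            "breakpoint1", "breakpoint2", "confidence", "discordant_mates",
            "split_reads1", "reading_frame", "tags"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            j5, j3 = c.junction5, c.junction3
            fh.write("\t".join([
                c.gene5, c.gene3,
                f"{j5.strand}/{j5.strand}", f"{j3.strand}/{j3.strand}",
                f"{j5.chrom}:{j5.pos}", f"{j3.chrom}:{j3.pos}",
                c.confidence if c.confidence != "none" else "low",
                str(c.spanning_pairs), str(c.spanning_unique_reads),
                c.predicted_effect if c.predicted_effect in
                ("in-frame", "out-of-frame") else ".",
                ",".join(sorted(c.tags)),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Gene models / annotation
# ---------------------------------------------------------------------------

def _gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(gtf_path,
                     mirna_hosts: Iterable[str] = (),
                     snorna_hosts: Iterable[str] = (),
                     cosmic: Iterable[str] = (),
                     kinases: Iterable[str] = ()) -> GeneAnnotation:
    """Load gene/exon/CDS features from a GTF and attach gene-list flags.

    Genes absent from the host/COSMIC/kinase lists get ``False`` flags.  A
    gene feature without exon children falls back (with a warning) to a single
    exon spanning the gene.
    """
    mirna_hosts = set(mirna_hosts)
    snorna_hosts = set(snorna_hosts)
    cosmic = set(cosmic)
    kinases = set(kinases)

    genes: dict[str, dict] = {}
    with open(gtf_path, encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"malformed GTF line: {raw[:60]!r}")
            chrom, _, feature, start, end, _, strand, _, attr_text = parts[:9]
            if feature not in ("gene", "exon", "CDS"):
                continue
            attrs = _gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise FormatError("GTF feature without gene_id attribute")
            rec = genes.setdefault(gene_id, {
                "gene_id": gene_id, "symbol": attrs.get("gene_name", gene_id),
                "chrom": chrom, "strand": strand, "start": None, "end": None,
                "biotype": attrs.get("gene_biotype", "protein_coding"),
                "exons": [], "cds": []})
            start, end = int(start), int(end)
            if feature == "gene":
                rec["start"], rec["end"] = start, end
                rec["strand"] = strand
                rec["symbol"] = attrs.get("gene_name", gene_id)
                rec["biotype"] = attrs.get("gene_biotype", rec["biotype"])
            elif feature == "exon":
                rec["exons"].append((start, end))
            else:
                rec["cds"].append((start, end))

    models = []
    for rec in genes.values():
        if rec["start"] is None:
            # no explicit gene feature: infer bounds from children
            spans = rec["exons"] + rec["cds"]
            rec["start"] = min(s for s, _ in spans)
            rec["end"] = max(e for _, e in spans)
        if not rec["exons"]:
            warnings.warn(
                f"gene {rec['symbol']} has no exons; using a single exon "
                "spanning the gene")
            rec["exons"] = [(rec["start"], rec["end"])]
        cds_start = min((s for s, _ in rec["cds"]), default=None)
        cds_end = max((e for _, e in rec["cds"]), default=None)
        symbol = rec["symbol"]
        models.append(GeneModel(
            gene_id=rec["gene_id"], symbol=symbol, chrom=rec["chrom"],
            start=rec["start"], end=rec["end"], strand=rec["strand"],
            biotype=rec["biotype"], exons=rec["exons"],
            cds_start=cds_start, cds_end=cds_end,
            is_mirna_host=symbol in mirna_hosts,
            is_snorna_host=symbol in snorna_hosts,
            in_cosmic=symbol in cosmic,
            is_kinase=symbol in kinases,
        ))
    return GeneAnnotation(models)


def read_bed_intervals(path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into 1-based interval trees.

    Returns chrom -> IntervalTree whose intervals are [start, end+1) in
    1-based coordinates with the BED name (or ``"."``) as data.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("track", "browser", "#")):
                continue
            parts = raw.rstrip("\n").split("\t")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            if end0 <= start0:
                continue
            tree = trees.setdefault(chrom, IntervalTree())
            tree.addi(start0 + 1, end0 + 1, name)  # 1-based inclusive span
    return trees


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------

def fetch_sequence(fasta, chrom: str, start: int, end: int,
                   strand: str = "+") -> str:
    """Fetch the 1-based inclusive interval; reverse-complement on minus.

    ``fasta`` is a path to an indexed FASTA or an open ``pysam.FastaFile``.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid interval {chrom}:{start}-{end}")
    own = False
    if not isinstance(fasta, pysam.FastaFile):
        fasta = pysam.FastaFile(str(fasta))
        own = True
    try:
        if chrom not in fasta.references:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        length = fasta.get_reference_length(chrom)
        if end > length:
            raise ValueError(
                f"interval {chrom}:{start}-{end} beyond chromosome length "
                f"{length}")
        seq = fasta.fetch(chrom, start - 1, end).upper()
    finally:
        if own:
            fasta.close()
    if strand == "-":
        seq = reverse_complement(seq)
    return seq


def read_expression_table(path) -> "pandas.DataFrame":
    """Read a per-gene FPKM table (first column gene symbol, one column per
    sample) into a gene-indexed DataFrame of floats."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return df.astype(float)


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                out.add(token.split("\t")[0])
    return out
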