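"""Tag- and read-evidence-based pre-filtering of caller output.

FusionCatcher annotates each prediction with descriptive tags; predictions
carrying tags associated with likely false positives (known read-through
events, paralog pairs, fusions seen in healthy tissue, ...) are removed
before any DNA-level validation or classification, as are calls whose
partner genes share multi-mapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import FusionCall

#: Tags marking likely false positive predictions; removed by default.
DEFAULT_BANNED_TAGS = frozenset({
    "1000genomes", "1k<gap<10k", "adjacent", "ambiguous", "duplicates",
    "ensembl_partially_overlapping", "gap<1k", "gencode_fully_overlapping",
    "gencode_partially_overlapping", "gencode_same_strand_overlapping",
    "healthy", "m0", "multi", "non_cancer_tissues", "non_tumor_cells",
    "refseq_partially_overlapping", "tcga-normal", "ucsc_partially_overlapping",
    "banned", "bodymap2", "cacg", "conjoing", "cta_gene", "ctb_gene",
    "ctc_gene", "ctd_gene", "distance1000bp", "ensembl_fully_overlapping",
    "ensembl_same_strand_overlapping", "gtex", "hpa", "mt",
    "pair_pseudo_genes", "paralogs", "readthrough", "refseq_fully_overlapping",
    "refseq_same_strand_overlapping", "rp_gene", "rp11_gene", "rrna",
    "similar_reads", "similar_symbols", "ucsc_fully_overlapping",
    "ucsc_same_strand_overlapping",
})


@dataclass
class BannedTagSet:
    """Case-insensitive set of banned tags; matching is exact-string after
    lowercasing (never substring, so "mt" does not catch "mt-like")."""

    tags: frozenset = field(default_factory=lambda: DEFAULT_BANNED_TAGS)

    def __post_init__(self):
        self.tags = frozenset(t.lower() for t in self.tags)

    def __contains__(self, tag: str) -> bool:
        return tag.lower() in self.tags

    def first_match(self, tags: Iterable[str]) -> str | None:
        """First banned tag among ``tags`` in sorted order (deterministic)."""
        hits = sorted(t for t in tags if t in self)
        return hits[0] if hits else None


@dataclass
class RemovedCall:
    call: FusionCall
    reason: str


def apply_prefilter(calls: Sequence[FusionCall],
                    banned_tags: BannedTagSet | Iterable[str] | None = None,
                    max_common_mapping: int = 0,
                    ) -> tuple[list[FusionCall], list[RemovedCall]]:
    """Partition calls into (kept, removed-with-reason).

    A call is removed iff it carries at least one banned tag or its
    ``common_mapping_reads`` exceeds ``max_common_mapping``.  The banned-tag
    reason takes precedence when both apply.  Idempotent: re-filtering the
    kept set removes nothing.
    """
    if banned_tags is None:
        banned_tags = BannedTagSet()
    elif not isinstance(banned_tags, BannedTagSet):
        banned_tags = BannedTagSet(frozenset(banned_tags))

    kept: list[FusionCall] = []
    removed: list[RemovedCall] = []
    for call in calls:
        hit = banned_tags.first_match(call.tags)
        if hit is not None:
            removed.append(RemovedCall(call, f"banned tag: {hit}"))
        elif call.common_mapping_reads > max_common_mapping:
            removed.append(RemovedCall(
                call,
                f"common mapping reads: {call.common_mapping_reads} > "
                f"{max_common_mapping}"))
        else:
            kept.append(call)
    return kept, removed


def fusion_set_jaccard(calls_a: Sequence[FusionCall],
                       calls_b: Sequence[FusionCall],
                       ordered: bool = False) -> float:
    """Intersection-over-union of the partner-pair sets of two call lists.

    Keyed by the unordered partner-symbol pair by default so reciprocal calls
    (A-B vs B-A) match; ``ordered=True`` keys by the (5', 3') tuple.  Returns
    0.0 when both sets are empty (by convention).
    """
    if ordered:
        keys_a = {(c.gene5, c.gene3) for c in calls_a}
        keys_b = {(c.gene5, c.gene3) for c in calls_b}
    else:
        keys_a = {c.partner_key for c in calls_a}
        keys_b = {c.partner_key for c in calls_b}
    union = keys_a | keys_b
    if not union:
        return 0.0
    return len(keys_a & keys_b) / len(union)
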