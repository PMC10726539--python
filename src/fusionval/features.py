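"""RNA-only feature construction for fusion classification.

Three feature categories mirror what is knowable without WGS: chimeric mRNA
evidence (read support, anchor length, predicted effect, remaining caller
tags), expression of the two partners (FPKM and their log-ratio), and
general genomic annotation (spatial relationship, COSMIC status, host-gene
flags, repeat overlap, gene structure).  Validation status supplies the
label downstream; nothing here reads the WGS data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import FusionCall, GeneAnnotation

logger = logging.getLogger(__name__)

#: caller tags marking presence in fusion databases (not banned; predictive)
KNOWN_DB_TAGS = frozenset({
    "known", "cgp", "ticdb", "chimerdb2", "chimerdb3kb", "cosmic",
    "oncogene", "tumor", "18cancers", "prostates", "tcga", "cell_lines",
})

META_COLUMNS = ("label", "group", "sample_id")


@dataclass
class FeatureConfig:
    expression_epsilon: float = 0.01   # pseudo-count in the log FPKM ratio
    repeat_window: int = 10            # bp around the junction for repeat overlap
    known_db_tags: frozenset = KNOWN_DB_TAGS


def _fpkm(expression, gene: str, sample_id: str) -> float:
    """FPKM for a gene; explicit NaN when the gene or sample is absent."""
    if expression is None:
        return float("nan")
    if isinstance(expression, pd.DataFrame):
        if gene not in expression.index:
            return float("nan")
        row = expression.loc[gene]
        if sample_id in expression.columns:
            return float(row[sample_id])
        return float(row.mean())
    return float(expression.get(gene, float("nan")))


def _repeat_overlap(repeats, chrom: str, pos: int, window: int) -> bool:
    if not repeats:
        return False
    tree = repeats.get(chrom)
    if tree is None:
        return False
    return bool(tree.overlap(pos - window, pos + window + 1))


def build_feature_vector(call: FusionCall,
                         annotation: GeneAnnotation | None,
                         expression=None,
                         repeats: Mapping | None = None,
                         config: FeatureConfig | None = None) -> dict:
    """One feature dict for a prefiltered call; deterministic given inputs.

    Missing expression is an explicit NaN (never silently zero);
    ``genomic_distance`` is present only for intrachromosomal pairs.  When a
    partner is absent from the annotation the row is flagged incomplete and
    its genomic fields stay missing.
    """
    config = config or FeatureConfig()
    eps = config.expression_epsilon
    fpkm5 = _fpkm(expression, call.gene5, call.sample_id)
    fpkm3 = _fpkm(expression, call.gene3, call.sample_id)
    j5, j3 = call.junction5, call.junction3
    same_chrom = j5.chrom == j3.chrom

    vec: dict = {
        "spanning_pairs": call.spanning_pairs,
        "spanning_unique_reads": call.spanning_unique_reads,
        "longest_anchor": call.longest_anchor,
        "predicted_effect": call.predicted_effect,
        "n_remaining_tags": len(call.tags),
        "tags": frozenset(call.tags),
        "known_db_flag": bool(call.tags & config.known_db_tags),
        "fpkm5": fpkm5,
        "fpkm3": fpkm3,
        "log_expr_ratio": math.log2((fpkm5 + eps) / (fpkm3 + eps))
        if not (math.isnan(fpkm5) or math.isnan(fpkm3)) else float("nan"),
        "same_chromosome": same_chrom,
        "genomic_distance": float(abs(j5.pos - j3.pos)) if same_chrom
        else float("nan"),
        "strand_combination": f"{j5.strand}/{j3.strand}",
        "repeat_overlap5": _repeat_overlap(repeats, j5.chrom, j5.pos,
                                           config.repeat_window),
        "repeat_overlap3": _repeat_overlap(repeats, j3.chrom, j3.pos,
                                           config.repeat_window),
        "incomplete": False,
    }
    if call.caller == "arriba-like":
        vec["confidence"] = call.confidence

    for side, symbol in (("5", call.gene5), ("3", call.gene3)):
        gene = annotation.get(symbol) if annotation is not None else None
        if gene is None:
            vec["incomplete"] = True
            vec[f"gene_length{side}"] = float("nan")
            vec[f"n_exons{side}"] = float("nan")
            for flag in ("in_cosmic", "is_mirna_host", "is_snorna_host"):
                vec[f"{flag}{side}"] = float("nan")
            continue
        vec[f"gene_length{side}"] = float(gene.length)
        vec[f"n_exons{side}"] = float(gene.n_exons)
        vec[f"in_cosmic{side}"] = gene.in_cosmic
        vec[f"is_mirna_host{side}"] = gene.is_mirna_host
        vec[f"is_snorna_host{side}"] = gene.is_snorna_host
    return vec


def assemble_feature_table(vectors: Sequence[dict],
                           labels: Sequence[bool],
                           groups: Sequence[str],
                           sample_ids: Sequence[str] | None = None
                           ) -> pd.DataFrame:
    """Feature table from per-call vectors plus labels and CV groups.

    Tag-set columns are expanded to one 0/1 indicator per observed tag;
    zero-variance feature columns are dropped (their names are logged and
    kept in ``df.attrs['dropped_columns']``).  Row order is preserved.
    """
    vectors = list(vectors)
    if not (len(vectors) == len(labels) == len(groups)):
        raise ValueError("vectors, labels and groups must have equal length")
    if sample_ids is not None and len(sample_ids) != len(vectors):
        raise ValueError("sample_ids length mismatch")
    if any(not str(g) for g in groups):
        raise ValueError("groups must be non-empty strings")

    df = pd.DataFrame(vectors)
    # expand multi-categorical tag sets into per-tag indicators
    if "tags" in df.columns:
        observed = sorted({t for tags in df["tags"] for t in tags})
        for tag in observed:
            df[f"tag_{tag}"] = df["tags"].map(lambda s, t=tag: int(t in s))
        df = df.drop(columns=["tags"])

    for col in df.columns:
        if df[col].dtype == object and not df[col].map(
                lambda v: isinstance(v, (str, float, int, bool))).all():
            raise ValueError(f"unsupported values in column {col!r}")
        if df[col].dtype == object:
            df[col] = df[col].astype("category")

    dropped = [c for c in df.columns
               if df[c].nunique(dropna=False) <= 1]
    if dropped:
        logger.info("dropping zero-variance columns: %s", ", ".join(dropped))
        df = df.drop(columns=dropped)

    df["label"] = np.asarray(labels, dtype=bool)
    df["group"] = list(map(str, groups))
    if sample_ids is not None:
        df["sample_id"] = list(map(str, sample_ids))
    df.attrs["dropped_columns"] = dropped
    return df


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Feature columns of a table (metadata columns removed), with
    categorical/bool columns coerced to model-ready dtypes."""
    X = table.drop(columns=[c for c in META_COLUMNS if c in table.columns])
    X = X.copy()
    for col in X.columns:
        if X[col].dtype == object:
            X[col] = X[col].astype("category")
        elif X[col].dtype == bool:
            X[col] = X[col].astype(int)
    return X


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in df.columns:
        if df[col].dtype == object and col not in META_COLUMNS:
            df[col] = df[col].astype("category")
    if "label" in df.columns:
        df["label"] = df["label"].astype(bool)
    return df
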