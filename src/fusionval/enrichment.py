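"""Binomial gene-set over-representation for fusion partner genes.

The same gene can take part in multiple fusion events, so the partner list
is a sample *with replacement* from the expressed-gene universe; the test
is therefore the upper binomial tail P(X >= k), X ~ Binomial(n, p_set),
rather than the hypergeometric tail a without-replacement design would use.
Benjamini-Hochberg correction is applied across gene sets within each
analysis stratum (cancer type x partner side in the intended workflow).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def define_universe(expression: pd.DataFrame, percentile: float = 95.0,
                    min_fpkm: float = 1.0) -> set[str]:
    """Expressed-gene universe: per-gene ``percentile``-th FPKM across
    samples >= ``min_fpkm`` (linear-interpolation percentile)."""
    if expression.shape[0] == 0 or expression.shape[1] == 0:
        raise ValueError("expression table is empty")
    values = expression.to_numpy(dtype=float)
    cut = np.percentile(values, percentile, axis=1)
    return set(expression.index[cut >= min_fpkm])


def binomial_enrichment(gene_list: Sequence[str],
                        gene_sets: Mapping[str, Iterable[str]],
                        universe: set[str]) -> pd.DataFrame:
    """Upper-tail binomial over-representation of each gene set.

    ``gene_list`` carries multiplicity (one entry per fusion partner slot);
    entries outside the universe are dropped with a log message.  For each
    set: p_set = |set ∩ universe| / |universe|, k = list hits counting
    multiplicity, p = P(X >= k) with X ~ Binomial(n, p_set), and q = BH
    across the supplied sets.
    """
    if not universe:
        raise ValueError("universe is empty")
    in_universe = [g for g in gene_list if g in universe]
    dropped = len(gene_list) - len(in_universe)
    if dropped:
        logger.info("dropped %d gene-list entries outside the universe",
                    dropped)
    if not in_universe:
        raise ValueError("gene list is empty after universe filtering")
    n = len(in_universe)

    rows = []
    for name, members in gene_sets.items():
        members_in = set(members) & universe
        p_set = len(members_in) / len(universe)
        k = sum(g in members_in for g in in_universe)
        # upper-tail binomial mass P(X >= k); sf(k-1) == 1 - cdf(k-1)
        p_value = float(stats.binom.sf(k - 1, n, p_set)) if k > 0 else 1.0
        rows.append({"set": name, "k": k, "n": n, "p_set": p_set,
                     "p_value": min(1.0, p_value)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def enrichment_by_stratum(gene_lists: Mapping[str, Sequence[str]],
                          gene_sets: Mapping[str, Iterable[str]],
                          universe: set[str]) -> pd.DataFrame:
    """Run the binomial test per stratum (e.g. cancer type x partner side);
    BH correction is applied within each stratum."""
    frames = []
    for stratum, gene_list in gene_lists.items():
        df = binomial_enrichment(gene_list, gene_sets, universe)
        df.insert(0, "stratum", stratum)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
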