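"""Hypergeometric over-representation of terms in a gene set.

For each term with at least one gene in the query set, the p-value is the
upper tail P[X >= k] of Hypergeometric(N, K, n) — N background genes, K of
them carrying the term, n in the query set, k carrying the term in the set.
BH correction runs across the tested terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HomeotripError
from .de import bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    gene_set,
    term_map: pd.DataFrame,
    background,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of every term hit by the gene set.

    Parameters
    ----------
    gene_set
        Query genes; must be a subset of ``background``.
    term_map
        DataFrame with columns ``gene`` and ``term`` (one row per
        assignment; genes may carry several terms).
    background
        The gene universe (e.g. all genes in the count matrix).

    Returns a DataFrame indexed by term with k, K, n, N, p and BH q, sorted
    by q then p then term id.
    """
    background = set(background)
    gene_set = set(gene_set)
    if not gene_set or not background:
        raise HomeotripError("gene set and background must be non-empty")
    if not gene_set <= background:
        raise HomeotripError("gene set must be a subset of the background")
    tm = term_map[term_map["gene"].isin(background)]
    uncovered = background - set(tm["gene"])
    if uncovered:
        logger.info("%d background gene(s) carry no term", len(uncovered))
    n_universe = len(background)
    n_set = len(gene_set)
    rows = []
    for term, sub in tm.groupby("term"):
        genes_with_term = set(sub["gene"])
        k = len(genes_with_term & gene_set)
        if k == 0:
            continue
        big_k = len(genes_with_term)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_set))
        rows.append({"term": term, "k": k, "K": big_k, "n": n_set, "N": n_universe, "pvalue": p})
    if not rows:
        return pd.DataFrame(columns=["k", "K", "n", "N", "pvalue", "qvalue"])
    out = pd.DataFrame(rows).set_index("term")
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_index().sort_values(["qvalue", "pvalue"], kind="stable")
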