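"""Cold-inducibility of homeolog triplets: Types 1-3, ranks and divergence.

A gene is *cold-induced* when it is significantly up-regulated under cold
stress (log2FC > 1 and p < 0.01, strictly; down-regulation never counts).
A triplet with three / two / one induced copies is a Type 1 / 2 / 3 triplet;
triplets with no induced copy are untyped.  Within each Type 1 triplet the
copies are ranked by *inducibility* — the FPKM fold change cold vs control
(with a small pseudo-count guarding zero control means) — and the triplet is
flagged *divergent* when the rank-1 copy's inducibility is at least twice
the rank-3 copy's.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, TripletMap

logger = logging.getLogger(__name__)

INDUCIBILITY_PSEUDO = 0.1  # FPKM added to both means before the ratio
DIVERGENCE_RATIO = 2.0  # "two-fold or greater" spread, boundary inclusive

_TYPE_BY_COUNT = {3: "type1", 2: "type2", 1: "type3", 0: "none"}


def cold_induced_set(de_results: pd.DataFrame) -> set[str]:
    """Genes called 'up' (strictly log2FC > 1 and p < 0.01)."""
    if len(de_results) == 0 or "call" not in de_results.columns:
        return set()
    return set(de_results.index[de_results["call"] == "up"])


def classify_type(members: tuple[str, str, str], induced: set[str]) -> str:
    """Map the number of induced copies (3/2/1/0) to type1/type2/type3/none."""
    return _TYPE_BY_COUNT[sum(g in induced for g in members)]


def rank_inducibility(
    cold_means: pd.Series,
    control_means: pd.Series,
    pseudo: float = INDUCIBILITY_PSEUDO,
) -> tuple[pd.Series, str]:
    """Rank three copies by inducibility and flag divergence.

    Inducibility = (cold mean + pseudo) / (control mean + pseudo).  Ranks
    are descending with lexicographic gene-id tie-break; the flag is
    ``divergent`` iff rank-1 / rank-3 inducibility >= 2.
    """
    genes = sorted(cold_means.index)
    ind = (cold_means.loc[genes] + pseudo) / (control_means.loc[genes] + pseudo)
    ind = ind.to_frame("inducibility").sort_values("inducibility", ascending=False, kind="stable")["inducibility"]
    flag = "divergent" if ind.iloc[0] / ind.iloc[2] >= DIVERGENCE_RATIO else "similar"
    return ind, flag


def cold_response_table(
    triplets: TripletMap,
    counts: CountMatrix,
    fpkm: ExpressionMatrix,
    de_results: pd.DataFrame,
    pseudo: float = INDUCIBILITY_PSEUDO,
) -> pd.DataFrame:
    """Per-triplet type, per-copy inducibility, ranks and divergence flag.

    The divergence flag is ``n/a`` for anything but Type 1 triplets.
    """
    induced = cold_induced_set(de_results)
    ctrl = fpkm.condition_means(counts.samples, "control")
    coldm = fpkm.condition_means(counts.samples, "cold")
    rows = []
    for anchor in triplets.anchors:
        genes = triplets.members(anchor)
        ttype = classify_type(genes, induced)
        ranked, flag = rank_inducibility(coldm.loc[list(genes)], ctrl.loc[list(genes)], pseudo)
        if ttype != "type1":
            flag = "n/a"
        rows.append(
            {
                "anchor": anchor,
                "type": ttype,
                "n_induced": sum(g in induced for g in genes),
                "rank1": ranked.index[0],
                "rank2": ranked.index[1],
                "rank3": ranked.index[2],
                "inducibility_rank1": ranked.iloc[0],
                "inducibility_rank2": ranked.iloc[1],
                "inducibility_rank3": ranked.iloc[2],
                "divergence": flag,
            }
        )
    return pd.DataFrame(rows).set_index("anchor")


def summarize_types(types: pd.DataFrame) -> dict:
    """Counts of Types 1-3, percent diverged (Type 2 or 3) and percent divergent Type 1."""
    from .report import percentage

    typed = types[types["type"].isin(("type1", "type2", "type3"))]
    n_typed = len(typed)
    if n_typed == 0:
        logger.warning("no triplet has an induced copy; type summary is empty")
        return {"n_typed": 0, "type_counts": {}, "percent_type2_or_3": None, "percent_type1_divergent": None}
    counts = {t: int((typed["type"] == t).sum()) for t in ("type1", "type2", "type3")}
    n_t1 = counts["type1"]
    n_div = int((typed["divergence"] == "divergent").sum())
    return {
        "n_typed": n_typed,
        "type_counts": counts,
        "percent_type2_or_3": percentage(n_typed - n_t1, n_typed, 0),
        "percent_type1_divergent": percentage(n_div, n_t1, 1) if n_t1 else 0.0,
        "n_type1_divergent": n_div,
    }
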