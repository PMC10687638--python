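"""Control-condition divergence of homeolog triplets: presence and Classes 1-3.

A retained triplet is summarized under control conditions by (i) how many of
its three copies are expressed at all (presence category 3/2/1/0) and (ii)
a dominance class:

* Class 1 — the top-expressed copy is significantly higher (p < 0.01 and
  FPKM fold change > 2) than *both* other copies;
* Class 2 — the two top copies are each significantly higher (same rule)
  than the third, without the top copy dominating the middle one;
* Class 3 — all three copies are within 1.5-fold of each other;
* otherwise the triplet is unclassified (a legal, reported outcome).

Because the significance test compares counts of two *different* genes
across the same samples, gene length must be removed first: counts are
rescaled to per-kilobase pseudo-counts before the NB exact test, while fold
changes are computed on mean FPKM (orientation >= 1).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, HomeotripError, TripletMap, geometric_mean
from .de import DispersionModel, nb_exact_test, quantile_adjust

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.01
DOMINANCE_FC = 2.0
SIMILAR_FC = 1.5


def presence_category(means, expressed_threshold: float = 0.0) -> int:
    """Number of copies whose mean control FPKM exceeds the threshold (strict)."""
    m = np.asarray(means, dtype=float)
    return int((m > expressed_threshold).sum())


def _fold_change(a: float, b: float) -> float:
    """Mean-FPKM fold change, oriented >= 1; both zero -> 1, one zero -> inf."""
    hi, lo = max(a, b), min(a, b)
    if hi == 0:
        return 1.0
    if lo == 0:
        return float("inf")
    return hi / lo


def pairwise_homeolog_tests(
    genes: tuple[str, str, str],
    counts: CountMatrix,
    lengths: pd.Series,
    model: DispersionModel,
    fpkm: ExpressionMatrix,
) -> dict[frozenset, tuple[float, float]]:
    """Exact-test and fold-change for each unordered pair of copies.

    Control samples only.  Returns ``{frozenset({a, b}): (p, fc)}`` where p
    comes from the NB exact test on per-kilobase pseudo-counts and fc is the
    ratio of mean control FPKMs (>= 1).
    """
    ctrl = counts.samples_for("control")
    if not ctrl:
        raise HomeotripError("no control samples")
    sub = counts.counts.loc[list(genes), ctrl]
    per_kb = np.round(sub.to_numpy(dtype=float) * 1000.0 / lengths.loc[list(genes)].to_numpy()[:, None])
    per_kb = pd.DataFrame(per_kb, index=list(genes), columns=ctrl)
    depths = model.effective_lib_sizes.loc[ctrl]
    pseudo = np.round(quantile_adjust(per_kb, depths, model.dispersion, geometric_mean(depths)).to_numpy())
    means = fpkm.condition_means(counts.samples, "control").loc[list(genes)]
    out: dict[frozenset, tuple[float, float]] = {}
    for i, j in itertools.combinations(range(3), 2):
        gi, gj = genes[i], genes[j]
        if pseudo[i].sum() + pseudo[j].sum() == 0:
            p = 1.0
        else:
            p = nb_exact_test(pseudo[i], pseudo[j], model.dispersion)
        out[frozenset((gi, gj))] = (p, _fold_change(means[gi], means[gj]))
    return out


def classify_triplet(
    ordered_means: pd.Series,
    pairwise: dict[frozenset, tuple[float, float]],
    p_threshold: float = P_THRESHOLD,
    dominance_fc: float = DOMINANCE_FC,
    similar_fc: float = SIMILAR_FC,
) -> str:
    """Apply the Class 1/2/3 rules to one triplet.

    ``ordered_means`` must be sorted descending by mean control FPKM (ties
    broken lexicographically by gene id for determinism).
    """
    top, mid, low = ordered_means.index
    p_tm, fc_tm = pairwise[frozenset((top, mid))]
    p_tl, fc_tl = pairwise[frozenset((top, low))]
    p_ml, fc_ml = pairwise[frozenset((mid, low))]
    if p_tm < p_threshold and fc_tm > dominance_fc and p_tl < p_threshold and fc_tl > dominance_fc:
        return "class1"
    if p_tl < p_threshold and fc_tl > dominance_fc and p_ml < p_threshold and fc_ml > dominance_fc:
        return "class2"
    if fc_tm < similar_fc and fc_tl < similar_fc and fc_ml < similar_fc:
        return "class3"
    return "unclassified"


def order_copies(means: pd.Series) -> pd.Series:
    """Sort copy means descending with lexicographic gene-id tie-break."""
    # stable sort on a pre-sorted-by-id frame gives the lexicographic tie-break
    df = means.loc[sorted(means.index)].to_frame("mean").sort_values("mean", ascending=False, kind="stable")
    return df["mean"]


def classify_triplets(
    counts: CountMatrix,
    triplets: TripletMap,
    lengths: pd.Series,
    model: DispersionModel,
    fpkm: ExpressionMatrix,
    expressed_threshold: float = 0.0,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Presence category and dominance class for every triplet.

    Returns one row per anchor with copies, mean control FPKMs, the three
    pairwise p-values/fold changes (in top-mid, top-low, mid-low order),
    presence category and class.
    """
    triplets.check_against(counts)
    ctrl_means = fpkm.condition_means(counts.samples, "control")
    rows = []
    for anchor in triplets.anchors:
        genes = triplets.members(anchor)
        ordered = order_copies(ctrl_means.loc[list(genes)])
        pres = presence_category(ordered, expressed_threshold)
        pairwise = pairwise_homeolog_tests(genes, counts, lengths, model, fpkm)
        cls = classify_triplet(ordered, pairwise, p_threshold=p_threshold)
        top, mid, low = ordered.index
        rows.append(
            {
                "anchor": anchor,
                "top": top,
                "mid": mid,
                "low": low,
                "mean_top": ordered.iloc[0],
                "mean_mid": ordered.iloc[1],
                "mean_low": ordered.iloc[2],
                "p_top_mid": pairwise[frozenset((top, mid))][0],
                "p_top_low": pairwise[frozenset((top, low))][0],
                "p_mid_low": pairwise[frozenset((mid, low))][0],
                "fc_top_mid": pairwise[frozenset((top, mid))][1],
                "fc_top_low": pairwise[frozenset((top, low))][1],
                "fc_mid_low": pairwise[frozenset((mid, low))][1],
                "presence": pres,
                "class": cls,
            }
        )
    return pd.DataFrame(rows).set_index("anchor")


def summarize_presence(classes: pd.DataFrame) -> dict:
    """Counts and percentages of presence categories and classes."""
    from .report import percentage

    n = len(classes)
    presence_counts = {k: int((classes["presence"] == k).sum()) for k in (3, 2, 1, 0)}
    class_counts = classes["class"].value_counts().to_dict()
    out = {
        "n_triplets": n,
        "presence_counts": presence_counts,
        "presence_percent": {k: (percentage(v, n, 1) if n else 0.0) for k, v in presence_counts.items()},
        "class_counts": {k: int(class_counts.get(k, 0)) for k in ("class1", "class2", "class3", "unclassified")},
    }
    return out
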