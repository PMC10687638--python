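"""Thresholded Pearson coexpression network and Leiden modules.

Genes passing a TPM filter are ranked by variance of their log2(TPM + 1)
profile; the top fraction enters the network.  Edges connect gene pairs with
Pearson r strictly above the threshold (signed — anti-correlation never makes
an edge).  Modules are Leiden communities under the modularity objective at a
fixed resolution and seed; isolated filtered genes become singleton modules.
"""

from __future__ import annotations

import logging

import igraph
import leidenalg
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, HomeotripError

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.7
TOP_FRACTION = 0.2
MIN_TPM = 1.0


def filter_variable_genes(
    expr: ExpressionMatrix, min_tpm: float = MIN_TPM, top_fraction: float = TOP_FRACTION
) -> list[str]:
    """Top-variance genes among those with max TPM above ``min_tpm``.

    Variance is computed on log2(TPM + 1); the kept count is
    ``ceil(top_fraction * n_passing)``.  Zero-variance genes are never
    selected while any positive-variance gene remains.
    """
    vals = expr.values
    passing = vals.index[vals.max(axis=1) > min_tpm]
    if len(passing) == 0:
        raise HomeotripError("no gene exceeds the TPM filter; lower min_tpm")
    logvals = np.log2(vals.loc[passing] + 1.0)
    var = logvals.var(axis=1, ddof=1)
    k = int(np.ceil(top_fraction * len(passing)))
    order = var.loc[sorted(var.index)].sort_values(ascending=False, kind="stable")
    chosen = [g for g in order.index[:k] if order[g] > 0]
    dropped = k - len(chosen)
    if dropped:
        extra = [g for g in order.index[k:] if order[g] > 0][:dropped]
        chosen.extend(extra)
    if not chosen:
        raise HomeotripError("all filtered genes have zero variance")
    return chosen


def correlation_edges(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    r_threshold: float = R_THRESHOLD,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pearson edges (r strictly above threshold) on log2(TPM + 1) profiles."""
    vals = expr.values if genes is None else expr.values.loc[genes]
    if vals.shape[1] < 3:
        raise HomeotripError("need at least 3 observations per gene for correlations")
    x = np.log2(vals.to_numpy(dtype=float) + 1.0) if log_transform else vals.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("%d zero-variance gene(s) excluded from the network", int((~keep).sum()))
    ids = np.asarray(vals.index)[keep]
    r = np.corrcoef(x[keep])
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = r[iu, ju] > r_threshold
    return pd.DataFrame({"geneA": ids[iu[mask]], "geneB": ids[ju[mask]], "r": r[iu, ju][mask]})


def detect_modules(
    edges: pd.DataFrame,
    nodes: list[str] | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Leiden communities (modularity objective) with deterministic seed.

    Returns a gene -> module-id Series; module ids are 0-based and ordered
    by decreasing module size (ties by smallest member id).  ``nodes`` may
    list genes without edges, which become singleton modules.
    """
    edge_nodes = pd.unique(pd.concat([edges["geneA"], edges["geneB"]], ignore_index=True)) if len(edges) else []
    all_nodes = sorted(set(edge_nodes) | set(nodes or []))
    if not all_nodes:
        raise HomeotripError("empty graph")
    index = {g: i for i, g in enumerate(all_nodes)}
    g = igraph.Graph(
        n=len(all_nodes),
        edges=[(index[a], index[b]) for a, b in zip(edges["geneA"], edges["geneB"])],
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        weights=None,
    )
    membership = np.asarray(part.membership)
    # renumber by decreasing size, ties by smallest member id for determinism
    sizes = pd.Series(membership).value_counts()
    first_member = {}
    for gid, m in zip(all_nodes, membership):
        first_member.setdefault(m, gid)
    order = sorted(sizes.index, key=lambda m: (-sizes[m], first_member[m]))
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[m] for m in membership], index=all_nodes, name="module")


def module_de_summary(modules: pd.Series, de_results: pd.DataFrame) -> pd.DataFrame:
    """Per-module size and number of up/down-called genes."""
    rows = []
    if len(modules) == 0:
        return pd.DataFrame(columns=["size", "n_up", "n_down"]).rename_axis("module")
    calls = de_results["call"] if "call" in de_results.columns else pd.Series(dtype=object)
    for mod in sorted(modules.unique()):
        genes = modules.index[modules == mod]
        known = [g for g in genes if g in calls.index]
        if len(known) < len(genes):
            logger.info("module %s: %d gene(s) missing from the DE table", mod, len(genes) - len(known))
        sub = calls.loc[known]
        rows.append(
            {
                "module": mod,
                "size": len(genes),
                "n_up": int((sub == "up").sum()),
                "n_down": int((sub == "down").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("module")
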