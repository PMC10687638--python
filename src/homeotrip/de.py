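"""Two-group negative-binomial exact test with common dispersion.

The model is the classical two-group RNA-seq setup: counts for gene g in
sample s are NB with mean mu_gs = p_g * D_s and variance mu + phi * mu**2,
where p_g is the gene's relative abundance, D_s the sample's effective
sequencing depth and phi a single dispersion shared by all genes.  phi = 0
degenerates to Poisson.

Testing proceeds in three steps:

1. *Library equalization*: each sample's counts are mapped to pseudo-counts
   at the geometric-mean depth via the NB quantile function (mid-P CDF in,
   quantile out), so both groups live at a common library size.
2. *Common dispersion* is estimated by maximizing the conditional
   log-likelihood given per-group totals (which is free of the abundance
   nuisance parameters), with the search bounded to [0, 10].
3. *Exact test*: conditional on the total T of both groups, the probability
   of every split is computed under per-group NB sums, and the two-sided
   p-value is the total conditional probability of all splits at most as
   probable as the observed one (minimum-likelihood method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import CountMatrix, HomeotripError, geometric_mean
from .quantify import effective_depths

logger = logging.getLogger(__name__)

DISPERSION_BOUNDS = (0.0, 10.0)
_TIE_REL_TOL = 1e-12


@dataclass
class DispersionModel:
    """Common NB dispersion plus the per-sample modelled depths it was fit at."""

    dispersion: float
    effective_lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise HomeotripError("dispersion must be >= 0")
        if (self.effective_lib_sizes <= 0).any():
            raise HomeotripError("effective library sizes must be positive")


# ---------------------------------------------------------------------------
# library equalization


def quantile_adjust(
    counts: pd.DataFrame, depths: pd.Series, dispersion: float, target_depth: float | None = None
) -> pd.DataFrame:
    """Map each sample's counts to pseudo-counts at a common depth.

    Uses the mid-P CDF of the count under NB(p_g * D_s, phi) followed by the
    NB quantile function at NB(p_g * D_target, phi).  Genes with zero total
    stay zero.  Output is a float matrix; round before exact testing.
    """
    depths = depths.loc[counts.columns].astype(float)
    if target_depth is None:
        target_depth = geometric_mean(depths)
    y = counts.to_numpy(dtype=float)
    p_g = y.sum(axis=1) / depths.sum()
    mu_in = p_g[:, None] * depths.to_numpy()[None, :]
    mu_out = p_g * target_depth
    pseudo = np.zeros_like(y)
    pos = p_g > 0
    if not pos.any():
        return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns)
    yi = y[pos]
    mi = mu_in[pos]
    mo = np.broadcast_to(mu_out[pos][:, None], mi.shape)
    if dispersion <= 0:
        cdf = stats.poisson.cdf(yi, mi)
        pmf = stats.poisson.pmf(yi, mi)
        u = np.clip(cdf - 0.5 * pmf, 1e-300, 1 - 1e-12)
        pseudo[pos] = stats.poisson.ppf(u, mo)
    else:
        r = 1.0 / dispersion
        p_in = r / (r + mi)
        p_out = r / (r + mo)
        cdf = stats.nbinom.cdf(yi, r, p_in)
        pmf = stats.nbinom.pmf(yi, r, p_in)
        u = np.clip(cdf - 0.5 * pmf, 1e-300, 1 - 1e-12)
        pseudo[pos] = stats.nbinom.ppf(u, r, p_out)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# common dispersion


def _conditional_loglik(pseudo_by_group: list[np.ndarray], phi: float) -> float:
    """Summed NB conditional log-likelihood over genes and groups at equal libraries."""
    phi = max(phi, 1e-10)
    r = 1.0 / phi
    total = 0.0
    for y in pseudo_by_group:
        n = y.shape[1]
        z = y.sum(axis=1)
        ll = (
            special.gammaln(y + r).sum(axis=1)
            + special.gammaln(n * r)
            - special.gammaln(z + n * r)
            - n * special.gammaln(r)
        )
        total += float(ll.sum())
    return total


def estimate_common_dispersion(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    n_iter: int = 2,
    init_dispersion: float = 0.1,
) -> DispersionModel:
    """Maximum conditional likelihood estimate of the common dispersion.

    Iterates library equalization and conditional-likelihood maximization
    (the pseudo-counts depend mildly on the dispersion used to build them).
    """
    depths = effective_depths(counts, factors)
    groups = [counts.samples_for(c) for c in ("control", "cold")]
    groups = [g for g in groups if g]
    if any(len(g) < 2 for g in groups):
        logger.warning("a group has a single replicate; dispersion is estimated from the other group(s)")
        groups = [g for g in groups if len(g) >= 2]
        if not groups:
            raise HomeotripError("no group with >= 2 replicates; cannot estimate dispersion")
    if counts.counts.to_numpy().sum() == 0:
        logger.warning("all counts are zero; dispersion set to 0")
        return DispersionModel(0.0, depths.where(depths > 0, 1.0))
    phi = init_dispersion
    for _ in range(n_iter):
        pseudo_groups = []
        for g in groups:
            ps = quantile_adjust(counts.counts[g], depths.loc[g], phi, geometric_mean(depths))
            y = np.round(ps.to_numpy())
            y = y[y.sum(axis=1) > 0]
            pseudo_groups.append(y)
        res = optimize.minimize_scalar(
            lambda d: -_conditional_loglik(pseudo_groups, d),
            bounds=(1e-6, DISPERSION_BOUNDS[1]),
            method="bounded",
            options={"xatol": 1e-6},
        )
        phi = float(res.x)
        if -res.fun <= _conditional_loglik(pseudo_groups, 1e-10) + 1e-9:
            phi = 0.0
            break
    return DispersionModel(max(phi, 0.0), depths)


# ---------------------------------------------------------------------------
# exact test


def _conditional_log_pmf(total: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Unnormalized log pmf of the group-A total over splits 0..T."""
    x = np.arange(total + 1)
    if dispersion <= 0:
        # Poisson sums condition to a binomial law
        return stats.binom.logpmf(x, total, n_a / (n_a + n_b))
    mu = total / (n_a + n_b)
    ra, rb = n_a / dispersion, n_b / dispersion
    pa = ra / (ra + n_a * mu)
    pb = rb / (rb + n_b * mu)
    return stats.nbinom.logpmf(x, ra, pa) + stats.nbinom.logpmf(total - x, rb, pb)


def nb_exact_test(group_a, group_b, model: DispersionModel | float) -> float:
    """Two-sided exact NB test on equalized pseudo-counts.

    ``group_a`` / ``group_b`` are the (integer, library-equalized) counts of
    one gene in each group.  Returns the conditional minimum-likelihood
    p-value; T = 0 gives p = 1.
    """
    phi = model.dispersion if isinstance(model, DispersionModel) else float(model)
    ya = np.asarray(group_a, dtype=float)
    yb = np.asarray(group_b, dtype=float)
    sa, sb = int(round(ya.sum())), int(round(yb.sum()))
    total = sa + sb
    if total == 0:
        return 1.0
    logp = _conditional_log_pmf(total, ya.size, yb.size, phi)
    logp -= special.logsumexp(logp)
    prob = np.exp(logp)
    p_obs = prob[sa]
    return float(min(1.0, prob[prob <= p_obs * (1 + _TIE_REL_TOL)].sum()))


def exact_test_table(
    counts: CountMatrix,
    model: DispersionModel,
    lfc_pseudo: float = 0.5,
) -> pd.DataFrame:
    """Exact-test every gene, cold vs control.

    Returns a DataFrame with normalized group means (at the common depth),
    log2FC (cold vs control, with ``lfc_pseudo`` added to both means),
    p-values and BH q-values.
    """
    ctrl = counts.samples_for("control")
    cold = counts.samples_for("cold")
    if not ctrl or not cold:
        raise HomeotripError("need samples in both conditions")
    depths = model.effective_lib_sizes
    pseudo = quantile_adjust(counts.counts, depths, model.dispersion)
    y = np.round(pseudo.to_numpy())
    ia = [counts.counts.columns.get_loc(s) for s in ctrl]
    ib = [counts.counts.columns.get_loc(s) for s in cold]
    ya, yb = y[:, ia], y[:, ib]
    pvals = np.ones(y.shape[0])
    for i in range(y.shape[0]):
        pvals[i] = nb_exact_test(ya[i], yb[i], model.dispersion)
    mean_control = ya.mean(axis=1)
    mean_cold = yb.mean(axis=1)
    log2fc = np.log2((mean_cold + lfc_pseudo) / (mean_control + lfc_pseudo))
    out = pd.DataFrame(
        {
            "mean_control": mean_control,
            "mean_cold": mean_cold,
            "log2FC": log2fc,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        },
        index=counts.gene_ids,
    )
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, lfc_threshold: float = 1.0, p_threshold: float = 0.01) -> pd.DataFrame:
    """Threshold-based up/down/ns calls with strict inequalities.

    up: log2FC > lfc_threshold and p < p_threshold; down symmetric.
    """
    out = results.copy()
    up = (out["log2FC"] > lfc_threshold) & (out["pvalue"] < p_threshold)
    down = (out["log2FC"] < -lfc_threshold) & (out["pvalue"] < p_threshold)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out
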