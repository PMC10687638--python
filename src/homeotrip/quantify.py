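"""Within- and between-sample normalization: FPKM, TPM and TMM factors.

FPKM and TPM are the two classical length- and depth-normalized abundance
units; both are exposed because different pipeline stages consume different
units (classification works on FPKM means, coexpression filtering on TPM).
TMM ("trimmed mean of M-values") provides robust between-sample scaling
factors used to equalize effective sequencing depth before the exact test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, HomeotripError, geometric_mean

logger = logging.getLogger(__name__)


def _check_lengths(counts: CountMatrix, lengths: pd.Series) -> pd.Series:
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise HomeotripError(f"gene length missing for {missing[0]!r} (and {len(missing) - 1} more)")
    lengths = lengths.loc[counts.gene_ids].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise HomeotripError(f"non-positive length for gene {bad!r}")
    return lengths


def compute_fpkm(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of gene per million mapped reads.

    FPKM(g, s) = count(g, s) * 1e9 / (librarySize(s) * length(g)).
    """
    lengths = _check_lengths(counts, lengths)
    lib = counts.library_sizes.astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise HomeotripError(f"sample {bad!r} has zero library size")
    vals = counts.counts.to_numpy(dtype=float) * 1e9
    vals /= lengths.to_numpy()[:, None]
    vals /= lib.to_numpy()[None, :]
    return ExpressionMatrix(pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "FPKM")


def compute_tpm(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample."""
    lengths = _check_lengths(counts, lengths)
    rate = counts.counts.to_numpy(dtype=float) / lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        for s in counts.sample_ids[zero]:
            logger.warning("sample %s has no counts; TPM column left all-zero", s)
    colsum = np.where(zero, 1.0, colsum)
    vals = rate / colsum[None, :] * 1e6
    return ExpressionMatrix(pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "TPM")


def _pick_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile count is closest to the mean upper quartile."""
    uq = counts.quantile(0.75, axis=0)
    return str((uq - uq.mean()).abs().idxmin())


def tmm_factors(
    counts: CountMatrix,
    reference_sample: str | None = None,
    log_ratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    min_genes: int = 10,
) -> pd.Series:
    """Per-sample scaling factors by a doubly-trimmed weighted mean of M-values.

    For each sample, M-values are log2 ratios of its counts against the
    reference sample on genes positive in both; the extreme 30% of M and 5%
    of A (average log abundance) are trimmed from each tail; M-values are
    averaged with inverse asymptotic-variance weights.  The factor is the
    multiplier that brings the sample onto the common scale
    (``2 ** -weighted_mean_M``), and factors are rescaled so their geometric
    mean is exactly 1.
    """
    if counts.counts.shape[1] < 2:
        raise HomeotripError("TMM needs at least two samples")
    mat = counts.counts.astype(float)
    ref = reference_sample if reference_sample is not None else _pick_reference(mat)
    if ref not in mat.columns:
        raise HomeotripError(f"reference sample {ref!r} not in matrix")
    lib = counts.library_sizes.astype(float)
    yref = mat[ref].to_numpy()
    raw: dict[str, float] = {}
    for s in mat.columns:
        if s == ref:
            raw[s] = 1.0
            continue
        ys = mat[s].to_numpy()
        ok = (ys > 0) & (yref > 0)
        if ok.sum() < min_genes:
            logger.warning("TMM: <%d genes shared between %s and %s; factor set to 1", min_genes, s, ref)
            raw[s] = 1.0
            continue
        m = np.log2(ys[ok] / yref[ok])
        a = 0.5 * np.log2(ys[ok] * yref[ok])
        # inverse of the delta-method variance of each M-value
        w = 1.0 / ((lib[s] - ys[ok]) / (lib[s] * ys[ok]) + (lib[ref] - yref[ok]) / (lib[ref] * yref[ok]))
        n = ok.sum()
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        keep = (
            (rank_m >= np.floor(n * log_ratio_trim))
            & (rank_m < np.ceil(n * (1 - log_ratio_trim)))
            & (rank_a >= np.floor(n * abundance_trim))
            & (rank_a < np.ceil(n * (1 - abundance_trim)))
        )
        if keep.sum() < min_genes:
            logger.warning("TMM: <%d genes survive trimming for %s; factor set to 1", min_genes, s)
            raw[s] = 1.0
            continue
        mbar = float(np.average(m[keep], weights=w[keep]))
        raw[s] = 2.0 ** (-mbar)
    factors = pd.Series(raw).loc[mat.columns]
    factors /= geometric_mean(factors)
    factors.name = "tmm_factor"
    return factors


def effective_depths(counts: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    """Modelled per-sample sequencing depth used by the NB machinery.

    With no factors this is the raw library size.  With TMM factors (which
    are count multipliers onto a common scale) the modelled depth is
    inversely proportional to the factor, anchored so the geometric mean of
    the depths equals the geometric mean library size.
    """
    lib = counts.library_sizes.astype(float)
    if factors is None:
        return lib
    depths = geometric_mean(lib) / factors.loc[lib.index]
    depths.name = "effective_depth"
    return depths
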