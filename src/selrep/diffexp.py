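"""Negative-binomial two-group differential expression for count matrices.

A deliberately small DE stage: median-of-ratios size factors, normalized
counts, method-of-moments per-gene dispersion, a delta-method Wald test on
pseudo-counted group means, and Benjamini-Hochberg adjustment. It makes the
same modelling assumption as the mainstream NB tools — counts[g, j] ~
NB(mean = s_j * q_gj, variance = mu + alpha_g * mu^2) — but deliberately
omits dispersion shrinkage, LFC shrinkage, independent filtering and outlier
handling; calibration is checked by simulation instead of tool parity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix

__all__ = [
    "size_factors",
    "normalize",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "detection_call",
    "PSEUDOCOUNT",
]

#: pseudo-count added to normalized counts for fold-change/display purposes
PSEUDOCOUNT = 0.5

LOG2 = np.log(2.0)


def size_factors(matrix: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    s_j = median over genes of counts[g, j] / geomean_g(counts[g, :]),
    taken over genes with nonzero counts in every sample. No rescaling is
    applied afterwards. If no gene is expressed in every sample, set
    ``pseudo_reference=True`` to compute gene geometric means over positive
    counts only.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        usable = ~np.all(np.isnan(logc), axis=1)
        if not usable.any():
            raise ValueError("count matrix is all zero; size factors undefined")
        log_geomean = np.nanmean(logc[usable], axis=1)
        ratios = np.log(np.where(counts[usable] > 0, counts[usable], np.nan)) - log_geomean[:, None]
        s = np.exp(np.nanmedian(ratios, axis=0))
    else:
        allpos = (counts > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to use a positive-count reference"
            )
        logc = np.log(counts[allpos])
        log_geomean = logc.mean(axis=1)
        s = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return pd.Series(s, index=matrix.samples, name="size_factor")


def normalize(
    matrix: CountMatrix, factors: pd.Series, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Counts divided by their sample's size factor.

    ``pseudocount`` (typically :data:`PSEUDOCOUNT`) is added after scaling;
    the default 0 returns the raw normalized values. Raises ``KeyError`` for
    samples without a factor.
    """
    missing = matrix.samples.difference(factors.index)
    if len(missing):
        raise KeyError(f"no size factor for sample(s): {', '.join(map(str, missing))}")
    s = factors.loc[matrix.samples]
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("size factors must be finite and positive")
    return matrix.counts.div(s, axis=1) + pseudocount


def _group_columns(metadata: pd.DataFrame, group: str) -> pd.Index:
    cols = metadata.index[metadata["group"] == group]
    if len(cols) == 0:
        raise KeyError(f"group {group!r} not present in metadata")
    return cols


def estimate_dispersion(
    norm: pd.DataFrame, group_labels: pd.Series
) -> pd.Series:
    """Method-of-moments NB dispersion per gene from normalized counts.

    alpha_g = max(0, (pooled within-group variance - mean) / mean^2), where
    the within-group variances (ddof=1) are pooled by degrees of freedom and
    the mean is taken over all samples in ``norm``. Genes with zero counts
    everywhere get NaN (dispersion undefined).
    """
    group_labels = group_labels.loc[norm.columns]
    values = norm.to_numpy(dtype=float)
    ss = np.zeros(values.shape[0])
    df = 0
    for g in group_labels.unique():
        cols = np.asarray(group_labels == g)
        ng = int(cols.sum())
        if ng < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples to estimate dispersion")
        sub = values[:, cols]
        ss += sub.var(axis=1, ddof=1) * (ng - 1)
        df += ng - 1
    pooled_var = ss / df
    mean = values.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum(0.0, (pooled_var - mean) / mean**2)
    alpha[mean == 0] = np.nan
    return pd.Series(alpha, index=norm.index, name="dispersion")


def wald_test(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    target_group: str,
    reference_group: str,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Two-group NB Wald test of target vs reference.

    The statistic is log2fc = log2((mean target + c) / (mean reference + c))
    on normalized group means with pseudo-count c, with a delta-method
    standard error from the NB variance mu + alpha mu^2 propagated through
    each group mean. Because the dispersion entering the SE is itself
    estimated from the pooled within-group variance, z = log2fc / SE is
    referred two-sided to Student's t with n_t + n_r - 2 degrees of freedom
    (the normal reference is visibly anti-conservative at typical replicate
    numbers). Genes with zero counts in all samples of both groups are
    flagged (NaN statistics) and excluded from BH adjustment.

    Returns a DataFrame indexed by gene id with columns ``base_mean``,
    ``log2fc``, ``se``, ``pvalue``, ``adj_p``, ``dispersion``, ``flagged``.
    """
    t_cols = _group_columns(metadata, target_group)
    r_cols = _group_columns(metadata, reference_group)
    if len(t_cols) < 2 or len(r_cols) < 2:
        raise ValueError("both groups need >= 2 replicates")
    sub = CountMatrix(matrix.counts[list(t_cols) + list(r_cols)])
    if factors is None:
        factors = size_factors(matrix)
    norm = normalize(sub, factors)

    labels = metadata.loc[sub.samples, "group"]
    alpha = estimate_dispersion(norm, labels)

    s = factors.loc[sub.samples].to_numpy()
    is_t = np.asarray(labels == target_group)
    values = norm.to_numpy()
    a = np.nan_to_num(alpha.to_numpy(), nan=0.0)

    def _mean_and_var(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = values[:, mask].mean(axis=1)
        # Var(count_j / s_j) = mu / s_j + alpha mu^2 under the NB model
        v = (mu[:, None] / s[None, mask] + a[:, None] * mu[:, None] ** 2).sum(axis=1)
        return mu, v / mask.sum() ** 2

    mean_t, var_t = _mean_and_var(is_t)
    mean_r, var_r = _mean_and_var(~is_t)

    log2fc = np.log2(mean_t + pseudocount) - np.log2(mean_r + pseudocount)
    se = np.sqrt(
        var_t / (mean_t + pseudocount) ** 2 + var_r / (mean_r + pseudocount) ** 2
    ) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    dof = is_t.sum() + (~is_t).sum() - 2
    pvalue = 2.0 * stats.t.sf(np.abs(z), dof)

    flagged = (mean_t == 0) & (mean_r == 0)
    base_mean = norm.to_numpy().mean(axis=1)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "adj_p": np.nan,
            "dispersion": alpha.to_numpy(),
            "flagged": flagged,
        },
        index=sub.genes,
    )
    out.loc[flagged, ["log2fc", "se", "pvalue"]] = np.nan
    tested = ~flagged
    if tested.any():
        out.loc[tested, "adj_p"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values must not contain NaN (exclude flagged genes)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detection_call(
    norm: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    threshold: float = 10.0,
) -> pd.Series:
    """Flag genes below the detection floor in a group.

    True iff every sample of ``group`` has a normalized count strictly below
    ``threshold`` (default 10, the "essentially silent" floor).
    """
    cols = _group_columns(metadata.loc[metadata.index.intersection(norm.columns)], group)
    return pd.Series(
        (norm[list(cols)].to_numpy() < threshold).all(axis=1),
        index=norm.index,
        name="below_detection",
    )
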