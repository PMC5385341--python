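"""Downstream screens over candidate disallowed genes.

Two follow-up questions about a ranked candidate list:

* **Developmental trajectory** — across an ordered series of maturation
  stages, is a gene already silent ("low"), actively shut down
  ("declining"), flat ("stable"), or something else ("other")?
* **Disease association** — in a case/control cohort, is candidate
  expression shifted with disease status at a given FDR?
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import CountMatrix
from .diffexp import wald_test
from .disallowance import GeneList

__all__ = ["classify_trajectories", "status_association"]

TRAJECTORY_CLASSES = ("low", "declining", "stable", "other")


def classify_trajectories(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    stages: Sequence[str] | None = None,
    low_threshold: float = 5.0,
    decline_rho: float = -0.8,
    decline_ratio: float = 0.5,
    stable_ratio: float = 2.0,
) -> pd.DataFrame:
    """Classify per-gene expression trajectories across ordered stages.

    ``expr`` is a genes x samples matrix on a normalized expression scale
    (RPKM or normalized counts — the threshold is in the caller's unit);
    ``metadata`` needs a ``stage`` column and ``stages`` fixes the order
    (defaults to first-appearance order). The rule, applied to per-stage
    mean expression, in order:

    1. "low" if every stage mean < ``low_threshold``;
    2. "declining" if Spearman rho of stage means vs stage index <=
       ``decline_rho`` and last/first stage-mean ratio <= ``decline_ratio``;
    3. "stable" if max/min stage-mean ratio <= ``stable_ratio``;
    4. "other" otherwise.

    Classes are exhaustive and mutually exclusive, and the call depends on
    replicate values only through stage means.
    """
    if "stage" not in metadata.columns or metadata["stage"].isna().any():
        raise ValueError("metadata must provide a stage label for every sample")
    if stages is None:
        stages = list(dict.fromkeys(metadata["stage"]))
    stages = list(stages)
    if len(stages) < 3:
        raise ValueError("trajectory classification needs >= 3 ordered stages")
    unknown = set(metadata["stage"]) - set(stages)
    if unknown:
        raise ValueError(f"sample stage(s) not in the stage order: {sorted(unknown)}")
    for st in stages:
        if (metadata["stage"] == st).sum() < 2:
            raise ValueError(f"stage {st!r} needs >= 2 replicates")

    stage_means = pd.DataFrame(
        {st: expr[metadata.index[metadata["stage"] == st]].mean(axis=1) for st in stages}
    )
    M = stage_means.to_numpy(dtype=float)
    idx = np.arange(len(stages), dtype=float)

    # Spearman rho of stage means against stage order, gene-vectorized
    ranks = stats.rankdata(M, axis=1)
    rho = np.array([stats.pearsonr(row, idx)[0] if len(set(row)) > 1 else 0.0
                    for row in ranks])

    with np.errstate(divide="ignore", invalid="ignore"):
        end_start = M[:, -1] / M[:, 0]
        max_min = M.max(axis=1) / M.min(axis=1)
    end_start = np.where(M[:, 0] == 0, np.inf, end_start)
    max_min = np.where(M.min(axis=1) == 0, np.inf, max_min)

    low = (M < low_threshold).all(axis=1)
    declining = ~low & (rho <= decline_rho) & (end_start <= decline_ratio)
    stable = ~low & ~declining & (max_min <= stable_ratio)
    cls = np.select([low, declining, stable], ["low", "declining", "stable"], "other")

    out = pd.DataFrame(
        {
            "class": cls,
            "spearman_rho": rho,
            "end_start_ratio": end_start,
        },
        index=expr.index,
    )
    for st in stages:
        out[f"mean_{st}"] = stage_means[st]
    return out


def status_association(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    candidates: GeneList | Sequence[str],
    alpha: float = 0.1,
    case_level: str | None = None,
) -> pd.DataFrame:
    """Test candidate genes for association with a binary sample status.

    Runs the NB Wald test of case vs control over *all* genes in the
    matrix, adjusts genome-wide by Benjamini-Hochberg, then reports the
    candidate subset sorted by adjusted p. The ``significant`` flag is
    strictly ``adj_p < alpha`` (default 0.1). Candidates absent from the
    matrix appear with missing statistics and a warning.
    """
    if "status" not in metadata.columns or metadata["status"].isna().any():
        raise ValueError("metadata must provide a status label for every sample")
    levels = list(dict.fromkeys(metadata["status"]))
    if len(levels) != 2:
        raise ValueError(f"status must be binary, found levels {levels}")
    if case_level is None:
        case_level = levels[0]
    control_level = next(l for l in levels if l != case_level)
    for lvl in (case_level, control_level):
        if (metadata["status"] == lvl).sum() < 2:
            raise ValueError(f"status level {lvl!r} needs >= 2 samples")

    meta = metadata.copy()
    meta["group"] = meta["status"]
    de = wald_test(matrix, meta, case_level, control_level)

    genes = list(candidates.genes) if isinstance(candidates, GeneList) else list(candidates)
    if not genes:
        raise ValueError("candidate list is empty")
    missing = [g for g in genes if g not in de.index]
    if missing:
        warnings.warn(
            f"candidate gene(s) absent from the count matrix: {', '.join(missing)}"
        )
    report = de.reindex(genes)[["base_mean", "log2fc", "adj_p"]]
    report["significant"] = report["adj_p"] < alpha
    report.loc[report["adj_p"].isna(), "significant"] = False
    report = report.sort_values("adj_p", na_position="last")
    report.index.name = "gene_id"
    return report
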