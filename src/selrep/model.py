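"""Model/Results interface for the disallowed-gene ranking.

:class:`DisallowanceModel` holds the data and design (count matrix, sample
metadata, the target cell type and the reference tissues); :meth:`fit` runs
the pairwise NB Wald tests, builds the pi-value table, applies the
direction-consistency combination and returns a
:class:`DisallowanceResults` carrying the per-comparison DE tables, the
combined ranking and convenience accessors for top-N candidate lists, the
detection floor and fold-change profiles.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import diffexp, disallowance, structure
from .counts_io import CountMatrix
from .disallowance import GeneList, PiTable

__all__ = ["DisallowanceModel", "DisallowanceResults"]


class DisallowanceModel:
    """Ranking model for genes selectively repressed in a target cell type.

    Parameters
    ----------
    matrix
        Gene x sample count matrix.
    metadata
        Sample metadata with a ``group`` column covering the matrix samples.
    target_group
        The cell type screened for selective repression (e.g., "beta").
    reference_groups
        Tissues the target is compared against pairwise; defaults to every
        non-target group in the metadata.
    pseudocount
        Offset added to normalized group means before log2 ratios.

    Examples
    --------
    >>> from selrep import simulate
    >>> cm, meta, truth = simulate.generate_counts(simulate.SimConfig(seed=7))
    >>> res = DisallowanceModel(cm, meta, "beta").fit()
    >>> top = res.top(20, "down")
    """

    def __init__(
        self,
        matrix: CountMatrix,
        metadata: pd.DataFrame,
        target_group: str,
        reference_groups: Sequence[str] | None = None,
        pseudocount: float = diffexp.PSEUDOCOUNT,
    ) -> None:
        missing = matrix.samples.difference(metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing sample(s): {sorted(missing)}")
        groups = list(dict.fromkeys(metadata.loc[matrix.samples, "group"]))
        if target_group not in groups:
            raise ValueError(f"target group {target_group!r} not in metadata")
        if reference_groups is None:
            reference_groups = [g for g in groups if g != target_group]
        else:
            unknown = set(reference_groups) - set(groups)
            if unknown:
                raise ValueError(f"unknown reference group(s): {sorted(unknown)}")
        if not reference_groups:
            raise ValueError("at least one reference group is required")
        self.matrix = matrix
        self.metadata = metadata.loc[matrix.samples]
        self.target_group = target_group
        self.reference_groups = list(reference_groups)
        self.pseudocount = pseudocount

    @classmethod
    def from_dataframes(
        cls, counts: pd.DataFrame, metadata: pd.DataFrame, target_group: str, **kwargs
    ) -> "DisallowanceModel":
        return cls(CountMatrix(counts), metadata, target_group, **kwargs)

    def fit(
        self,
        require_all_present: bool = True,
        combine_method: str = "min_abs",
    ) -> "DisallowanceResults":
        """Run all pairwise comparisons and combine into a ranking."""
        factors = diffexp.size_factors(self.matrix)
        de_results = {
            ref: diffexp.wald_test(
                self.matrix, self.metadata, self.target_group, ref,
                factors=factors, pseudocount=self.pseudocount,
            )
            for ref in self.reference_groups
        }
        pi_table = disallowance.build_pi_table(de_results)
        combined = disallowance.combine(
            pi_table, require_all_present=require_all_present, method=combine_method
        )
        ranking = disallowance.rank(combined)
        return DisallowanceResults(self, factors, de_results, pi_table, ranking)


class DisallowanceResults:
    """Fitted ranking with uncertainty carried per comparison.

    Attributes
    ----------
    de_results : dict[str, DataFrame]
        One DE table (log2fc, se, pvalue, adj_p, dispersion, flagged) per
        reference comparison.
    pi_table : PiTable
        Per-gene, per-comparison pi scores.
    ranking : DataFrame
        Direction-consistent genes with combined_pi, direction, rank.
    """

    def __init__(
        self,
        model: DisallowanceModel,
        size_factors: pd.Series,
        de_results: dict[str, pd.DataFrame],
        pi_table: PiTable,
        ranking: pd.DataFrame,
    ) -> None:
        self.model = model
        self.size_factors = size_factors
        self.de_results = de_results
        self.pi_table = pi_table
        self.ranking = ranking

    # -- candidate lists ---------------------------------------------------
    def top(self, n: int, direction: str = "down", label: str = "") -> GeneList:
        """Top-``n`` candidate list ("down" = most disallowed)."""
        label = label or f"{self.model.target_group}_{direction}_top{n}"
        return disallowance.top_n(self.ranking, n, direction, label=label)

    # -- diagnostics -------------------------------------------------------
    def below_detection(self, group: str | None = None, threshold: float = 10.0) -> pd.Series:
        """Genes under the detection floor in a group (default: the target)."""
        norm = diffexp.normalize(self.model.matrix, self.size_factors)
        return diffexp.detection_call(
            norm, self.model.metadata, group or self.model.target_group, threshold
        )

    def fold_change_profiles(self, reference_group: str | None = None) -> pd.DataFrame:
        """Group-level log2 fold-change profiles (default reference: target)."""
        return structure.fold_change_profiles(
            self.model.matrix,
            self.model.metadata,
            reference_group or self.model.target_group,
            self.size_factors,
            pseudocount=self.model.pseudocount,
        )

    def summary(self, n: int = 10) -> str:
        """Human-readable summary of the fit and the extremes of the ranking."""
        m = self.model
        lines = [
            "Disallowance ranking (pi-value combination)",
            "=" * 46,
            f"target group:      {m.target_group}",
            f"reference groups:  {', '.join(m.reference_groups)}",
            f"genes:             {len(m.matrix.genes)}",
            f"samples:           {len(m.matrix.samples)}",
            f"scored (direction-consistent): {len(self.ranking)}",
            "",
            f"Top {n} most disallowed (combined pi closest to zero among "
            "consistently repressed genes):",
            f"{'rank':>5} {'gene_id':<16} {'combined_pi':>12} {'weakest_vs':<12}",
        ]
        down = self.ranking.loc[self.ranking["direction"] == "down"].head(n)
        for gene, row in down.iterrows():
            lines.append(
                f"{int(row['rank']):>5} {gene:<16} {row['combined_pi']:>12.3f} "
                f"{row['min_comparison']:<12}"
            )
        up = self.ranking.loc[self.ranking["direction"] == "up"].tail(n)
        lines += [
            "",
            f"Top {n} most enriched:",
            f"{'rank':>5} {'gene_id':<16} {'combined_pi':>12} {'weakest_vs':<12}",
        ]
        for gene, row in up[::-1].iterrows():
            lines.append(
                f"{int(row['rank']):>5} {gene:<16} {row['combined_pi']:>12.3f} "
                f"{row['min_comparison']:<12}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DisallowanceResults: {len(self.ranking)} scored genes, "
            f"{len(self.de_results)} comparisons, target={self.model.target_group!r}>"
        )
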