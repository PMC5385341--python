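"""The pi-value ranking of consistently, selectively repressed genes.

A gene is a candidate "disallowed" gene in a target cell type when it is
expressed broadly across reference tissues but consistently lower in the
target. For each pairwise comparison (target vs one reference tissue) the
fold-change and significance are combined into a single score,

    pi = log2fc * (-log10 adj_p),

so that both highly significant small changes and large variable changes
contribute. Per-comparison scores are combined only for genes whose
fold-change direction is consistent across *all* comparisons, by taking the
pi-value closest to zero (minimum absolute value) — the gene's weakest
evidence. Ranking by the combined score puts the most consistently repressed
genes at one end of the list and the most consistently enriched at the
other; candidate lists are then read off the top of the ranking rather than
through a significance/fold-change threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "pi_value",
    "PiTable",
    "build_pi_table",
    "combine",
    "rank",
    "top_n",
    "GeneList",
    "overlap",
    "TOP_N_PRESETS",
]

#: list sizes used for reporting candidate disallowed genes
TOP_N_PRESETS = (20, 50)

#: floor applied to adjusted p-values before taking logs
ADJ_P_FLOOR = 1e-300


def pi_value(log2fc, adj_p, floor: float = ADJ_P_FLOOR):
    """Combine fold-change and significance: pi = log2fc * (-log10 adj_p).

    ``adj_p`` must lie in (0, 1]; exact zeros (p-value underflow) are floored
    at ``floor`` with a warning, anything negative or above 1 is an error.
    Accepts scalars or arrays; NaNs propagate (missing comparisons).
    """
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(adj_p, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("adjusted p-values must lie in (0, 1]")
    if np.any(p[valid] == 0):
        warnings.warn(
            f"adjusted p-value of 0 floored at {floor:g} before log", stacklevel=2
        )
        p = np.where(p == 0, floor, p)
    out = lfc * (-np.log10(p))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class PiTable:
    """Per-gene, per-comparison fold-changes, adjusted p-values and pi scores.

    Each attribute is a genes x comparisons DataFrame; cells are NaN where a
    gene was flagged (untestable) in that comparison.
    """

    log2fc: pd.DataFrame
    adj_p: pd.DataFrame
    pi: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.log2fc, self.adj_p, self.pi):
            df.index.name = "gene_id"
            df.columns.name = "comparison"

    @property
    def comparisons(self) -> list[str]:
        return list(self.pi.columns)

    @property
    def genes(self) -> pd.Index:
        return self.pi.index

    def to_frame(self) -> pd.DataFrame:
        """Long format: gene_id, comparison, log2fc, adj_p, pi."""
        frames = []
        for name, df in [("log2fc", self.log2fc), ("adj_p", self.adj_p), ("pi", self.pi)]:
            frames.append(df.stack(future_stack=True).rename(name))
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["gene_id", "comparison", "log2fc", "adj_p", "pi"]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PiTable":
        piv = {
            c: df.pivot(index="gene_id", columns="comparison", values=c)
            for c in ("log2fc", "adj_p", "pi")
        }
        return cls(piv["log2fc"], piv["adj_p"], piv["pi"])


def build_pi_table(de_results: Mapping[str, pd.DataFrame]) -> PiTable:
    """Assemble a :class:`PiTable` from per-comparison DE result tables.

    ``de_results`` maps a comparison id (e.g., the reference tissue) to a
    DE table with columns ``log2fc``, ``adj_p`` and ``flagged`` indexed by
    gene id. The gene universe is the outer union; flagged or absent rows
    become missing cells.
    """
    if not de_results:
        raise ValueError("at least one comparison is required")
    genes: pd.Index | None = None
    for df in de_results.values():
        genes = df.index if genes is None else genes.union(df.index)
    lfc = pd.DataFrame(index=genes, columns=list(de_results), dtype=float)
    adj = pd.DataFrame(index=genes, columns=list(de_results), dtype=float)
    for comp, df in de_results.items():
        usable = df.index[~df["flagged"].astype(bool)] if "flagged" in df else df.index
        lfc.loc[usable, comp] = df.loc[usable, "log2fc"]
        adj.loc[usable, comp] = df.loc[usable, "adj_p"]
    pi = pd.DataFrame(
        pi_value(lfc.to_numpy(), adj.to_numpy()), index=genes, columns=list(de_results)
    )
    return PiTable(lfc, adj, pi)


def combine(
    pi_table: PiTable,
    require_all_present: bool = True,
    method: str = "min_abs",
) -> pd.DataFrame:
    """Combine per-comparison pi scores under the direction-consistency rule.

    A gene is scored iff its log2 fold-changes share a strict common sign
    across every (non-missing) comparison; zero fold-change breaks
    consistency. With ``require_all_present`` (default) genes missing from
    any comparison are excluded — consistent repression demands evidence
    against every reference.

    ``method`` selects the combination: ``"min_abs"`` (default) takes the
    pi-value closest to zero; ``"min_signed"`` takes the literal signed
    minimum (for repressed genes this is the *strongest* evidence and is
    provided for comparison only).

    Returns a DataFrame over scored genes with columns ``combined_pi``,
    ``direction`` ("down"/"up"), ``n_comparisons`` and ``min_comparison``
    (the comparison supplying the combined value).
    """
    if len(pi_table.genes) == 0:
        return pd.DataFrame(
            columns=["combined_pi", "direction", "n_comparisons", "min_comparison"]
        )
    if method not in ("min_abs", "min_signed"):
        raise ValueError(f"unknown combination method {method!r}")
    lfc = pi_table.log2fc.to_numpy()
    pi = pi_table.pi.to_numpy()
    present = ~np.isnan(lfc)
    n_present = present.sum(axis=1)

    all_neg = ((lfc < 0) | ~present).all(axis=1) & (n_present > 0)
    all_pos = ((lfc > 0) | ~present).all(axis=1) & (n_present > 0)
    consistent = all_neg | all_pos
    if require_all_present:
        consistent &= n_present == pi.shape[1]

    masked = np.where(present, pi, np.nan)
    if method == "min_abs":
        key = np.abs(masked)
    else:
        # signed minimum: most negative for down-genes, smallest positive for up
        key = masked
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        pick = np.nanargmin(np.where(np.isnan(key), np.inf, key), axis=1)
    rows = np.arange(pi.shape[0])
    combined = masked[rows, pick]

    out = pd.DataFrame(
        {
            "combined_pi": combined,
            "direction": np.where(all_neg, "down", "up"),
            "n_comparisons": n_present,
            "min_comparison": np.asarray(pi_table.comparisons, dtype=object)[pick],
        },
        index=pi_table.genes,
    )
    return out.loc[consistent]


def rank(combined: pd.DataFrame) -> pd.DataFrame:
    """Totally order scored genes by combined pi-value.

    Ascending order: the most negative (most consistently repressed) genes
    sit at rank 1, the most positive (most enriched) at the bottom. Ties are
    broken lexicographically by gene id. Adds a ``rank`` column (1..K).
    """
    if combined.empty:
        warnings.warn("no scored genes to rank")
        out = combined.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = combined.assign(_gene=combined.index).sort_values(
        ["combined_pi", "_gene"], kind="mergesort"
    ).drop(columns="_gene")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class GeneList:
    """An ordered candidate list read off one end of the ranking."""

    genes: list[str]
    scores: list[float]
    direction: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.genes, "combined_pi": self.scores,
             "direction": self.direction}
        )


def top_n(ranking: pd.DataFrame, n: int, direction: str, label: str = "") -> GeneList:
    """The ``n`` most extreme genes of a direction ("down" or "up").

    "down" lists start from the most negative combined pi (most disallowed),
    "up" lists from the most positive. Returns fewer than ``n`` (with a
    warning) when the direction is exhausted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("down", "up"):
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    sub = ranking.loc[ranking["direction"] == direction]
    sub = sub.sort_values("rank", ascending=(direction == "down"))
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} {direction}-regulated gene(s) available for top-{n}"
        )
    head = sub.head(n)
    return GeneList(
        genes=list(head.index),
        scores=list(head["combined_pi"]),
        direction=direction,
        label=label or f"top{n}_{direction}",
    )


def overlap(lists: Iterable[GeneList]) -> pd.DataFrame:
    """Exact Venn region counts for two or more gene lists.

    Returns one row per non-empty membership pattern with columns per list
    label (bool), ``count`` and ``genes`` (comma-joined, sorted). Region
    counts sum to the size of the union.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("overlap needs at least two gene lists")
    labels = [gl.label or f"list{i+1}" for i, gl in enumerate(lists)]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i+1}" for i, lab in enumerate(labels)]
    membership: dict[str, tuple[bool, ...]] = {}
    for gene in set().union(*(set(gl.genes) for gl in lists)):
        membership[gene] = tuple(gene in set(gl.genes) for gl in lists)
    rows = []
    patterns = sorted(set(membership.values()), reverse=True)
    for pat in patterns:
        members = sorted(g for g, p in membership.items() if p == pat)
        rows.append({**dict(zip(labels, pat)), "count": len(members),
                     "genes": ",".join(members)})
    return pd.DataFrame(rows)
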