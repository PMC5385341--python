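"""Structure discovery: fold-change clustering, co-expression modules, ORA.

Complements the ranked lists with three views of shared behaviour:

* hierarchical clustering of per-group log2 fold-change profiles relative to
  a reference group (which genes are repressed in the same tissues);
* weighted co-expression network analysis on variance-stabilized expression:
  soft-thresholded correlation adjacency, topological overlap, average-
  linkage clustering, static tree cut, module eigengenes and trait
  association;
* hypergeometric over-representation of user-supplied gene sets within a
  candidate list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .counts_io import CountMatrix, GeneSetCollection
from .diffexp import PSEUDOCOUNT, bh_adjust, normalize
from .disallowance import GeneList

__all__ = [
    "fold_change_profiles",
    "vst",
    "ClusterTree",
    "hcluster",
    "tom",
    "Module",
    "detect_modules",
    "eigengene",
    "module_trait",
    "group_indicator",
    "ora",
]


def fold_change_profiles(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    reference_group: str,
    factors: pd.Series,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2 fold-change of every group against a reference group.

    Entry (g, group) = log2((mean norm in group + c) / (mean norm in
    reference + c)); the reference column is identically zero. This is the
    matrix behind fold-change heatmaps and fold-change clustering.
    """
    groups = list(dict.fromkeys(metadata["group"]))
    if reference_group not in groups:
        raise KeyError(f"reference group {reference_group!r} not in metadata")
    norm = normalize(matrix, factors)
    means = pd.DataFrame(
        {g: norm[metadata.index[metadata["group"] == g]].mean(axis=1) for g in groups}
    )
    ref = means[reference_group]
    return np.log2(means.add(pseudocount)).sub(np.log2(ref + pseudocount), axis=0)


def vst(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilized expression: log2(normalized count + 0.5).

    A parameter-free, monotone stand-in for fitted variance-stabilizing
    transforms; adequate for the correlation-based analyses downstream.
    """
    return np.log2(normalize(matrix, factors, pseudocount=PSEUDOCOUNT))


@dataclass
class ClusterTree:
    """Agglomerative tree over named leaves (scipy linkage + labels)."""

    linkage: np.ndarray
    leaves: list[str]
    metric: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, height: float) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaves)
        return str(tree).strip()


def hcluster(
    data: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> ClusterTree:
    """Deterministic agglomerative clustering of the rows of ``data``."""
    if data.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    if data.isna().to_numpy().any():
        raise ValueError("input contains missing values")
    Z = hierarchy.linkage(data.to_numpy(), method=method, metric=metric)
    return ClusterTree(Z, [str(i) for i in data.index], metric, method)


def tom(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Topological overlap matrix of genes (rows of ``expr``).

    Adjacency a_ij = |cor(g_i, g_j)|^beta (unsigned network, diagonal 0);
    overlap w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_u a_iu; w_ii = 1.
    """
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr.to_numpy())
    if np.isnan(corr).any():
        raise ValueError("constant gene rows must be removed before TOM")
    a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    w = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(w, 1.0)
    return pd.DataFrame(w, index=expr.index, columns=expr.index)


@dataclass
class Module:
    """A co-expression module: members, per-sample eigengene, associations."""

    label: str
    genes: list[str]
    eigengene: pd.Series
    soft_power: float
    trait_associations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component of gene-standardized member expression.

    Expression rows are z-scored per gene, so the summary is invariant to
    gene-wise rescaling; the score is unit-variance per sample and
    sign-oriented so the mean gene loading is positive.
    """
    X = expr.to_numpy(dtype=float)
    X = (X - X.mean(axis=1, keepdims=True))
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    X = X / sd
    # samples x genes SVD; first right-singular vector of gene space
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    score = Vt[0]
    loadings = X @ score
    if loadings.mean() < 0:
        score = -score
    score = score - score.mean()
    sdev = score.std(ddof=0)
    if sdev > 0:
        score = score / sdev
    return pd.Series(score, index=expr.columns, name="eigengene")


def detect_modules(
    expr: pd.DataFrame,
    beta: float = 6.0,
    min_size: int = 10,
    cut_height: float = 0.9,
) -> list[Module]:
    """Detect co-expression modules by topological overlap clustering.

    Average-linkage clustering on the TOM dissimilarity 1 - w, cut
    statically at ``cut_height``; clusters of at least ``min_size`` genes
    become modules (labelled M1, M2, ... by decreasing size) with eigengenes.
    Genes outside any such cluster stay unassigned; constant genes are
    dropped with a warning.

    Uncorrelated genes have overlap near 0 (dissimilarity near 1), so the
    default cut at 0.9 requires substantial shared-neighbourhood structure
    while tolerating the moderate overlap (~0.3-0.6) that realistic
    correlated modules reach.
    """
    if expr.shape[1] < 4:
        raise ValueError("module detection needs >= 4 samples")
    var = expr.to_numpy().var(axis=1)
    if (var == 0).any():
        dropped = expr.index[var == 0]
        warnings.warn(f"dropping {len(dropped)} constant gene(s) before TOM")
        expr = expr.loc[expr.index[var > 0]]
    if expr.shape[0] < min_size:
        return []
    w = tom(expr, beta=beta)
    dissim = 1.0 - w.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2  # enforce exact symmetry for squareform
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    modules = []
    sizes = pd.Series(labels).value_counts()
    for cluster_id in sizes.index[sizes >= min_size]:
        members = list(expr.index[labels == cluster_id])
        modules.append(
            Module(
                label="",
                genes=members,
                eigengene=eigengene(expr.loc[members]),
                soft_power=beta,
            )
        )
    modules.sort(key=lambda m: (-len(m.genes), m.genes[0]))
    for i, m in enumerate(modules, 1):
        m.label = f"M{i}"
    return modules


def group_indicator(metadata: pd.DataFrame, group: str) -> pd.Series:
    """0/1 indicator of membership in a tissue/cell-type group."""
    return (metadata["group"] == group).astype(float).rename(group)


def module_trait(module: Module, trait: pd.Series) -> tuple[float, float]:
    """Pearson association between a module eigengene and a sample trait.

    ``trait`` is a numeric covariate or a 0/1 group indicator over the same
    samples as the eigengene; p comes from the t-distribution with n - 2
    degrees of freedom. The result is also stored on the module under the
    trait's name.
    """
    x = module.eigengene
    y = trait.loc[x.index].astype(float)
    if y.nunique() <= 1:
        raise ValueError("trait is constant; association undefined")
    r, p = stats.pearsonr(x.to_numpy(), y.to_numpy())
    name = trait.name if trait.name is not None else f"trait{len(module.trait_associations)}"
    module.trait_associations[str(name)] = (float(r), float(p))
    return float(r), float(p)


def ora(
    gene_list: GeneList | list[str],
    sets: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets within a list.

    For each set: population N = |universe|, successes K = |set|, draws
    n = |list|, overlap k; the one-sided upper-tail p is P(X >= k). List
    members outside the universe are dropped with a warning; BH adjustment
    runs across sets.

    Returns a DataFrame indexed by set name with columns ``overlap``,
    ``list_size``, ``set_size``, ``universe_size``, ``pvalue``, ``adj_p``.
    """
    uni = set(universe) if universe is not None else set(sets.universe)
    if not uni:
        raise ValueError("empty universe")
    members = list(gene_list.genes) if isinstance(gene_list, GeneList) else list(gene_list)
    inside = [g for g in members if g in uni]
    if len(inside) < len(members):
        warnings.warn(
            f"{len(members) - len(inside)} list gene(s) outside the universe dropped"
        )
    n, N = len(inside), len(uni)
    rows = {}
    for name, genes in sets.sets.items():
        K = len(genes & uni)
        k = len(genes & set(inside))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows[name] = (k, n, K, N, min(p, 1.0))
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["overlap", "list_size", "set_size", "universe_size", "pvalue"],
    )
    out.index.name = "set_name"
    if len(out):
        out["adj_p"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["adj_p"] = []
    return out
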