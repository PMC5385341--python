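"""Synthetic multi-tissue RNA-seq count data with planted ground truth.

The generator emulates the study design behind disallowed-gene screens:
several tissue/cell-type groups with replicate libraries, negative-binomial
counts with per-gene dispersion, varying library sizes, a subset of genes
repressed only in the target group(s), a correlated gene module driven by a
latent per-sample factor, a stage-ordered developmental time course, and a
case/control cohort with planted expression shifts.

Counts follow NB(mean = s_j * q_g * 2^lfc, dispersion alpha_g) with variance
mu + alpha * mu^2, the same mean/dispersion convention the differential
expression stage estimates, so planted effects are interpretable in the units
the pipeline reports. Baseline means q_g are log-normal, dispersions are
gamma; both are heteroscedastic across genes as in real bulk data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix

__all__ = [
    "ConfigError",
    "SimConfig",
    "SyntheticTruth",
    "generate_counts",
    "generate_timecourse",
    "generate_cohort",
]

#: non-islet reference tissues used in the default study design
DEFAULT_REFERENCE_GROUPS = (
    "brain", "heart", "kidney", "liver", "lung", "spleen", "thymus",
)


class ConfigError(ValueError):
    """Simulation configuration violates an invariant."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults encode the default study design: a target cell type ("beta")
    plus seven reference tissues, three replicate libraries each, 2,000
    genes of which 40 are repressed 16-fold only in the target group, 40 are
    enriched 16-fold, and 50 form a latent-factor co-expression module.

    Parameters
    ----------
    baseline_mean, baseline_sigma
        Per-gene baseline expected normalized counts are drawn log-normal
        with expectation ``baseline_mean`` and log-scale spread
        ``baseline_sigma``.
    dispersion_shape, dispersion_mean
        Per-gene NB dispersions alpha_g ~ Gamma(shape, mean/shape); the
        default mean 0.05 is typical of bulk replicates.
    library_size_factors
        Optional explicit per-sample size factors; if None, drawn
        log-uniformly from ``library_size_range``.
    module_loading
        Scale of the shared standard-normal latent factor added to module
        genes on the log2-mean scale; in (0, 1).
    """

    n_genes: int = 2000
    groups: Sequence[tuple[str, int]] = field(
        default_factory=lambda: [("beta", 3)] + [(g, 3) for g in DEFAULT_REFERENCE_GROUPS]
    )
    target_groups: Sequence[str] = ("beta",)
    baseline_mean: float = 200.0
    baseline_sigma: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.05
    library_size_factors: Sequence[float] | None = None
    library_size_range: tuple[float, float] = (0.5, 2.0)
    n_disallowed: int = 40
    disallowed_log2fc: float = -4.0
    n_enriched: int = 40
    enriched_log2fc: float = 4.0
    module_size: int = 50
    module_loading: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.groups:
            raise ConfigError("at least one group is required")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ConfigError("group names must be unique")
        for name, n_rep in self.groups:
            if n_rep < 2:
                raise ConfigError(f"group {name!r} needs >= 2 replicates")
        unknown = set(self.target_groups) - set(names)
        if unknown:
            raise ConfigError(f"target group(s) not in groups: {sorted(unknown)}")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.dispersion_shape <= 0 or self.dispersion_mean < 0:
            raise ConfigError("dispersion parameters must be non-negative (shape > 0)")
        for n, label in [
            (self.n_disallowed, "n_disallowed"),
            (self.n_enriched, "n_enriched"),
            (self.module_size, "module_size"),
        ]:
            if n < 0:
                raise ConfigError(f"{label} must be >= 0")
        if self.n_disallowed + self.n_enriched + self.module_size > self.n_genes:
            raise ConfigError(
                "planted gene sets exceed n_genes: "
                f"{self.n_disallowed} + {self.n_enriched} + {self.module_size} "
                f"> {self.n_genes}"
            )
        if self.n_disallowed and self.disallowed_log2fc >= 0:
            raise ConfigError("disallowed_log2fc must be negative")
        if self.n_enriched and self.enriched_log2fc <= 0:
            raise ConfigError("enriched_log2fc must be positive")
        if self.module_size and not (0 < self.module_loading < 1):
            raise ConfigError("module_loading must lie in (0, 1)")
        n_samples = sum(n for _, n in self.groups)
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != n_samples:
                raise ConfigError(
                    f"library_size_factors has {len(self.library_size_factors)} "
                    f"entries for {n_samples} samples"
                )
            if any(s <= 0 for s in self.library_size_factors):
                raise ConfigError("library size factors must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must satisfy 0 < lo <= hi")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    disallowed_genes: set[str] = field(default_factory=set)
    enriched_genes: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    latent_factor: pd.Series | None = None
    trajectory_class: pd.Series | None = None
    status_shifted_genes: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format manifest (gene_id, role, planted_log2fc)."""
        rows = []
        for g in sorted(self.disallowed_genes):
            rows.append((g, "disallowed", np.nan))
        for g in sorted(self.enriched_genes):
            rows.append((g, "enriched", np.nan))
        for g in sorted(self.module_genes):
            rows.append((g, "module", np.nan))
        if self.trajectory_class is not None:
            for g, cls in self.trajectory_class.items():
                rows.append((g, f"trajectory:{cls}", np.nan))
        for g, lfc in sorted(self.status_shifted_genes.items()):
            rows.append((g, "status_shifted", lfc))
        return pd.DataFrame(rows, columns=["gene_id", "role", "planted_log2fc"])


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"gene{str(i).zfill(width)}" for i in range(n)]


def _draw_baselines(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    # log-normal with expectation baseline_mean: E = exp(mu + sigma^2/2)
    mu = np.log(cfg.baseline_mean) - cfg.baseline_sigma**2 / 2
    return rng.lognormal(mu, cfg.baseline_sigma, size=n)


def _draw_dispersions(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.dispersion_mean == 0:
        return np.zeros(n)
    scale = cfg.dispersion_mean / cfg.dispersion_shape
    return rng.gamma(cfg.dispersion_shape, scale, size=n)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2; alpha == 0 is Poisson."""
    alpha = np.broadcast_to(np.asarray(alpha, float)[:, None], mean.shape)
    counts = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        counts[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        counts[~pois] = rng.negative_binomial(r, p)
    return counts


def _size_factors_for(rng: np.random.Generator, cfg: SimConfig, n_samples: int) -> np.ndarray:
    if cfg.library_size_factors is not None:
        return np.asarray(cfg.library_size_factors, dtype=float)
    lo, hi = cfg.library_size_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))


def generate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a multi-group count matrix with planted structure.

    Returns the count matrix, sample metadata (``group`` column) and the
    :class:`SyntheticTruth` naming planted disallowed/enriched/module genes
    and the module's latent factor. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config.n_genes)
    sample_ids, group_of = [], []
    for name, n_rep in config.groups:
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{name}_{r}")
            group_of.append(name)
    n_samples = len(sample_ids)
    in_target = np.array([g in set(config.target_groups) for g in group_of])

    q = _draw_baselines(rng, config, config.n_genes)
    alpha = _draw_dispersions(rng, config, config.n_genes)
    s = _size_factors_for(rng, config, n_samples)

    order = rng.permutation(config.n_genes)
    dis_idx = order[: config.n_disallowed]
    enr_idx = order[config.n_disallowed : config.n_disallowed + config.n_enriched]
    mod_idx = order[
        config.n_disallowed + config.n_enriched :
        config.n_disallowed + config.n_enriched + config.module_size
    ]

    log2fc = np.zeros((config.n_genes, n_samples))
    log2fc[np.ix_(dis_idx, in_target)] = config.disallowed_log2fc
    log2fc[np.ix_(enr_idx, in_target)] = config.enriched_log2fc

    z = rng.standard_normal(n_samples)
    if config.module_size:
        log2fc[mod_idx, :] += config.module_loading * z[None, :]

    mean = s[None, :] * q[:, None] * 2.0**log2fc
    counts = _nb_sample(rng, mean, alpha)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    metadata = pd.DataFrame({"group": group_of}, index=pd.Index(sample_ids, name="sample_id"))
    truth = SyntheticTruth(
        disallowed_genes={genes[i] for i in dis_idx},
        enriched_genes={genes[i] for i in enr_idx},
        module_genes={genes[i] for i in mod_idx},
        latent_factor=pd.Series(z, index=sample_ids, name="latent_factor"),
    )
    return matrix, metadata, truth


def generate_timecourse(
    config: SimConfig,
    stages: Sequence[str],
    n_replicates: int = 3,
    p_low: float = 0.2,
    p_declining: float = 0.2,
    decline_ratio: float = 0.1,
    low_mean: float = 2.0,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a stage-ordered developmental time course.

    Genes are assigned trajectory classes: "low" genes sit at ``low_mean``
    (below any sensible detection threshold) at every stage, "declining"
    genes fall geometrically so the last stage mean is ``decline_ratio``
    times the first, and the remainder are "stable". Library size factors
    are 1 so counts are on the normalized scale. Stage order follows the
    ``stages`` argument.
    """
    config.validate()
    if len(stages) < 3:
        raise ConfigError("a time course needs >= 3 stages")
    if len(set(stages)) != len(stages):
        raise ConfigError("stage labels must be unique")
    if n_replicates < 2:
        raise ConfigError("each stage needs >= 2 replicates")
    if not (0 <= p_low and 0 <= p_declining and p_low + p_declining <= 1):
        raise ConfigError("class proportions must be in [0, 1] and sum to <= 1")
    if not (0 < decline_ratio < 1):
        raise ConfigError("decline_ratio must lie in (0, 1)")

    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_stages = len(stages)

    n_low = int(round(p_low * config.n_genes))
    n_dec = int(round(p_declining * config.n_genes))
    order = rng.permutation(config.n_genes)
    classes = np.full(config.n_genes, "stable", dtype=object)
    classes[order[:n_low]] = "low"
    classes[order[n_low : n_low + n_dec]] = "declining"

    q = _draw_baselines(rng, config, config.n_genes)
    # keep non-low baselines comfortably above the low-expression floor so
    # the planted classes are unambiguous
    floor = 20.0 * low_mean
    q = np.where((classes != "low") & (q < floor), floor + q, q)
    alpha = _draw_dispersions(rng, config, config.n_genes)

    stage_mult = np.ones((config.n_genes, n_stages))
    t = np.arange(n_stages) / (n_stages - 1)
    stage_mult[classes == "declining"] = decline_ratio**t[None, :]
    q_eff = np.where(classes == "low", low_mean, q)
    stage_means = q_eff[:, None] * stage_mult

    sample_ids, stage_of = [], []
    for st in stages:
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"{st}_{r}")
            stage_of.append(st)
    mean = np.repeat(stage_means, n_replicates, axis=1)
    counts = _nb_sample(rng, mean, alpha)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    metadata = pd.DataFrame(
        {"group": "beta", "stage": stage_of},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(
        trajectory_class=pd.Series(classes, index=genes, name="trajectory_class")
    )
    return matrix, metadata, truth


def generate_cohort(
    config: SimConfig,
    n_cases: int,
    n_controls: int,
    shifted: Mapping[str, float] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a case/control cohort with planted status-associated shifts.

    ``shifted`` maps gene ids (``gene0000`` style, matching the emitted
    matrix) to the log2 fold-change planted in cases relative to controls;
    all other genes are null.
    """
    config.validate()
    if n_cases < 2 or n_controls < 2:
        raise ConfigError("need >= 2 cases and >= 2 controls")
    shifted = dict(shifted or {})

    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    unknown = set(shifted) - set(genes)
    if unknown:
        raise ConfigError(f"shifted gene id(s) not in matrix: {sorted(unknown)}")

    n_samples = n_cases + n_controls
    sample_ids = [f"case_{i+1}" for i in range(n_cases)] + [
        f"ctrl_{i+1}" for i in range(n_controls)
    ]
    status = ["case"] * n_cases + ["control"] * n_controls
    is_case = np.array([st == "case" for st in status])

    q = _draw_baselines(rng, config, config.n_genes)
    alpha = _draw_dispersions(rng, config, config.n_genes)
    # explicit library_size_factors apply to generate_counts only (they are
    # sized to config.groups); cohorts draw from the configured range
    lo, hi = config.library_size_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    log2fc = np.zeros((config.n_genes, n_samples))
    for g, lfc in shifted.items():
        log2fc[gene_pos[g], is_case] = lfc

    mean = s[None, :] * q[:, None] * 2.0**log2fc
    counts = _nb_sample(rng, mean, alpha)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    metadata = pd.DataFrame(
        {"group": "islet", "status": status},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(status_shifted_genes=shifted)
    return matrix, metadata, truth
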