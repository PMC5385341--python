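# Methods

This note documents the statistical model behind `selrep`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical corner cases. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts are modelled as negative binomial per gene and sample,

    K_gj ~ NB(mean = s_j · q_gj,  variance = μ + α_g μ²),

with `s_j` a per-sample size factor, `q_gj` the normalized expected
expression, and `α_g ≥ 0` a per-gene dispersion. This is the standard
mean–dispersion parameterization of bulk RNA-seq tools, chosen so that
planted effects in simulations and estimated effects in the pipeline are in
the same units.

**Size factors** are median-of-ratios: over genes with nonzero counts in
every sample, `s_j = median_g K_gj / geomean(K_g·)`, with no rescaling
afterwards. When no gene is positive everywhere, a `pseudo_reference`
fallback computes each gene's geometric mean over its positive counts only.
Size factors are identified only up to a common scale: multiplying one
column of the matrix by `c` multiplies its factor by `c` *relative to the
others* exactly (the geometric-mean reference absorbs `c^(1/n)` of the
change uniformly), which is the form in which equivariance is tested.

**Normalized counts** are `K_gj / s_j`. A pseudo-count of 0.5 is added for
fold-change and display purposes only, mirroring the common convention of
offsetting normalized counts by 0.5 so that zeros remain visible on log
axes and log fold-changes stay finite.

**Dispersion** is method-of-moments on normalized counts:
`α_g = max(0, (v_g − m_g) / m_g²)` with `v_g` the within-group variance
pooled by degrees of freedom and `m_g` the mean over the samples of the
comparison. Genes with zero counts everywhere have undefined dispersion and
are flagged. No shrinkage across genes is applied; the estimator is noisy
at small replicate numbers, which the test below accounts for.

**The Wald test** compares two groups on pseudo-counted normalized means:
`log2FC = log2((m_t + 0.5)/(m_r + 0.5))`, with a delta-method standard
error propagating the per-sample NB variance `μ/s_j + αμ²` through each
group mean and the log transform. Because the dispersion entering the SE is
itself estimated from the pooled within-group variance (≈ `n_t + n_r − 2`
degrees of freedom), the statistic `log2FC / SE` is referred two-sided to
Student's *t* with `n_t + n_r − 2` df rather than the normal: at five
replicates per group and 10,000 simulated null NB genes (mean 100,
dispersion 0.1) the normal reference rejects at ~8.6% for a nominal 5% and
has a KS distance from uniformity of ~0.037, while the *t* reference gives
~5.0–5.3% and KS ~0.008–0.015 across seeds (recomputed by
`scripts/acceptance.py`). The two references coincide as replication grows.

Genes with zero counts in all samples of both groups are flagged; their
statistics are undefined and they are excluded from the Benjamini–Hochberg
denominator. BH runs per pairwise comparison (each comparison is its own
multiple-testing family), through the standard step-up procedure.

**Detection floor.** A gene is called below detection in a group when every
sample of that group has fewer than 10 normalized counts — the conventional
threshold for "essentially silent".

Deliberately omitted relative to full-featured DE tools: dispersion
shrinkage toward a mean–dispersion trend, LFC shrinkage, independent
filtering, outlier replacement, multi-factor designs. The stage is validated
by calibration and planted-recovery simulation, not by parity with any
external tool.

## π-value ranking

Per comparison, `π = log2FC · (−log10 adj_p)`; the sign of π is the sign of
the fold-change, and `π = 0` iff `log2FC = 0` or `adj_p = 1`. Adjusted
p-values of exactly zero (underflow) are floored at 1e−300 before the log,
with a warning; values outside (0, 1] are errors.

Combination: a gene is scored iff its fold-change direction is strictly
consistent — the same sign in every comparison, zeros breaking consistency
— and its combined π is the per-comparison π of **minimum absolute value**
("closest to zero"): the gene's weakest evidence against any reference,
which is what "consistently repressed everywhere" requires. Genes missing
from any comparison (flagged rows) are excluded by default
(`require_all_present=False` relaxes this). A literal `min_signed` variant
(the signed minimum, i.e., the *strongest* evidence for repressed genes) is
exposed for comparison, since "smallest π" is ambiguous between the two
readings; `min_abs` is the default because only the weakest-evidence
reading makes the combined score a guarantee over all references.

Ranking sorts scored genes by combined π ascending; ties break
lexicographically by gene id so output is reproducible. Candidate lists are
read off the ends (`top_n`, with the conventional sizes 20 and 50 as
presets); no significance or fold-change threshold defines "disallowed" —
the method deliberately ranks instead. `overlap` computes exact Venn region
counts across lists.

## Structure discovery

**Fold-change profiles** are per-group `log2((mean + 0.5)/(mean_ref + 0.5))`
against a chosen reference group; the reference column is identically zero.
Hierarchical clustering of profiles defaults to Euclidean distance and
average linkage (both configurable; no canonical choice exists for such
heatmaps), runs through `scipy.cluster.hierarchy`, and exports Newick via
scikit-bio.

**VST.** Correlation-based analyses run on `log2(normalized + 0.5)` — a
parameter-free, monotone variance-stabilizing transform. Fitted VSTs
change values but barely change gene–gene correlations, which is all the
network stage consumes.

**Module detection** follows the weighted co-expression network recipe:
unsigned adjacency `a_ij = |cor|^β` with soft power β = 6 (the customary
default for unsigned networks), topological overlap
`ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij)`, average-linkage
clustering on `1 − ω`, and a **static** cut (no dynamic tree cut) with
clusters of ≥ 10 genes becoming modules. The cut height defaults to 0.9:
since `ω ≈ a` within a large coherent module, a module whose genes
correlate at |cor| ≈ 0.8–0.9 sits at TOM dissimilarity ≈ 0.4–0.7, while
uncorrelated genes concentrate near 1 (empirically > 0.98 at 60 samples);
0.9 cleanly separates the regimes, whereas a much lower cut would require
near-perfect correlation and detect nothing. All parameters (β, minimum
size, cut height) are exposed.

**Eigengenes** are the first principal component of gene-standardized
member expression (hence invariant to gene-wise rescaling), unit variance
across samples, sign-oriented to a positive mean loading. Trait association
is the Pearson correlation between eigengene and a numeric covariate or 0/1
group indicator, with p from the *t* distribution on n − 2 df.

**ORA** is the one-sided hypergeometric upper tail `P(X ≥ k)` per gene set
(population = universe, successes = set, draws = list), BH-adjusted across
sets. The universe defaults to the union of set members; callers analysing
genome-wide lists should supply the full measured universe instead.

## Screens

**Trajectory classification** operates on per-stage mean expression in the
caller's unit (RPKM or normalized counts — the threshold travels with the
unit). The rule, in order: *low* if every stage mean < 5; *declining* if
Spearman ρ(stage means, stage index) ≤ −0.8 **and** last/first ratio ≤ 0.5;
*stable* if max/min ratio ≤ 2; else *other*. The ρ and ratio cutoffs
operationalize "consistent down-regulation" and "little clear change";
only the <5 floor has a conventional value, so all three cutoffs are
configurable. Classes are exhaustive, mutually exclusive, and invariant to
replicate order.

**Status association** runs the Wald test of case vs control over *all*
genes, adjusts genome-wide (candidate adj_p values must come from a
transcriptome-wide family, not a 20-gene one), then reports the candidate
subset sorted by adjusted p with a `significant` flag at strictly
`adj_p < 0.1` by default.

## Synthetic data

The generator emulates the study design the screen is meant for: one target
cell type plus a panel of reference tissues, a handful of replicate
libraries each, NB counts with per-gene dispersion, and varying library
depths.

Defaults, chosen once as a realistic desk-scale design: 2,000 genes; groups
`beta` + {brain, heart, kidney, liver, lung, spleen, thymus} with 3
replicates each; baseline means log-normal with expectation 200 normalized
counts and log-sd 1 (two orders of magnitude of expression spread);
dispersions Gamma with mean 0.05 and shape 2 (typical bulk biological
replication); library size factors log-uniform in [0.5, 2]; 40 genes
repressed 16-fold (log2FC −4) in the target only; 40 genes enriched
16-fold; a 50-gene module driven by a standard-normal per-sample latent
factor with loading 0.8 on the log2-mean scale. Time-course mode plants
{low, declining, stable} classes with a 10× geometric decline for
"declining" genes and keeps non-low baselines well above the low floor so
planted classes are unambiguous; cohort mode plants case-only log2
fold-changes. All outputs are deterministic given the seed.

Not emulated: read-level data (FASTQ), GC/length bias, batch effects,
cross-study heterogeneity of real compendia (the real screen mixes single-
and paired-end studies from many labs), cell-type contamination of
FACS-purified samples, and correlated gene–gene structure beyond the single
planted module. Passing planted-recovery tests therefore demonstrates that
the algebra and inference behave as specified under the stated model — not
that the screen is robust to every artefact of real compendia; on real
data, contamination in particular inflates apparent expression of repressed
genes and is the main caveat for interpretation.

## Numerical choices and degenerate inputs

- Adjusted p floored at 1e−300 before logs; π therefore finite always.
- Zero counts: pseudo-count 0.5 keeps fold-changes finite; an all-zero gene
  is flagged, not tested, and excluded from the BH family.
- Underdispersed genes clamp to α = 0 (Poisson).
- Dispersion = 0 simulations draw Poisson counts directly.
- Ties in ranking break by gene id; module labels order by size then first
  member, so all outputs are byte-stable across runs at a fixed seed.
- Constant genes are dropped (with a warning) before correlation networks;
  constant traits are an error.
- TOM dissimilarity is symmetrized to machine precision before linkage.
- `fcluster`-style static cuts use distance criterion; merge heights are
  non-decreasing by construction of average linkage.

## Known limitations

- The DE stage's per-gene MoM dispersion is inefficient below ~3 replicates
  per group; calibration was verified at 5 + 5 and will degrade at 2 + 2.
- Static tree cut cannot separate nested or overlapping modules; only
  well-separated modules are recovered.
- The π combination requires full evidence by default, so a gene untestable
  against even one tissue drops out of the ranking unless
  `require_all_present=False`.
- Trajectory classification uses stage means only; within-stage variance is
  ignored (duplicate/triplicate designs carry too few df to model it well).
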