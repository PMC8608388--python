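# Methods

This note documents the statistical models, the synthetic data they are
validated on, the numerical choices, and the limits of what the test suite
demonstrates.

## Data model

The unit of analysis is a proteins × samples matrix of iBAQ intensities
(summed peptide intensity over theoretically observable peptides — a
per-protein abundance proxy). Exactly one representation of missingness is
used throughout: **0 means not detected**. Each analysis arm decides for
itself whether a zero is "missing" (frequentist and empirical-Bayes arms)
or "data" (self-similarity transform, random-forest features, CV/count
descriptives). Detection is missing-not-at-random: the probability of
observing a protein rises with its latent abundance and with the volume of
fluid collected, so zeros are biased toward low-abundance proteins and
small samples. Sample metadata carries the comparison label, colony,
volume (µl), an optional pairing key, and the sample scale (pooled colony
vs single individual); the two scales are analysed separately because
protein counts correlate with volume on both scales.

Protein-level pre-filters mirror standard search-engine output hygiene:
contaminant, decoy ("reverse") and only-identified-by-site groups are
excluded, as are identification scores **strictly below** 70 (a score of
exactly 70 is kept). Protein identity defaults to the first accession of
the majority-protein-IDs group.

## Frequentist arm

Pipeline: presence filter (strictly more than 70% of samples, i.e. a
protein in exactly 70% is dropped) → log2 → per-sample median centering
(detected values only) → per-sample downshifted-normal imputation: missing
entries of sample *s* are drawn from Normal(μ_s − 2σ_s, (0.3σ_s)²), where
μ_s, σ_s are the observed mean and SD. The 0.3 width is interpreted in SD
units, like the shift, following the convention of the desktop proteomics
tools that popularised this imputation.

The test statistic is `d_g = (x̄_B − x̄_A)/(se_g + s0)` with pooled-variance
standard error and `s0 = 2` — the SAM-style regularisation in which the
constant enters the denominator on the standard-error scale, damping
proteins whose nominal significance rests on a vanishing variance.
Paired designs use the per-pair differences, `d = x̄_diff/(se_diff + s0)`.

Permutation FDR: group labels are relabelled (or pair signs flipped); with
`C(n, n_B) ≤ n_permutations` (default 1000) enumeration is exhaustive and
the observed assignment is the first row of the enumeration, so the
identity permutation's tie with the observed threshold is counted
bit-identically (both group sums are computed directly rather than via
complements for the same reason). At threshold *t*,
`FDR(t) = (mean #null |d| ≥ t over permutations) / (#observed |d| ≥ t)`,
clipped to [0, 1]; a protein's q is the minimum estimate over all
candidate thresholds at which it would still be called, making q
non-increasing in |d|. No π₀ correction is applied. Two-sided throughout.
Significance: q ≤ 0.05 for colony-scale comparisons. Single-individual
comparisons use Welch t with Benjamini–Hochberg adjustment at the stricter
0.01, the convention for that noisier design; the switch is automatic from
the sample scale and can be overridden. The factorial individual design
(colony × behaviour) is additionally analysed per protein by two-way
ANOVA with type-II sums of squares (unstated in the original description;
type II is the standard choice for main effects in near-balanced factorial
designs) and BH adjustment within each factor.

## Empirical-Bayes arm

Log2 with zeros missing, per-sample median normalisation, then per-protein
two-group OLS. Residual variances are assumed exchangeable,
`σ²_g ~ s₀²·d₀/χ²_{d₀}`, giving the posterior
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` and a moderated t with `d₀ + d_g`
degrees of freedom. The prior is estimated by moment matching on the log
scale: with `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`, the excess of
`var(e)` over the sampling component `mean(ψ′(d_g/2))` identifies d₀ by
trigamma inversion (Newton, tolerance 1e-10) and s₀² follows from the mean
of e. No excess dispersion yields the degenerate prior d₀ = ∞ with
s₀² = exp(mean e). This estimator reproduces Bioconductor limma's
`fitFDist`/`eBayes` to machine precision on complete data (asserted in the
test suite by running limma through Rscript), but limma remains an
independent cross-check only — the implementation here is self-contained.

No imputation in this arm: proteins with fewer than two observed values in
either group are reported *untested* (and counted in the results object),
keeping the arm's assumptions independent of the frequentist arm's
MNAR imputation. Significance: BH q ≤ 0.05 **and** |log2FC| ≥ 2. The
α = 0.05 is chosen to match the frequentist arm's level; the fold-change
gate is the arm's defining convention.

## Random-forest arm

Features are the raw iBAQ values with zeros as zeros — deliberately no
imputation or normalisation, so the arm sees the data through a third,
independent lens. For each of 10 seeds: stratified 80/20 split
(stratification keeps both classes present at small n), fit a forest
(100 trees, depth ≤ 5, √p features per split, min leaf 3, min split 8,
out-of-bag scoring); if test accuracy < 85%, one 3-fold cross-validated
grid search over depth {3, 5} × min-split {8, 12} × trees {100, 500};
retain the seed iff final accuracy > 75%. Reported accuracy averages over
retained seeds. Per-sample class scores are out-of-bag for training
samples and full-ensemble probabilities for held-out or new samples
("out-of-box" scores). Cross-prediction scores new samples (missing
proteins filled with 0) with the first five retained models, in seed
order.

Feature importance is the mean |Shapley value| per protein across all
samples, averaged over retained models, computed by an exact
path-dependent tree-Shapley recursion (`tropho/_treeshap.py`): per
root-to-leaf path the algorithm tracks, per subset size, the summed
permutation weights of feature subsets keeping the path active, with
branch probabilities taken from training cover. Attributions are exact
Shapley values of the tree's cover-conditional expectation and satisfy
per-sample efficiency `Σ_j φ_j(x) = f(x) − E[f]` to floating point; the
implementation is verified against a brute-force subset-enumeration
oracle.

**A structural caveat on the 0.15 selection cutoff.** Because the model
output is a class probability, each sample's total attribution mass is
bounded by |f(x) − E[f]| ≤ ~0.5 and is *shared* across the proteins the
forest uses. Mean-|Shapley| importance above a fixed 0.15 therefore
requires a protein to carry a large fraction of the classification
single-handedly. With many redundant markers (e.g. 30–50 planted
differential proteins) the mass spreads and no protein crosses the
cutoff — the arm then contributes nothing to the consensus, which
degrades gracefully to the two testing arms. The cutoff is exposed in
`ProtocolConfig.fi_cutoff`; the suite exercises the selection rule on a
small panel with a single dominant marker, where it selects that marker
with precision 1.0.

## Consensus

A protein untested by an arm (presence-filtered out, too few observations,
or no retained models) counts as not significant in that arm; the
consensus set is `n_methods ≥ 2`, and the seven exclusive Venn regions are
reported. The algebra is property-tested: regions sum to the union,
per-arm totals match, consensus equals the ≥2-method region sum.

## Descriptive layer

*Self-similarity.* Abundances are square-root transformed and
median-subtracted, distances are standardized Euclidean (per-protein SD,
ddof = 1, computed across all samples of the two compared groups; zero-SD
proteins dropped), and per sample
`S = |D̄_within − D̄_across| / D̄_all`. S = 0 marks a sample equidistant to
both group centroids. The median subtraction is **per protein** by
default: per-protein centering leaves inter-sample distances unchanged
(so the metric is the standardized distance structure itself), and it is
the reading under which the degenerate one-protein configuration has a
defined S; the per-sample alternative is exposed via
`median_axis="sample"`. The standalone `sqrt_median_transform` used
elsewhere centers per sample.

*Variability and counts.* CV = SD/mean per protein per type over strictly
positive intensities (≥ 2 positives required), modelled by a gamma GLM
with log link on sample type; detected-protein counts per sample by a
negative-binomial GLM with log link (the NB maximum likelihood starts at
the per-type log means; if the dispersion collapses to the zero boundary —
counts not overdispersed — the model degenerates to its Poisson limit,
which is then used). All pairwise type contrasts get the single-step
max-|z| adjustment (multivariate-normal equicoordinate probabilities),
the standard multiple-comparison treatment for GLM contrasts. Pearson
correlation of count vs volume is computed separately per sample scale.
PCA operates on raw intensities, column-centered and unscaled (the
centering/scaling convention is unstated in the field descriptions this
mirrors; centered-unscaled is the minimal choice).

## Synthetic generator

`SyntheticSpec` defaults define the package's standard study conditions:
500 proteins, 20 samples per group, baseline abundances 10^N(7, 1.2)
(five orders of magnitude), a 5% core set that never drops out, 50 planted
differential proteins at |log2FC| = 4 with random sign applied to group B,
multiplicative log2-normal noise (SD 0.5), and logistic detection in
log10 abundance (midpoint 10^5, slope 1 per decade) shifted by
0.5·(volume − mean volume) per µl — about 20% zeros overall, i.e.
*moderate* dropout. Volumes are log-normal (mean ≈ 4 µl for colony pools,
≈ 0.8 µl for individuals). Individual-scale samples receive colony-level
log2-normal intercepts (SD 0.5) from colonies assigned round-robin and
crossed with groups. All randomness flows from one master seed through
named `SeedSequence` substreams, so output is byte-identical per spec.

What the generator does **not** emulate: the real fluid's much heavier
sparsity (57% of proteins present in fewer than half the samples in the
motivating dataset), correlated protein modules, batch structure, or
peptide-level effects. Recovery results under the default conditions
(consensus sensitivity ≈ 0.75 at false-discovery proportion ≈ 0 over ten
master seeds) therefore certify the pipeline's mechanics — filters,
statistics, gates and their composition — not its power on data with
real-world sparsity, where the presence filter removes far more of the
signal and the consensus is correspondingly more conservative.

## Numerical and degenerate-input conventions

- Score filter is strict `<`; presence filter is strict `>`.
- `s0 = 0` with zero pooled SD is an error; any `s0 > 0` yields a finite
  statistic.
- Permutation FDR with zero discoveries at a threshold is defined as 0;
  estimates are clipped to [0, 1] before monotonisation.
- BH adjustment validates p ∈ [0, 1] and preserves input order.
- A sample with no detected values (log transform) or fewer than two
  observed values (imputation) raises an error naming the sample.
- Zero-SD proteins are dropped from standardized distances; a sample at
  zero distance from all others is an error.
- Splits that lose a class are re-drawn with a derived seed (≤ 10 tries).
- Forest out-of-bag gaps (a sample in every bootstrap) fall back to the
  full-ensemble probability for that sample.
- Problem sizes in the test suite are scaled to desk hardware: the
  type-I suite uses 20 null datasets of 500 × 40, recovery uses 10 master
  seeds, oracle comparisons enumerate all two-group layouts up to 10
  samples.

## Known limitations

- The permutation FDR's sampled (non-exhaustive) mode draws distinct
  assignments without replacement but its oracle equivalence is only
  asserted for exhaustive enumeration.
- The moderated model supports two-group contrasts only (no multi-factor
  linear models, trends, or robust variants).
- Feature-importance selection with a fixed absolute cutoff on
  probability-scale Shapley values is scale-bound (see above); ranking by
  importance is meaningful regardless.
- The gamma GLM excludes zero CVs (constant positive proteins) since a
  gamma response must be positive.
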