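# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## The setting

A case/control cohort of hiPSC-derived cultures: each donor contributes one
to three clonal lines, each line is differentiated and profiled in up to two
culture cell types (NPC, neuron). Observations from the same donor are
correlated (shared genetics and reprogramming history), and each bulk
profile is a mixture of constituent cell types whose proportions vary from
differentiation to differentiation. The pipeline's job is to quantify these
nuisance structures, correct for them, and keep the case/control inference
calibrated despite them.

## Synthetic cohorts

`synthetic.simulate_cohort` draws, in a fixed order from one seeded
generator stream: the signature panel (if not supplied), per-gene effect
assignments, donor attributes, library sizes, per-sample Dirichlet mixing
proportions, per-donor gene effects, residual noise, the Sendai covariate,
and finally counts.

Per gene g and sample s (donor d, culture type t), the log2 mean is

    mu_gs = log2( sum_c pi_sc * S_gc + 1 ) + u_gd + beta_g * 1[d is case]

with `pi_s ~ Dirichlet(alpha_t)` over the reference profiles,
`u_gd ~ N(0, sigma_d_g^2)`, and `beta_g ~ N(0, lfc_sd^2)` on a random
fraction `frac_de_genes` of genes (zero elsewhere). Counts are
negative-binomial with `Var = mu + phi mu^2` (gamma–Poisson; `phi = 0`
degenerates to Poisson), with library sizes log-normal.

Defaults mirror the emulated cohort: 11 + 11 donors, two lines per donor,
NPC + neuron cultures (88 samples), donor effect 2.2%, dispersion 0.1,
library sizes around 2×10⁷. Where the cohort description gives no value
(DE fraction 0.10, log2-FC spread 0.30, Dirichlet concentrations, marker
structure of the panel) the defaults are one-time choices of plausible
magnitudes and are documented here as such.

**Donor-effect calibration.** The target intraclass correlation `icc`
defines `sigma_d^2 = icc * sigma_res^2 / (1 − icc)` against a *total*
residual log2-scale budget `sigma_res = 0.5`. Counting noise is part of
that budget: the delta-method log2-variance of an NB count,
`v_NB = (1/mu + phi) / ln(2)^2`, is subtracted from `sigma_res^2` and only
the remainder is added as Gaussian noise (clipped at zero). For
well-expressed genes the realized donor fraction therefore matches `icc` in
expectation; for weakly expressed genes (`1/mu` large) the residual floor
exceeds the budget and the donor fraction is attenuated — as in real data.
A genome-wide variance-partition median consequently sits *below* the
nominal `icc` when most genes' donor variance is near the estimator's
boundary at zero, while the consensus-correlation estimator (a trimmed mean,
not a median of boundary-truncated values) recovers it closely; the
acceptance script reports both routes.

Sex signatures are written in CPM units against the sample's simulated
transcriptome total (XIST 50 CPM / chrY 30 CPM when "on", 0.2 CPM "off"),
so log2-CPM thresholds behave identically at any gene count; intermediate
samples are 50/50 male/female mixtures. CNV events multiply the mean of
genes inside a (0-based, half-open) region for one donor's samples by the
dosage. The Sendai covariate is a quantile-normalized nonnegative score,
positive only for the configured donors.

`simulate_paired_cohorts` gives two cohorts whose true effect vectors are
jointly normal with a requested correlation (exactly equal at ±1), sharing
the DE gene set; cohort B's counts are adjusted multiplicatively on case
samples, which is exact on the mean scale.

**What the generator does not emulate:** batch/technician effects with real
structure (a round-robin batch label is provided but carries no signal),
RIN or other continuous technical covariates, donor-specific differentiation
propensity (mixing is independent of donor, so correcting for composition
does not unmask donor variance the way it can in real cohorts), isoform- or
GC-level biases, and outlier samples. Passing tests demonstrate correctness
of the estimators under the stated model, not robustness to everything real
data contains.

## Normalization and QC

Filtering retains genes with CPM > 1 (raw library sizes, pre-TMM) in at
least `ceil(0.30 · n)` samples; a gene exactly at the 30% boundary is
retained. TMM factors are weighted trimmed means of gene-wise log2 ratios
against a reference sample (the one whose library-scaled 75th percentile is
closest to the mean), trimming 30% of M-values and 5% of A-values, weights
from the delta-method variance of M; factors are rescaled to geometric mean
1 and log2-CPM uses a prior count of 0.5 (scaled per sample by effective
library size). Degenerate trims fall back to factor 1 with a warning.

Sex calls: female if XIST ≥ 2 and mean chrY < 1 (log2-CPM), male if
XIST < 1 and mean chrY ≥ 2, otherwise intermediate. The thresholds are
package choices (the separation in both real and simulated data is many
log2 units, so the exact values are uncritical within that gap).

CNV z-scores: log2-CPM is residualized on cell type (one-way OLS), then
z-scored per gene across samples (sd with one delta degree of freedom).
Zero-variance genes get z = 0 with a `flat_gene` flag rather than NaN. Gene
coordinates are 1-based inclusive and converted internally to the BED
convention.

## Cell-type composition

Scores come from nonnegative least squares of the sample's linear-scale
expression on the signature profiles, restricted to marker genes (top 50
per profile by fold over the mean of the others), after standardizing each
gene by the panel's per-profile mean and sd. Because centering breaks
affine consistency, the design includes a free mean-term column (a ±pair
under the nonnegative solver): with it, a pure profile recovers a unit
score, noise-free mixtures recover their weights exactly, and the
normalized scores are invariant to rescaling a sample — properties the
tests assert at 1e-6. Coefficients are summed within cell type
(multiple noisy representatives per type are deliberate) and normalized to
sum 1. The scores are comparative, not absolute percentages: the panel is
incomplete and cross-species, so only differences across samples are
interpreted, and any externally computed score table can be substituted.

Residualization is per-gene OLS on intercept + covariates (rank-checked,
collinear columns named in the error); PCs are computed on centered,
unscaled log2-CPM. The PC screen correlates every score with the first
`n_pcs` PCs of every matrix and flags at `alpha / (n_scores · n_pcs ·
n_matrices)`.

## Variance partitioning

Per gene, REML with the residual variance profiled out: minimize
`(n−p)·log(y'P̃y) + log|V₀| + log|X'V₀⁻¹X|` over log variance ratios,
`V₀ = I + Σ_k γ_k Z_k Z_k'`, by L-BFGS-B from two starts (a flat start and
a method-of-moments start); non-convergence marks the gene NA with a
reason. Random-effect fractions are `σ̂²_k / total`; each fixed effect
contributes the empirical variance of `X_k β̂_k` across samples; residual is
`σ̂²_e / total`. Fractions are invariant to affine rescaling of y and sum
to 1 (asserted at 1e-8). Genes with total variance < 1e-12 are skipped.
For a balanced one-way design the estimate equals the ANOVA ICC estimator
truncated at zero; the tests verify agreement to 1e-3, which bounds the
optimizer tolerance. Diagnosis is nested within donor yet both components
are fitted; with few donors the split between them is partly confounded and
the diagnosis fraction should be read qualitatively.

## eQTL fold enrichment

Cutoffs are 40 quantile-spaced points of the observed fraction
distribution; at each cutoff with more than 100 genes passing,
`FE = observed / mean(permuted)` where permutation shuffles the fraction
vector across genes (equivalently: samples the overlap hypergeometrically —
the tests check the permutation mean against `n_pass·n_top/n_universe` at
2%). The 90% band is the (0.05, 0.95) permutation quantiles of the same
ratio. The curve is truncated at the first cutoff at or below 100 genes.
Because cutoffs are quantile-based, the curve is invariant to monotone
transforms of the fractions.

## Differential expression

Precision weights follow the mean–variance-trend recipe: per-gene OLS on
log2-CPM, lowess of sqrt(residual sd) on average log2 count (span 0.5),
weights = predicted⁻⁴ at each observation's fitted log2 count.

The consensus correlation fits, per gene, a compound-symmetry correlation
to the residual covariance (grid of ~80 values over
(−1/(k_max−1), 0.99) via the shared eigendecomposition of the
block-membership matrix, vectorized across genes) and combines estimates by
a 15%-trimmed mean on the Fisher-z scale. Parameterizing by the correlation
itself, not a nonnegative variance ratio, lets null data average to ~0
instead of stacking at a boundary. With no replicated blocks the function
warns and returns 0, and supplying a block structure with one sample per
donor reproduces the unblocked analysis exactly.

GLS solves each gene with the block-CS correlation (shared Cholesky
whitening when weights are absent; per-gene covariance when present); a
singular correlation receives a 1e-6 ridge with a warning. Moderation
estimates (d₀, s₀²) by moment matching on log variances (digamma/trigamma
inversion, Newton); equal variances give d₀ = ∞ and the pooled analysis.
Moderated t uses d₀ + df degrees of freedom and the reported SE is
|log2FC/t|, so SE, t and log2FC stay mutually consistent. Storey q-values
estimate π₀ from a cubic fit to π₀(λ) over λ = 0.05…0.95 evaluated at
λ = 0.95, clamped to (1/m, 1].

On null cohorts with a donor-level contrast, ignoring the donor correlation
inflates type-I error to ≈ `2Φ(−z_{α/2}/√(1+ρ(k−1)))` (≈0.085 at ρ = 0.3,
k = 2); the acceptance script computes both the GLS (~0.05) and OLS rates.

## Concordance and sample maps

Concordance is rank (and linear) correlation of per-gene statistics on the
gene intersection, one-sided p via the t approximation with average ranks
for ties. Distances are 1 − Pearson correlation after quantile
normalization (sorted-mean reference; ties interpolate the reference at
average ranks); category trees use the median cross-category distance and
complete linkage, serialized as Newick; classical MDS double-centers the
squared distances and truncates to the positive eigenvalues (warning if
fewer than requested).

## Coexpression

Unsigned adjacency `|cor|^β`, β = 9; TOM with connectivity excluding
self-links and `TOM_ii = 1`. Modules are branches of the average-linkage
tree on 1 − TOM below a static cut at 0.99 × the tallest merge height —
uncorrelated genes join the tree at dissimilarity ≈ 1 while coherent
branches merge well below, so this one-parameter cut stands in for dynamic
branch pruning; it is configurable and its behavior (planted blocks found,
independent genes grey, sub-minimum blocks grey) is pinned by tests.
Branches under 20 genes fall into grey; labels follow the conventional
colour order by size, with stable sorted-gene-id processing so input order
cannot change the result. Module enrichment tests every module *including
grey* (diffuse signals concentrate there) against the clustered-gene
universe, Bonferroni over modules × sets.

## Effective sample size and design

`ESS = Σ k_i / (1 + (k_i − 1)ρ)` (inverse Kish design effect per donor,
exact under compound symmetry); ESS is m at ρ = 1 and n at ρ = 0, a new
donor adds exactly 1, and the (k+1)-th line adds
`(k+1)/(1+kρ) − k/(1+(k−1)ρ)`, strictly decreasing in ρ. ρ can be a single
value or summarized (median) from a variance-partition run. The optimizer
enumerates (number of donors m, total extra lines L) with the L lines
spread as evenly as possible — exact because the per-donor contribution is
discretely concave in k — under either a budget or a fixed-donor
constraint; ties prefer fewer total lines, then more donors. Costs:
`c_d` per donor including the first line, `α·c_d` per extra line, α ∈ (0,1].

## Orchestration

`pipeline.run_pipeline` chains qc → deconvolution → varpart → enrichment →
DE → coexpression → design from a YAML config (unknown keys and parameters
rejected), writes one subdirectory per stage plus a manifest (seed,
resolved parameters, input checksums, per-stage summaries), floats at 10
significant digits; identical config + seed reproduce outputs byte for
byte. A stage failure writes a FAILED marker naming the stage and re-raises.
The coexpression stage restricts to the most-variable genes (default 2000)
to keep the O(G²) network tractable.

## Problem sizes

The test suite and acceptance script use desk-scale versions of each
analysis — cohorts of 500–5000 genes and 12–80 donors, 2000 permutations
for the enrichment null, 20 replicates for the concordance regimes, 150–200
genes per variance-partition recovery point — sizes chosen so each check's
Monte-Carlo error is comfortably inside the asserted tolerance while the
whole suite runs in minutes on one core.

## Known limitations

- The variance-partition median understates small donor effects when many
  genes sit at the boundary (see calibration note above); compare with the
  consensus-correlation route when the donor effect is the quantity of
  interest.
- The moderation prior assumes a single scaled-inverse-chi-square variance
  population; strong mean–variance structure should be absorbed by the
  precision weights first.
- The static module cut is a simplification of dynamic branch pruning;
  nested module structure within a tall branch is not split.
- CTC scores are comparative; absolute composition claims require a
  same-species, same-platform reference panel.
- The ESS formula assumes one variance scale shared by all genes and
  compound symmetry within donors; designs with strong line-level (clone)
  effects nested inside donors would need a second correlation level.
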