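# Methods

## Problem setting and model

The package targets individualized tumor/nontumor diagnosis from bulk
expression profiles pooled across heterogeneous cohorts. The core statistic
is the within-sample gene-pair order indicator: for a canonical pair
(a, b), a < b lexicographically, a sample scores s_ab = 1 iff its
expression of a strictly exceeds that of b, and 0 otherwise (ties score 0).
Because s_ab depends on the expression vector only through the order of two
of its entries, it is invariant to every strictly increasing per-sample
transform — the formal content of the claim that the features need no batch
correction. The diagnostic score is a sparse linear function of pair
indicators, score = β₀ + Σ_k β_k s_k, with tumor coded as the positive
class throughout.

Assumptions worth stating: expression is gene-level and log2-scale (the
pair indicator itself only needs monotonicity, but the differential screen
interprets differences as log2 fold changes); batch effects act per sample
as monotone distortions plus per-gene additive shifts — pair features
neutralize the former and the cross-dataset consensus screen is robust to
the latter because screening happens within datasets; and nontumor
heterogeneity (adjacent normal, adenoma, healthy) is a labeling of the
negative class only.

## Differential screening

Each dataset is screened separately with a moderated two-sample t-test.
Gene-wise pooled variances s²_g (d_g = n₁ + n₀ − 2 df) are shrunk toward a
common prior s₀² with weight d₀ estimated by the standard closed-form
method of moments on log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over
ψ′(d_g/2) determines d₀ through the inverse trigamma (Newton iteration),
and E(e) then determines s₀². When the excess is non-positive the solution
is d₀ = ∞ and every gene is tested against s₀² (the normal reference is
used for the resulting infinite df; we do not replicate limma's capping of
the total df at the summed residual df, which matters only in this limit).
Genuinely degenerate moment estimates fall back to the plain pooled t-test
with a warning. p-values are two-sided; q-values are Benjamini–Hochberg
(via statsmodels, cross-checked against a literal step-up oracle).

Screening keeps genes with q < 0.05 and |log₂FC| > 0.585 — both strict, so
boundary ties are excluded; 0.585 is kept verbatim (≈ log₂ 1.5). log₂FC is
defined as mean(tumor) − mean(nontumor) of log2 values. The consensus rule
keeps genes flagged in ≥ 4 datasets (configurable), sorted
lexicographically so the downstream pair enumeration is deterministic.
Screening is per-dataset-then-count rather than on the merged pool: the
consensus frequency is the quantity of interest, and within-dataset
screening is immune to additive batch shifts.

## Penalized signature fit

The signature minimizes the L1-penalized average binomial negative
log-likelihood with unpenalized intercept. Binary pair features are *not*
standardized: coefficients stay interpretable on the 0/1 indicator scale,
and standardizing near-constant indicators would inflate them. The solver
is cyclic coordinate descent on the IRLS quadratic approximation
(weights clamped at 1e-5), warm-started along a descending grid of 100
log-spaced λ values from λ_max = max_j |(1/n) Σ_i x_ij (y_i − ȳ)| (the KKT
bound at which the penalized solution is exactly zero) down to
λ_max·10⁻³; convergence when the largest coefficient change falls below
1e-9. Every fitted solution satisfies the KKT stationarity system to well
under 1e-6 (certified in the tests), and the path agrees with glmnet run
with `standardize = FALSE` to ~1e-4.

λ is selected by stratified, seeded 10-fold cross-validation of the
held-out mean binomial deviance (probabilities clamped at 1e-10), taking
the largest λ whose mean CV deviance is within one standard error (SD
across folds / √folds) of the minimum. Stratification guards against folds
losing a class under the tumor/nontumor imbalance typical of these cohorts.

The published 19-pair signature ships with its printed coefficients to nine
decimals and zero intercept — the published coefficients carry no
intercept, and since ROC/AUC is invariant to score shifts this choice does
not affect any evaluation; `score_samples(..., include_intercept=False)`
exposes the alternative. Pair orientation is lexicographic (every published
pair is printed in alphabetical order), and coefficients are interpreted
with respect to that orientation.

## Evaluation

AUC is the Mann–Whitney midrank statistic, AUC = P(score_T > score_N) +
½P(tie), which equals the trapezoidal area under the ROC step curve
(predict positive when score ≥ threshold); the equivalence is asserted to
1e-12 in the tests. Subgroup evaluation: for nontumor subtypes — defined
only on negative samples — each subtype's nontumor samples are compared
against the pooled tumor samples; for platform and dataset strata, where
every sample carries the key, the comparison is within stratum. Strata
lacking a class are reported with AUC = NaN rather than dropped.
Comparator gene-list signatures are evaluated by unpenalized logistic
regression on raw expression (scikit-learn, iteration-capped against
separation), by default in the resubstitution design. The comparator gene
lists themselves are caller inputs, not package constants.

## Synthetic generator

The generator emulates a multi-cohort two-class compendium: a shared gene
universe with per-gene baseline means U(6, 12) and SDs U(0.3, 0.8) (log2
units, typical of processed arrays), per-gene-per-batch additive shifts
N(0, 0.3), and a configurable informative subset shifted in tumor samples
by ±effect_lfc with signs fixed per gene. Per-dataset class sizes default
to (53, 34), the mean composition of the five training cohorts
(263/5, 172/5). Each informative gene carries its effect in a given
dataset independently with probability `informative_in_fraction`
(default 0.8), modeling cross-dataset DEG frequency. Optional per-sample
distortions are affine maps on the log2 scale or power maps applied on the
anti-logged scale and re-logged; the latter is algebraically again affine
in log space (x → γx + log₂ c) — both are kept for interface parity, and
tests additionally use nonlinear monotone maps. Randomness is split
hierarchically (collection seed → per-dataset → per-sample) via
`SeedSequence` spawn keys, so extending a collection never perturbs
existing datasets.

What the generator does **not** model: probe-level noise,
normalization artifacts, count-based RNA-seq distributions, correlated
gene modules, or non-monotone batch effects. Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not clinical performance on real cohorts — the
published cohort AUCs require the original GEO/TCGA downloads and are out
of scope here.

A consequence of the Bernoulli effect-frequency design worth knowing when
reading recovery numbers: with 5 datasets, frequency 0.8 and a ≥4/5
consensus rule, an informative gene is *recoverable* only with probability
0.4096 + 0.32768 ≈ 0.737, so even a perfect screen recovers about 74% of
informative genes on average (binomial SD ≈ 2 genes of 20). Sensitivity is
therefore reported both against all informative genes and against the
recoverable set (genes whose planted effect lands in ≥ min_datasets
datasets — the estimand the consensus rule actually targets); the second is
the implementation-quality metric.

## Problem sizes and numerical choices

Seeded test and acceptance runs use the default conditions (5 × (53+34)
samples, 1,000 genes, 20 informative at effect 1.0, frequency 0.8), chosen
to mirror the training-compendium scale while keeping a full pipeline run
around a minute on one CPU; unit tests use smaller instances. Other
numerics: pair ties score 0 exactly per the indicator's definition (no
random tie-breaking); missing signature genes are an error, never imputed,
since silent imputation would corrupt an individualized score; duplicate
gene rows must be collapsed explicitly (arithmetic probe mean);
score computation uses a fixed-order, fixed-layout reduction so equal
indicator matrices yield bit-identical scores; consensus lists with fewer
than two genes short-circuit to an explicitly empty signature (the null-run
behavior) rather than failing.

## Known limitations

Gene identity is the bare case-sensitive symbol with no alias resolution;
cross-platform merging intersects gene sets (how the original study
handled platform-specific genes is unstated); the GEO reader parses only
the series-matrix table block; and elastic-net variants, refitting on the
selected support, probability calibration, and confidence intervals or
DeLong tests for AUCs are deliberately out of scope.
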