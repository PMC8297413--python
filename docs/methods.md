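# Methods

## Model and assumptions

The package implements summary-level two-sample Mendelian randomization.
For variant j, let γⱼ be its true effect on the exposure and Γⱼ its true
effect on the outcome. A valid instrument satisfies the three IV
assumptions (associated with the exposure; independent of confounders;
affecting the outcome only through the exposure), under which

    Γⱼ = θ · γⱼ,

with θ the causal effect of interest. Horizontal pleiotropy adds a direct
effect αⱼ, so Γⱼ = θγⱼ + αⱼ, and the six estimators differ in what they
assume about the αⱼ. Throughout, the observed coefficients are treated as
normally distributed around their true values with known standard errors,
and the exposure coefficients are treated as exact in all weights and
ratio standard errors (the NOME / first-order convention:
se(r̂ⱼ) = σ_Γⱼ/|γ̂ⱼ|). A second-order Wald-ratio SE that propagates
γ-uncertainty is available via `harmonize(..., second_order_se=True)`.

## Pipeline stages and their parameters

**Selection.** Statistical route: p < 5×10⁻⁸ (strict inequality, as
printed in GWAS convention), greedy index-variant clumping at r² < 0.001
within a 10,000 kb window; ties in p are broken by (chromosome, position,
id) so clumping is deterministic. Biological route: restriction to
candidate-gene intervals (1-based inclusive), the same p threshold, and
r²-pruning at 0.1 with no distance window — inside a gene region, LD above
the bar disqualifies regardless of distance. LD pairs absent from the
user-supplied table are treated as independent with a warning; passing
`strict_ld=True` treats them as dependent instead (conservative when the
LD table is known to be incomplete). Instrument strength is F = (β̂/σ̂)²
with the conventional F > 10 bar, and variance explained uses the identity
r² = F/(F + n − 2), which needs only printed fields.

**Harmonization.** The outcome association is re-expressed on the
exposure's effect allele: same orientation kept; swapped alleles flip the
outcome beta's sign and replace eaf by 1 − eaf; strand-complement
representations (A↔T, C↔G) are complemented first. Palindromic variants
(A/T or G/C pairs) carry no strand information, so they are oriented by
effect-allele-frequency agreement; when the minor-allele frequency exceeds
0.42 in *either* dataset, or eaf is missing, frequency is uninformative
and the variant is excluded. The "either dataset" reading is the
conservative resolution of an ambiguity (the threshold could be applied to
one dataset only); it is what the harmonization tests assume. Variants
with γ̂ = 0 exactly are excluded rather than producing infinite ratios.
Proxy substitution is an explicit pre-step (`apply_proxies`) taking a
user-supplied (missing id → proxy id, r²) table with r² ≥ 0.8 enforced; no
reference-panel lookup is performed.

## Estimators

**IVW.** θ̂ = Σwⱼr̂ⱼ/Σwⱼ with wⱼ = 1/se(r̂ⱼ)² (equivalently γ̂ⱼ²/σ_Γⱼ²),
identical to the origin-constrained WLS slope of Γ̂ on γ̂ with weights
1/σ_Γ². Heterogeneity is Cochran's Q = Σwⱼ(r̂ⱼ − θ̂)² on J − 1 df. The
default random-effects model is *multiplicative*: the fixed-effect SE is
scaled by max(1, √(Q/(J−1))). A multiplicative rather than additive model
was chosen because it keeps the point estimate identical to the
fixed-effect one and is the standard choice for summary-data MR; the
max(1, ·) floor never rewards under-dispersion. Normal reference for
p-values and CIs.

**MR-Egger.** Instruments are oriented so γ̂ⱼ > 0 (flipping both
coefficients leaves each ratio unchanged), then intercept + slope are
fitted by WLS with weights 1/σ_Γ². The intercept estimates the mean direct
effect ᾱ (requires InSIDE: instrument strength independent of direct
effects). SEs are scaled by max(1, √(RSS/(J−2))) and p-values use the t
reference with J − 2 df — the heavier-tailed reference is the standard
small-J practice for Egger and is applied to slope and intercept alike.

**Weighted median.** Ratios sorted ascending; with normalized
inverse-variance weights, the estimate interpolates the 50% point of the
mid-cumulative weights pⱼ = (Σₖ≤ⱼwₖ − wⱼ/2). Consistent while valid
instruments hold > 50% of the weight. SE by parametric bootstrap
(both coefficients redrawn from normals at their reported SEs; default
1000 replicates, seed-controlled). `n_boot=0` returns the point estimate
alone, which the large Monte-Carlo studies use.

**Weighted mode.** Normal-kernel weighted density of the ratios with
bandwidth h = φ·0.9·min(SD, IQR/1.349)·J^(−1/5) (modified Silverman rule;
φ defaults to 1), evaluated on a 512-point grid spanning the ratios ± 3h;
the grid argmax is refined by bounded golden-section search. Inside the
bootstrap only the grid argmax is used (the refinement is well below the
bootstrap noise floor). If all ratios coincide the bandwidth degenerates
and the common ratio is returned.

**MR-PRESSO.** Global test: observed RSS = Σwⱼ(r̂ⱼ − θ̂₍₋ⱼ₎)², with
θ̂₍₋ⱼ₎ the leave-one-out fixed-effect IVW estimate, referred to a
parametric null in which each outcome coefficient is redrawn from
N(θ̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ) and the statistic recomputed (n_sim = 1000 by default;
+1-smoothed exceedance p). Outlier test: each variant's observed weighted
squared residual against its own simulated distribution, Bonferroni-
adjusted across J, flagged below 0.05. Distortion test: the reference
describes a bootstrap over "expected outliers"; here the null removes
random subsets of the same size as the flagged set (n_sim draws) and
compares the induced shift in the IVW estimate with the observed raw →
corrected shift — a simulated distortion null that needs no auxiliary
classification step. The corrected estimate is IVW on the non-flagged
instruments; with no outliers it *is* the raw estimate and the distortion
p is absent.

**Contamination mixture.** Each ratio is modelled as valid,
N(r̂ⱼ; θ, se(r̂ⱼ)²), or invalid, N(r̂ⱼ; 0, se(r̂ⱼ)² + ψ²); the profile
log-likelihood takes the per-instrument maximum and is evaluated on a
2001-point grid spanning [min r̂ − 2·max se, max r̂ + 2·max se]. ψ defaults
to 1.5 × SD of the ratios. The 95% confidence set is every grid value
within χ²₁(0.95)/2 = 1.9207 log-likelihood units of the maximum, reported
as maximal disjoint segments; endpoints are accurate to one grid step,
which is recorded in the estimate's extras. Because the invalid component
is centred at zero, a cluster of instruments at the null is absorbed by
the contamination component — multi-range confidence sets arise when
instrument clusters support *competing non-null* effects, and the
multi-range tests construct exactly that. The method defines no standard
error; the reported p-value is the χ²₁ likelihood-ratio test of θ = 0,
noted as such in the output.

**Batch runner.** `estimate_all` derives one child seed per method from a
shared seed stream, captures per-method failures without aborting the
panel, and for binary outcomes attaches the odds-ratio transform exp(θ)
with exp-transformed CI endpoints.

## Sensitivity analyses

Leave-one-out re-runs the multiplicative random-effects IVW J times and
flags rows whose omission changes whether the 95% CI crosses the null.
Steiger filtering computes per-trait variance explained from the
t-statistic identity r² = t²/(t² + n − 2) and removes variants with
r²(outcome) ≥ r²(exposure); the tie is removed deliberately — the keep
rule demands strictly more exposure correlation. For binary outcomes the
same identity is applied on the log-odds scale, which is an approximation
(logged as a caveat). Variants lacking a sample size are retained with an
undetermined-direction flag. In the pipeline, Steiger filtering sits
between harmonization and estimation and can be switched off; the choice
of placement keeps every estimator downstream of the same instrument set.
Bidirectional MR runs the full pipeline in both directions, each with its
own selection and harmonization; a direction with no significant
instruments is reported empty rather than failing the run.

## Mediation

For a continuous mediator M on the path from exposure X to a binary
outcome Y, with β_XM the exposure→mediator effect, OR_MY the
mediator→outcome odds ratio and OR_XY the total odds ratio, all odds
ratios are taken to natural-log odds and

    indirect = β_XM · ln OR_MY,    proportion = indirect / ln OR_XY.

Expressing the mediator effect per unit decrease (inverting the OR) while
flipping β_XM's sign is the identical arithmetic. Both the unrounded
proportion and the integer percent are reported. No uncertainty is
propagated — the calculation combines point estimates only.

## Synthetic data generator

`simulate_pair` draws, per variant: maf ~ Uniform(maf_range); true
γⱼ ~ Normal(gamma_dist) truncated below at `gamma_min` for instruments and
0 for background variants; αⱼ = 0 for valid instruments and
~ Normal(mean, sd) for the configured invalid fraction (balanced: mean 0);
Γⱼ = θγⱼ + αⱼ. Traits are standardized (variance 1), giving the
closed-form per-allele standard error 1/√(2·n·maf(1−maf)); observed
coefficients add normal noise at that SE, independently for the two
samples (separate random streams — two-sample independence by
construction). Alleles include a configurable palindromic fraction, and
the outcome file's allele orientation is swapped at random per variant so
harmonization is genuinely exercised. Binary outcomes are simulated
directly on the log-odds scale; the pipeline consumes only summary
statistics, so no individual-level logistic sampling is needed.

Defaults mirror the serum-urate study design: exposure n = 110,347,
outcome n = 94,595, J = 25 instruments, θ = −0.05, γ ~ N(0.08, 0.03)
giving F statistics spanning roughly 35–1400. Named scenarios
(`statistical_27`, `biological_15`, `reverse_85`) strengthen the minimum
instrument effect (true z ≥ ~12) so the expected selection counts —
27 significant / 25 after excluding two high-MAF palindromic variants,
15 inside the six urate-transporter gene regions, 87/85 in the reverse
direction — hold essentially deterministically across seeds.

What the generator does *not* emulate: LD between instruments (simulated
variants are unlinked; clumping tests use hand-constructed LD tables),
sample overlap between the two GWAS, winner's-curse selection bias, and
allele-frequency differences between cohorts. Passing tests therefore
demonstrate correctness of the estimators and the pipeline plumbing under
the stated generative model, not robustness to those real-data features.

## Monte-Carlo study conditions

The calibration and recovery studies (tests and `scripts/acceptance.py`)
use J = 25 instruments at the default sample sizes: 1000 null replicates
for the IVW type-I error, 500 replicates for bias/coverage at θ = 0.1, 400
for the Egger intercept under directional pleiotropy (αⱼ ~ N(0.01, 0.005)
on every instrument), 1000 for intercept-p uniformity under balanced
pleiotropy, and 100 planted-outlier replicates for MR-PRESSO. Two
conditions deserve comment:

* *Directional pleiotropy for the weighted-median study* uses
  αⱼ ~ N(0.0025, 0.025) on 30% of instruments — scatter an order of
  magnitude above the mean. This is the contamination regime the weighted
  median is designed for: invalid instruments deviate on both sides while
  their net (directional) offset biases the IVW mean. With one-sided
  offsets instead, *any* median-type estimator incurs a finite-sample
  quantile shift of order 0.57·se(r̂) that no replicate budget removes, so
  near-unbiasedness of the median is only a property of the scattered
  regime.
* *Balanced pleiotropy for intercept-p uniformity* uses α SD = 0.002,
  i.e. at the outcome sampling-noise scale. With much larger α the 1/σ_Γ²
  weights are misspecified (weighted residual variances become
  heteroscedastic) and the t-reference p-values deviate measurably from
  uniform — a property of MR-Egger itself, not of this implementation.

## Numerical choices and degenerate inputs

Input p-values of exactly 0 are clamped to the smallest positive float
with a warning. Rows with unparseable beta/se are dropped and counted.
Threshold comparisons (p, r², MAF) are strict, matching printed
conventions. The conmix grid step bounds its CI endpoint accuracy; the
weighted-mode refinement is bounded between neighbouring grid points. All
bootstraps and simulations take explicit seeds; `estimate_all` spawns
per-method child streams from one seed, so adding or removing a method
does not perturb the others. Degenerate cases — single instrument (IVW
degrades to the Wald ratio), identical ratios (mode/conmix return the
common value), empty selection (warning, empty result), zero retained
instruments after harmonization (structured error) — are handled
explicitly and tested.

## Known limitations

Correlated instruments (generalized IVW), multivariable MR, MR-Lasso and
MR-RAPS are out of scope. LD clumping consumes a user-supplied pairwise r²
table; the package does not compute LD from genotypes or fetch reference
panels. Steiger filtering on binary traits uses the t-based identity as an
approximation. The mediation calculation propagates no uncertainty. The
contamination-mixture p-value is a likelihood-ratio convenience, not part
of the method's original definition.
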