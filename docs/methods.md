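# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization for a
binary outcome. Each instrument j supplies an observed SNP–exposure effect
β_GP,j (per allele, SD units, SE_GP,j) from the exposure GWAS and an observed
SNP–disease effect β_GD,j (per allele, log odds, SE_GD,j) from an independent
case-control GWAS. Under the instrumental-variable assumptions — the SNP is
associated with the exposure, independent of confounders, and affects the
outcome only through the exposure — and a log-linear exposure–risk
relationship, β_GD,j = β · γ_j where γ_j is the true SNP–exposure effect and
β is the causal log odds ratio per SD of exposure. Horizontal pleiotropy adds
a direct term α_j: β_GD,j = β γ_j + α_j; the estimators differ in what they
assume about the α_j.

- The **likelihood-based estimator** assumes α_j = 0 for all j and models the
  observed pairs as independent bivariate normals with means (ξ_j, β ξ_j) and
  SDs (SE_GP,j, SE_GD,j), zero cross-correlation (two-sample design, no
  participant overlap). The nuisance means are profiled analytically:
  ξ_j*(β) = (β_GP,j/SE_GP,j² + β β_GD,j/SE_GD,j²) / (1/SE_GP,j² + β²/SE_GD,j²),
  leaving a one-dimensional profile log-likelihood in β.
- The **weighted median** is consistent when instruments carrying more than
  half the total weight are valid, whatever the α_j of the rest.
- **MR-Egger** assumes the α_j are independent of the γ_j (InSIDE); its
  intercept estimates the mean directional pleiotropic effect and its slope
  remains a consistent causal estimate under that weaker assumption.
- **IVW** is the α_j = 0 closed form that the likelihood estimator reduces to
  when the exposure effects are measured without error; it serves as the
  optimizer start and reference limit.

## Numerical choices

- Profile-likelihood optimization is bounded scalar minimization bracketed at
  ±max(10·SE_IVW, 0.5) around the IVW start, with up to eight 4× bracket
  widenings before a convergence error (which carries the optimizer trace).
  Absolute x-tolerance 1e-10.
- The likelihood SE is Wald-type from the observed information of the profile
  log-likelihood, central second difference with step 1e-4·max(1, |β̂|). A
  chi-square(1) profile-likelihood CI is available behind
  `ci_method="profile"`; Wald is the default because the package's own
  simulations show the two agree closely at the instrument strengths of
  consortium-scale GWAS, and Wald intervals are what downstream meta-analysis
  consumes.
- Weighted-median weights are the first-order inverse ratio variances
  β_GP,j²/SE_GD,j²; percentile p_j = (cum w − w_j/2)/Σw with linear
  interpolation at 0.5. The SE is a parametric bootstrap (default 1000
  replicates) redrawing both effect columns from their sampling
  distributions; the seed is a required argument — no global RNG state.
- MR-Egger uses weighted least squares with weights 1/SE_GD,j² and a
  multiplicative residual-dispersion factor floored at 1, so an under-dispersed
  fit never reports an SE smaller than the fixed-dispersion value. Slope and
  intercept get normal-reference two-sided p-values; the source GWAS are
  large-sample, so t-references would change nothing material.
- All 95% CIs use z = 1.959964 so that CI→SE reconstruction
  (`se_from_ci`) is the exact inverse of CI construction; I² is truncated at
  zero; heterogeneity P comes from the chi-square upper tail with
  (strata − 1) degrees of freedom.
- Instrument selection prunes greedily by ascending p-value (ties by
  lexicographic SNP id), so output is invariant to input order; SNP pairs
  absent from the LD table are treated as unlinked, matching instrument lists
  from already-pruned published GWAS.
- Palindromic (A/T, C/G) SNPs are replaced by a supplied proxy only when the
  proxy's LD R² exceeds 0.8 and the proxy itself is unambiguous, otherwise
  dropped. Allele-frequency-based strand inference is deliberately not
  attempted: at intermediate frequencies it misassigns strands silently, and
  replace-or-remove is auditable.
- Harmonization orients every pair to the trait-increasing allele
  (β_GP ≥ 0), which MR-Egger requires for its intercept to be interpretable;
  irreconcilable allele sets (e.g. A/G vs C/T) yield a logged drop rather
  than a guess, since strand flips cannot be distinguished from genuine
  mismatches without frequencies.
- SD-unit recalibration divides by the sample-size-weighted mean of the
  per-study SDs, Σ nᵢSDᵢ / Σ nᵢ; the per-study SDs and sizes are explicit
  inputs because published tables rarely print them in one place.
- `min_detectable_or` inverts the power formula by Brent root-finding on
  OR ∈ (1, 10], where power is strictly monotone.

## Power formula

For N = cases + controls with case fraction K, instrument R², true OR per SD,
the causal z-test has non-centrality √(N·R²·K(1−K))·|ln OR|, giving two-sided
power Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂). Both tails are kept: the second term is
negligible away from the null but makes power(OR = 1) = α exact and preserves
power(OR) = power(1/OR). This normal approximation ignores weak-instrument
bias and winner's curse; published power figures computed with other
calculators or effective sample sizes can differ by several points, so the
package validates its formula by property (null level, symmetry,
monotonicity) and against a direct simulation of score-test rejections under
the generative model (agreement within Monte-Carlo error at multiple design
points) rather than against any particular printed percentage.

## Synthetic-data generator

`simulate_two_sample` emulates the two-sample summary-statistics regime
directly, without individual-level genotypes: allele frequencies f_j ~
Uniform(maf_range); true effects γ_j from folded normals rescaled so the
realized variance explained Σ 2f_j(1−f_j)γ_j² equals `r2_target` exactly;
analytic standard errors SE_GP,j = 1/√(2f_j(1−f_j)·n_exposure) and SE_GD,j =
1/√(2f_j(1−f_j)·N·K(1−K)); observed effects drawn independently around γ_j
and β γ_j + α_j. Pleiotropy modes: none, balanced (mean-zero α on an
`invalid_fraction` of SNPs), directional (nonzero mean). Optional per-stratum
outcome studies with their own sample sizes and, for heterogeneity studies,
stratum-specific causal effects; optional palindromic-allele assignment and
cyclic pathway labels. Everything flows from one seed and reruns are
byte-identical.

Defaults are a BMI-scale study: J = 96 instruments, R² = 2.7%, true OR 1.34
per SD, outcome sample 7110 cases / 7264 controls. The exposure GWAS size
defaults to 300,000 — the scale of the anthropometric consortium
meta-analyses that discover such instruments — making exposure-side
measurement error realistically small but nonzero. MAFs default to
Uniform(0.05, 0.5), the range where genome-wide-significant instruments
typically live.

What the generator does not emulate — and hence what passing tests do not
establish about real data: LD between instruments (draws are independent),
winner's-curse inflation of discovery effect sizes, sample overlap between
the two GWAS, population stratification, and non-collapsibility subtleties of
odds ratios at high disease prevalence. Simulated instruments are uniformly
"honest"; real instrument sets fail in ways the curation stages can only
partially detect.

Test and benchmark problem sizes (dozens of SNPs, a few hundred replicates,
bootstrap counts of 50–200 inside replicated loops) are chosen to keep the
default suite fast on a laptop while leaving Monte-Carlo error comfortably
inside the asserted tolerances; the API defaults (n_boot = 1000) are what an
analysis of real data should use.

## Pipeline conventions

The overall causal estimate pools the per-stratum β_GD per SNP by
fixed-effect inverse-variance meta-analysis *before* MR (the convention of
consortium GWAS that publish METAL-combined summary statistics); running MR
per stratum and pooling the causal estimates afterwards is equally available
via `stratified_mr`, and stratum heterogeneity (Q, I²) is computed from
per-stratum MR estimates. Funnel "instrument strength" is β_GP/SE_GD by
default with β_GD/SE_GP as an option (`strength_definition`), since both
definitions circulate in the literature. The Bonferroni threshold for
pathway-subset tests divides α by the total subset count across *all* traits
in the analysis — an explicit input, never inferred from one trait's labels —
because per-trait correction would understate the multiplicity actually
incurred. Headline per-trait p-values stay uncorrected, matching standard
reporting practice. The multi-command CLI (`simulate`, `harmonize`, `mr`,
`meta`, `power`, `pathways`, `funnel`, `run-all`) is a thin layer over the
library; the JSON-lines run log contains no timestamps so reruns are
bit-identical.

## Known limitations

Correlated-instrument (generalized) IVW, multivariable MR, mode-based
estimators, and outlier-removal schemes are out of scope. The weighted-median
bootstrap SE is approximate in small instrument sets (J near 3). The
likelihood estimator's Wald SE can understate uncertainty when instruments
are collectively weak; the profile CI option is the remedy. Power
calculations assume no sample overlap and no weak-instrument attenuation.
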