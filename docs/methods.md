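# Methods

This note documents the statistical model behind `mr2s`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Model and assumptions

The package estimates the causal effect θ (log odds ratio of colorectal
cancer per SD of circulating resistin) from two independent GWAS summary
datasets. For each instrument *j* the exposure association β̂ⱼ ~ N(βⱼ, σₓⱼ²)
and the outcome association Γ̂ⱼ ~ N(Γⱼ, σⱼ²) are observed; under the
instrumental-variable assumptions (relevance, exchangeability, exclusion
restriction) Γⱼ = θ·βⱼ. The estimators relax exclusion in different ways:

- **IVW** assumes all instruments valid, or at worst balanced pleiotropy
  with mean zero. It is the weighted regression of Γ̂ on β̂ through the
  origin with weights 1/σⱼ².
- **MR-Egger** allows directional pleiotropy αⱼ with nonzero mean provided
  InSIDE holds (αⱼ uncorrelated with βⱼ); the intercept estimates the mean
  pleiotropic effect and the slope is the pleiotropy-adjusted θ.
- **Median** estimators are consistent when at least half the weight is on
  valid instruments; the **weighted mode** when the largest group of
  instruments sharing one ratio value is valid.
- **Correlated-instrument IVW** generalizes IVW to instruments in linkage
  disequilibrium via GLS with Ω = diag(σ)·P·diag(σ), P the signed LD
  correlation matrix. It exists for the "partially independent cis" set
  retained by LD clumping (r² ≤ 0.1 within ±100 kb of the gene), where
  residual correlation cannot be ignored.

Two-sample independence (no overlapping participants) is assumed
throughout; overlap would bias estimates toward the null-confounded
association rather than the causal one.

## Numerical and inferential choices

- **Multiplicative random effects.** For IVW and Egger the fixed-effect SE
  is scaled by √φ with φ = max(1, Q/df): overdispersion inflates the SE,
  but the SE is never deflated below the fixed-effect value. This is the
  standard construction in the reference MR implementations. A consequence,
  verified by simulation here, is mild conservatism of the IVW test when
  heterogeneity is truly absent (the truncation at 1 only ever inflates);
  under genuine balanced pleiotropy the truncation rarely binds and the
  type-I error is nominal.
- **P-values** use the normal reference for all methods. For Egger a
  t-reference with J−2 degrees of freedom is exposed as an option
  (`p_reference="t"`), since reference implementations differ and neither
  convention is canonical.
- **Egger orientation.** Pairs with β̂ⱼ < 0 are negated before fitting so
  every exposure effect is non-negative; the slope is invariant and the
  intercept is sign-normalized by construction.
- **Median interpolation.** The weighted median interpolates the ratio
  estimates θⱼ (sorted ascending) at cumulative weight midpoints
  sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2, evaluated at s = 1/2; weights are the first-order
  inverse ratio variances βⱼ²/σⱼ², normalized. The simple median uses equal
  weights.
- **Mode bandwidth.** Gaussian kernel with modified Silverman bandwidth
  h = φ_bw·0.9·min(sd, IQR/1.349)·J^(−1/5), φ_bw = 1 by default. The
  argmax is located on a 512-point grid spanning mean ± 4 sd of the ratios
  and refined by bounded scalar minimization (xatol 1e-10). If all ratios
  coincide the common value is returned with a warning.
- **Bootstrap SEs** for median and mode are parametric: β̂ⱼ* and Γ̂ⱼ* are
  redrawn from normals centred at the observed values with their reported
  SEs, the point estimator is recomputed, and the SE is the SD over
  n_boot = 10,000 resamples (weights recomputed from the resampled β̂ⱼ*).
  Inside the bootstrap the mode skips golden-section refinement (256-point
  grid only) for speed; the refinement affects the fourth decimal of a
  single evaluation and is negligible against bootstrap noise. All
  bootstraps take an explicit seed.
- **Sidik–Jonkman τ²** is initialized at the unweighted variance
  τ₀² = mean((βₛ−β̄)²) and takes one reweighting step with
  vₛ = σₛ²/τ₀² + 1; all-equal inputs short-circuit to τ² = 0. The
  implementation was cross-checked against an independent R meta-analysis
  package (values frozen in the test suite). DerSimonian–Laird is available
  as an alternative.
- **Harmonization.** Outcome records are aligned by direct allele match,
  allele swap (sign flip, EAF complement), or strand complement
  (non-palindromic variants only). Palindromic variants with exposure MAF
  above 0.42 are excluded as strand-ambiguous; below the threshold they are
  oriented by matching minor-allele identity between datasets. The 0.42
  cutoff is the conventional one and excludes the study's MAF-0.48
  ambiguous variant; it is configurable. Proxy lookup requires r² ≥ 0.80
  (inclusive, so the study's r² = 0.80–0.82 proxy qualifies) within
  ±500 kb, highest r² first, ties broken by distance then rsid.
- **Clumping** retains candidates greedily in ascending p-value order
  subject to pairwise r² ≤ 0.1 and spacing ≥ 100 bp. The source protocol
  also mentions an upper spacing bound, which is not interpretable as a
  pairwise constraint for more than two variants and is not implemented.
- **Per-variant F** uses k = 1 and each variant's own sample size; the
  reported "mean F" is the arithmetic mean of per-variant values. The
  published per-variant F column itself is not reproducible from the stated
  formula with the printed inputs (e.g. 51.3 by formula vs 41.7 printed for
  one variant); the package always computes from the formulas and keeps the
  printed columns in the fixture for reference only.
- **Power** uses the closed-form non-centrality approximation
  b = (z₁₋α/₂ + z_pow)/√(N·R²·k(1−k)); the minimum detectable OR is its
  exact inversion, and the two directions are verified against each other
  to 1e-9.

## The instrument fixture

The packaged table carries the 15 published resistin pQTLs. The 13 analysis
rows are reproduced cell-for-cell from the published instrument table
(GRCh37 positions, effect/reference alleles, EAF, per-SD effects, SEs,
p-values, per-variant N between 15,136 and 21,749). The two excluded
variants have no published summary statistics beyond the palindromic
variant's MAF of 0.48; their remaining numeric fields are synthetic
placeholders, flagged in the fixture's `note` column, present only so that
the 15 → 13 exclusion accounting is executable. They never enter an
analysis.

## What the synthetic generator emulates

`generate_two_sample` draws true exposure effects βⱼ ~ N(0.08, 0.03²)
(signed at random unless `signed_effects=False`), optionally overriding the
first variant with a large-effect low-frequency cis variant (β = 1.10,
EAF 0.017, patterned on the dominant promoter variant); EAFs uniform over
the MAF range with random effect-allele assignment; pleiotropy
αⱼ ~ N(μ_α, σ_α²), optionally correlated with instrument strength to
violate InSIDE; Γⱼ = θβⱼ + αⱼ; and observation noise at the GWAS-asymptotic
level, σₓⱼ = 1/√(2nₓ·EAF(1−EAF)) for the standardized continuous exposure
and σⱼ = 1/√(2ñ·EAF(1−EAF)) with effective sample size
ñ = n_cases·n_controls/(n_cases+n_controls) for the binary outcome.
Optional wrinkles: a palindromic A/T variant at MAF > 0.42, a variant
missing from the outcome set with an LD proxy at r² ≥ 0.8, and an AR(1)
cis block whose effect-estimate noise is correlated accordingly. All
randomness flows from one seed through `SeedSequence` spawning.

`replicate_study_shape` wraps the real exposure fixture with synthetic
outcome datasets in the two real sample shapes — consortium-like
(58,131 cases / 67,347 controls, case:control 0.86) and biobank-like
(total 250,399, case:control 0.0198, the shape used in the power
computation) — plus subgroup datasets with the real availability pattern
(subsite-beyond-colon/rectal and sex strata only in the consortium-shaped
bundle). Subgroup sample sizes are scaled to 40–50% of the parent dataset,
roughly matching subsite case fractions.

What it does **not** emulate: genome-wide LD beyond the declared block,
allele-frequency differences between exposure and outcome populations,
imputation-quality variation, winner's-curse in instrument selection, and
case-control EAF distortion under strong effects. Passing calibration
tests therefore demonstrates correctness of the estimators under the
stated generative model, not robustness to those additional real-data
features.

## Calibration experiments (desk scale)

The test suite runs three seeded Monte-Carlo experiments at the study's
shape (J = 13 including the large cis variant, consortium-sized samples):

- **Type-I error**: θ = 0 with balanced pleiotropy σ_α = 0.01 log-odds
  (the order of the per-variant outcome SE), 1000 replicates; the IVW
  rejection rate at α = 0.05 must lie within the two-sigma binomial band.
- **Recovery**: θ = 0.1, 500 replicates; the mean IVW estimate must match
  θ within Monte-Carlo error plus an attenuation allowance of θ/100 — with
  mean instrument F ≈ 100, regression dilution of order 1/F ≈ 1% is an
  expected property of IVW, not an implementation defect.
- **Directional pleiotropy**: μ_α = 0.02 with InSIDE holding and a large
  exposure GWAS (n = 2·10⁶, isolating the asymptotic property from
  dilution), 500 replicates; the Egger slope must be centred on θ while
  the IVW bias must equal the weighted-leverage prediction
  μ_α·Σwβ/Σwβ² (≈ μ_α/mean β).

Problem sizes (13 instruments, 500–1000 replicates, 10,000 bootstrap
resamples by default and 50–1000 in tests) keep the full suite in the
tens of seconds while leaving Monte-Carlo error well below the tested
tolerances.

## Limitations

- The headline causal estimates of the source study can only be reproduced
  with its supplementary per-variant outcome tables, which are consortium
  data and not packaged; the reproduction test activates when the user
  supplies them (`tests/data/external/outcome_{gecco,finngen}.tsv`).
- Proxy allele orientation relies on the LD table's allele mapping; when it
  is absent, frequency matching is the fallback and ambiguous cases are
  logged rather than silently aligned.
- No multiple-testing adjustment is applied across methods or subgroups,
  matching the source analysis; p-values are reported unadjusted and
  should be read accordingly.
- MR-PRESSO-style outlier correction, multivariable MR and Steiger
  filtering are out of scope.
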