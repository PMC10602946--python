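# mr2s — two-sample Mendelian randomization for summary statistics

`mr2s` implements a complete two-sample Mendelian randomization (MR)
workflow over GWAS summary statistics, built around the question of whether
genetically determined circulating **resistin** concentrations affect
**colorectal cancer** risk. It is aimed at genetic epidemiologists who want
a scriptable, fully tested pipeline: allele harmonization with LD-proxy
rescue, instrument diagnostics and power, the standard MR estimator battery
with sensitivity analyses, and meta-analytic pooling across outcome
datasets. A synthetic-data generator with known ground truth makes every
stage testable without access to consortium data.

## The model

Each genetic instrument *j* carries an exposure association β̂*ⱼ* (SD units
of resistin per effect allele, with SE σ*ₓⱼ*) and an outcome association
Γ̂*ⱼ* (log odds of colorectal cancer, with SE σ*ⱼ*). Under the instrumental
variable assumptions the causal log odds ratio per SD of exposure, θ,
satisfies Γ*ⱼ* = θ·β*ⱼ*, and the estimators are:

- **Wald ratio** (single instrument): θ̂*ⱼ* = Γ̂*ⱼ*/β̂*ⱼ*, SE σ*ⱼ*/|β̂*ⱼ*|.
- **IVW**: weighted regression of Γ̂ on β̂ through the origin with weights
  1/σ*ⱼ*²; multiplicative random effects scale the SE by √max(1, Q/(J−1)),
  where Q is Cochran's heterogeneity statistic and I² = max(0,(Q−df)/Q)·100.
- **Correlated-instrument IVW**: generalized least squares with
  Ω*ᵢⱼ* = σ*ᵢ*σ*ⱼ*ρ*ᵢⱼ* from a signed LD correlation matrix, for
  "partially independent" cis instruments retained by LD clumping
  (r² ≤ 0.1 within ±100 kb of the gene).
- **MR-Egger**: the same regression with a free intercept after orienting
  all β̂*ⱼ* ≥ 0; the intercept estimates average directional pleiotropy.
- **Simple/weighted median** and **weighted mode** (kernel-density argmax
  of the ratio estimates), with parametric-bootstrap SEs.

Instrument strength uses R²*ⱼ* = 2β̂*ⱼ*²·EAF*ⱼ*(1−EAF*ⱼ*) and
F = ((N−K−1)/K)·R²/(1−R²); variants with F < 10 are flagged weak. Power for
a binary outcome follows the non-centrality approximation
b = (z₁₋α/₂ + z_pow)/√(N·R²·k(1−k)) with case fraction k, giving the
minimum detectable OR exp(b). Per-dataset estimates are pooled by
inverse-variance random-effects meta-analysis with the **Sidik–Jonkman**
τ² estimator.

The package ships the published 15-variant SCALLOP resistin pQTL instrument
table as a fixture (13 analysis variants after excluding one variant absent
from both outcome datasets and one strand-ambiguous palindromic variant).

## Worked example

```python
import mr2s

# instrument diagnostics on the packaged pQTL fixture
d = mr2s.diagnose(mr2s.load_resistin_instruments(analysis_only=True))
print(f"K = {d.k_instruments}, total R2 = {d.total_r2:.4f}, mean F = {d.mean_f:.1f}")
# K = 13, total R2 = 0.0788, mean F = 104.2

# minimum detectable ORs for the two outcome sample shapes
print(round(mr2s.minimum_detectable_or(125_478, 0.86, 0.078), 2),
      round(mr2s.minimum_detectable_or(250_399, 0.0198, 0.078), 2))
# 1.06 1.16

# a full synthetic study under the null
bundle = mr2s.replicate_study_shape(theta=0.0, seed=3)
report = mr2s.run_study(mr2s.StudyConfig(output_dir="report", n_boot=1000),
                        exposure=bundle.exposure, outcomes=bundle.outcomes,
                        ld=bundle.ld, subgroup_outcomes=bundle.subgroup_outcomes)
print(report["pooled"][["instrument_set", "or", "ci_low", "ci_high"]].round(3))
#   instrument_set     or  ci_low  ci_high
# 0            all  1.024   0.967    1.085
# 1            cis  1.037   0.955    1.126
# 2          trans  1.008   0.937    1.086
```

The 13 instruments explain 7.9% of the variance in circulating resistin
with mean F ≈ 104 (no weak instruments); at 80% power the two outcome
sample shapes can detect ORs per SD of 1.06 and 1.16. In the synthetic
null study the pooled IVW confidence intervals cover OR = 1, and the
harmonization log reproduces the 15 → 13 instrument accounting (one
variant missing with no proxy, one palindromic exclusion, one proxy
substitution at r² = 0.82).

The same workflow is available from the shell:

```bash
mr2s diagnose
mr2s power --n-total 125478 --case-control-ratio 0.86 --r2 0.078
mr2s estimate --outcome outcome.tsv --methods ivw,egger
mr2s run --config study.yaml
```

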