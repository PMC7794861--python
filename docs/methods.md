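# Methods

## The problem

Observational epidemiology repeatedly finds higher body-mass index (BMI)
among people with atopic dermatitis (AD), but association alone cannot say
whether adiposity raises AD risk, whether skin disease changes weight, or
whether shared confounders (lifestyle, socio-economic factors) drive both.
`ivmr` implements the bidirectional Mendelian-randomization (MR) design
used to separate these explanations: genetic variants associated with a
trait are fixed at conception, so they are immune to classical confounding
and to reverse causation, and can serve as instrumental variables for the
trait.

The package provides the full analysis chain — simulation of cohorts with a
known causal structure, instrument construction and diagnostics, one- and
two-sample MR estimators with sensitivity statistics, scale transforms, and
meta-analytic combination — and characterises its operating behaviour by
replicate simulation rather than by any single data set.

## Generative model

A cohort of n individuals carries J independent biallelic SNPs,
g_ij ~ Binomial(2, maf_j) (Hardy–Weinberg, no linkage disequilibrium:
instruments in practice are index SNPs from distinct loci).  With a latent
confounder U ~ N(0,1):

    X0_i = μ_X + Σ_j γ_j g_ij + c_x U_i + ε_i,   ε ~ N(0, σ²)
    Y_i  ~ Bernoulli( expit( b0 + β X0_i + c_y U_i + Σ_j α_j g_ij ) )
    X_i  = X0_i + ρ Y_i

* γ_j — per-allele effects on the continuous exposure (kg/m² per allele);
* β — the causal log-odds of outcome per exposure unit (the estimand);
* α_j — direct per-allele log-odds on the outcome.  On instrument SNPs this
  is horizontal pleiotropy (an exclusion-restriction violation); on a
  separate block of outcome-trait SNPs it is those SNPs' legitimate effect,
  and that block is what the reverse direction instruments;
* ρ — reverse causation: an additive exposure shift in cases, applied after
  the outcome draw;
* c_x, c_y — the confounder's two arms.

With α ≡ 0 on the instruments and ρ = 0 the instrumental-variable
assumptions hold by construction.

## Scenario presets

Presets are flat YAML files; each expands deterministically from a seed.
Shared choices, picked once to resemble an adult population cohort:
exposure mean 25 kg/m² and total SD 4.5 kg/m² (BMI-like); outcome baseline
prevalence 5% (adult AD sits in the 2–10% range); minor-allele frequencies
uniform on (0.05, 0.45); 100 exposure-instrument SNPs plus 24 outcome-trait
SNPs (the published AD GWAS count in Europeans); confounder arms of
1 kg/m² and 0.4 log-odds per SD where confounding is on.

Per-SNP exposure effects receive heterogeneous variance shares
(exponential, normalised).  This matches real GWAS architecture (a few
large loci, a long tail) and is what identifies the MR-Egger intercept: a
design-time power calculation showed that with equal shares every
instrument carries the same precision-weighted leverage (w_jγ_j² constant)
and the intercept SE roughly triples, leaving the Egger test nearly
powerless even under gross pleiotropy.

| preset | causal OR/unit | confounding | instrument pleiotropy | reverse ρ | h² (instruments) | n |
|---|---|---|---|---|---|---|
| null | 1.00 | off | none | 0 | 2% | 20,000 |
| forward_causal | 1.05 | on | none | 0 | 2% | 20,000 |
| confounded_null | 1.00 | strong (c_y = 0.6) | none | 0 | 2% | 20,000 |
| directional_pleiotropy | 1.05 | on | +0.05 log-odds/allele, all SNPs | 0 | 10% | 20,000 |
| balanced_pleiotropy | 1.05 | on | N(0, 0.05²) | 0 | 10% | 20,000 |
| reverse_causal | 1.00 | on | none | +1 kg/m² | 2% | 20,000 |

The forward-causal conditions (true OR 1.05 per kg/m², 100 instruments
explaining 2% of exposure variance, 20,000 per cohort) define the package's
recovery study.  The pleiotropy presets use strong instruments (10% of
exposure variance, per-SNP F ≈ 20) because the Egger intercept test is a
strong-instrument diagnostic; at 2% shared variance each SNP's F ≈ 5 and
no pleiotropy test has useful power.

## Estimators

Two-sample, from harmonized per-SNP pairs (γ̂_j, Γ̂_j):

* **Wald ratio** Γ̂/γ̂, SE σ_Γ/|γ̂| (first order) or with the
  + Γ̂²σ_γ²/γ̂⁴ term (second order).
* **IVW** β̂ = Σw γ̂Γ̂ / Σw γ̂², w = 1/σ_Γ²; fixed SE √(1/Σwγ̂²);
  the multiplicative-random option inflates by √max(1, Q/(J−1)).
  Weights use outcome-side SEs only (the usual first-order convention);
  the second-order ratio SE is available where exposure-side uncertainty
  matters.
* **MR-Egger** — the same weighted regression with a free intercept, γ̂
  oriented positive; coefficient SEs carry max(1, RSS_w/(J−2)).
* **Weighted median** — ratio order statistics interpolated at cumulative
  normalised weight 0.5 (centred convention; ties resolved by linear
  interpolation), SE by parametric bootstrap (default ≥1000 draws, seeded).
* **Cochran's Q** on the ratios with weights γ̂²/σ_Γ²; df = J − 1.

One-sample, with a genetic risk score (GRS) as the single instrument:

* continuous outcome — 2SLS with the proper IV sandwich (stage-2 residuals
  from the observed exposure);
* binary outcome — logistic reduced form over linear first stage,
  Γ̂_score/γ̂_score, delta-method SE (both stages' uncertainties, treated
  as independent; a nonparametric bootstrap SE is available as a check);
* binary exposure (the reverse direction) — logistic first stage, linear
  reduced form, giving outcome units per unit exposure log-odds.

Binary-trait effects stay on the log-odds scale internally; odds ratios and
the per-doubling-of-odds scale (multiply by ln 2) are reporting transforms
recorded in the estimate's `scale` field.

Meta-analysis: fixed-effect inverse-variance pooling combines the one- and
two-sample arms of each direction (the default; the choice between fixed
and random combination of two arms is underdetermined, and random-effects
is available).  DerSimonian–Laird random-effects pooling, with Q, I², τ²,
serves observational per-study OR tables, where real heterogeneity is
expected; study SEs are reconstructed from CI widths as
(ln CI_hi − ln CI_lo)/(2·1.96).

## Pipeline layout

Simulation mode draws three cohorts per run, mirroring a biobank +
published-GWAS design: the biobank gives individual-level data for
one-sample MR; an exposure-GWAS cohort supplies the per-SNP exposure
effects used both as GRS weights and as the two-sample exposure side; an
outcome-GWAS cohort supplies the outcome side.  External GRS weights
matter: weights estimated in the analysis cohort itself suffer the
many-weak-instrument overfitting bias (order J/(nR²) ≈ 25% toward the
confounded estimate at the recovery-study conditions).  An
`overlap_fraction` knob shares individuals between the biobank and the
outcome GWAS to reproduce the null-ward sample-overlap bias.

The reverse direction swaps trait roles (AD-block SNPs as instruments,
logistic exposure side) and reports per doubling of odds.  Observational
analyses fit logistic outcome-on-exposure models within half-open exposure
strata (default [25,30) and [30,∞) kg/m²; strata with <10 cases skipped).

## Numerical choices

* Per-SNP GWAS scans are vectorised: the univariate logistic likelihood
  depends only on per-genotype-class totals and case counts, so each SNP
  is an exact 3-support-point Newton problem; equivalence with statsmodels
  is asserted in tests.  Monomorphic or non-converged SNPs are flagged with
  missing SEs, never silently dropped.
* Harmonization default is strict exclusion of palindromic SNPs (A/T, C/G);
  the `eaf-infer` option keeps them only when both allele frequencies fall
  clearly on the same side (<0.42 or >0.58).  No strand complementing is
  attempted; irreconcilable allele pairs are logged as mismatches.
* All randomness flows through numpy `SeedSequence` children of one run
  seed; identical runs are byte-identical, including bootstrap stages
  (report tables use a fixed float format).
* Weak-instrument F threshold 10 is reported, not enforced.
* CIs use the exact normal 0.975 quantile; p-values are two-sided normal.
  τ² truncates at 0, I² at 0, the Egger/IVW residual inflation floors at 1.

## Replicate studies and their scales

`ivmr.replication` (driven by `scripts/acceptance.py`) measures: forward
recovery and CI coverage (200 replicates of forward_causal), IVW type-I
error and the Q distribution (1000 replicates of null), the
confounding contrast (150 replicates of confounded_null), the reverse-
direction null (the same 200 forward_causal replicates), and Egger
intercept behaviour (200 replicates of each pleiotropy preset).  These
sizes give Monte-Carlo SEs of ~0.003 on mean estimates and ~0.7–1.5
percentage points on rates, small enough to detect meaningful
miscalibration while keeping a full run in the tens of minutes on one
core.

## What the simulations do and do not show

At the recovery-study conditions each instrument is individually weak
(per-SNP F ≈ 5), so the two-sample arm carries finite-sample regression
dilution of roughly Σwγ²/(Σwγ² + Σw·σ_γ²) ≈ 0.8–0.9 toward the null
(direction-of-null, as expected for non-overlapping samples); the combined
estimate inherits about half of it.  The recovery and coverage studies
measure the estimators as used, dilution included.

The generator omits linkage disequilibrium, population stratification,
relatedness, genotyping error, selection into the cohort, and phenotype
misclassification.  Passing recovery and calibration studies therefore
demonstrate the estimators' correctness under the stated causal diagrams —
not robustness to those real-data complications.  The confounder is a
single Gaussian; real confounding is a mixture whose arms need not be
linear.  Reverse causation as a constant case shift is the simplest
mechanism producing a reverse-direction signal; the per-doubling estimand
it implies (ρ·p(1−p)·ln 2, via the marginal case-probability shift per
allele) is attenuated relative to ρ itself.
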