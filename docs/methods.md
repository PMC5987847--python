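# Methods

`edumr` implements a bidirectional Mendelian-randomisation (MR) analysis
of years in full-time education and refractive error, together with a
synthetic biobank-style cohort generator that provides the statistical
structure the analysis assumes. This note records the models, the
defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic experiments demonstrate.

## The causal question and the estimators

Education (EDU, years) and refractive error (mean spherical equivalent,
MSE, dioptres; negative = myopic) are observationally associated.
MR asks whether the association is causal and in which direction, using
allele scores as instruments: a weighted sum of effect-allele dosages

    S_j = Σ_i w_i d_ij,        d_ij = 2·P(aa) + P(Aa) ∈ [0, 2],

with weights from an external discovery GWAS. Under the instrumental-
variable assumptions (the score is associated with the exposure,
independent of confounders, and affects the outcome only through the
exposure), two-stage least squares (2SLS) on the one-sample cohort
estimates the causal effect. The bidirectional analysis runs 2SLS twice:
education score → EDU → MSE, and myopia score → MSE → EDU. All
regressions adjust for age and sex by default (extended covariate sets
are accepted for sensitivity runs).

Reported 2SLS standard errors use stage-2 residuals evaluated at the
*observed* exposure (the standard 2SLS variance), homoskedastic by
default with an HC0 sandwich option. Confidence intervals and p-values
use the normal reference — a deliberate large-n convention, documented
because a t reference is equally defensible at small n.

Endogeneity is tested with the Durbin–Wu–Hausman test in
control-function form: the outcome is regressed on exposure, covariates
and the first-stage residual, and the squared t statistic of the
residual term is referred to F(1, df). A perfect fit (OLS and IV
coincide exactly) is reported as statistic 0 rather than 0/0.

### Summary-statistic sensitivity estimators

Because MR-Egger is not valid when the variant–exposure and
variant–outcome associations come from the same participants, the
pleiotropy-robust estimators operate on split-sample summary statistics:
the cohort is divided into random halves A and B, exposure associations
are computed per variant in one half and outcome associations in the
other (and the halves swap roles for the reverse direction), so no
participant contributes to both sides of either fit.

* **Wald ratio**: β_ZY/β_ZX with first-order delta SE se_ZY/|β_ZX|.
* **IVW**: weighted regression of β_ZY on β_ZX through the origin,
  weights 1/se_ZY²; fixed-effect SE, no over-dispersion scaling
  (exactly the Wald ratio for one variant).
* **MR-Egger**: the same regression with an intercept, after orienting
  every variant so β_ZX ≥ 0 (without a fixed orientation the intercept
  has no direction). The intercept estimates directional pleiotropy;
  SEs are multiplied by max(1, √(RSS_w/(L−2))) and p-values use
  t(L−2). Constraining the intercept to zero reproduces IVW.
* **Weighted median**: Wald ratios ordered, inverse-variance weights
  normalised; the estimate interpolates the ratio at which the mid-point
  cumulative weight (cum − w/2) crosses 0.5. Consistent when valid
  instruments carry ≥ 50% of the weight.
* **Weighted mode**: argmax on a fine grid (4096 points) of a
  normal-kernel weighted density of the ratios; bandwidth =
  bandwidth_factor × 0.9·min(SD, MAD)·L^(−1/5) (modified Silverman
  rule, MAD normal-consistent). Consistent when the largest group of
  variants sharing one ratio is valid.

Weighted-median and mode SEs come from a seeded parametric bootstrap
(per-variant betas resampled from their normal sampling distributions;
default 1000 draws).

**A structural caveat the synthetic experiments make visible.** With L
variants of combined first-stage R² and half-samples of size n_A, the
exposure associations carry estimation noise that attenuates the
split-sample IVW slope by roughly 1/(1 + L/(n_A·R²)). At this
analysis's own scale (69 variants, R² ≈ 0.007, n_A ≈ 30 000) that factor
is ≈ 0.7, so the split-sample estimators are conservative in magnitude
relative to the one-sample 2SLS; Egger's slope is hit hardest. This is a
property of the split-sample design itself, not of the implementation —
the estimators recover the truth exactly when given precise summary
statistics, which the test suite checks separately.

## Power

Statistical power for continuous-outcome MR uses the non-centrality
parameter of the IV test,

    NCP = n · R²_XZ · (β · σ_X/σ_Y)²,
    power = P(|Z + √NCP| > z_{1−α/2}),

so power(β = 0) = α exactly. The minimal detectable effect inverts this
by bisection (Brent, 1e-8 relative tolerance). Trait SDs default to 1
(standardised effects) with explicit overrides; the cohort generator's
conventions (below) are used when reporting effects in natural units.

## Confounding diagnostics

The confounder scan regresses each candidate covariate on the allele
scores, the exposure and the outcome (slope and p each). Bias components
compare, per covariate c, the standardised bias of the two estimators:

    bias_OLS = r_cx·r_cy,      bias_IV = (r_cz/r_zx)·r_cy,

in SD units of outcome per SD of exposure. A covariate uncorrelated with
the instrument contributes no IV bias however strongly it confounds the
observational estimate; the definition is fixed here because the source
methodology is cited rather than printed in the literature this package
emulates.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which everything downstream is exercised.

**Genotypes.** Biallelic variants in Hardy–Weinberg equilibrium, allele
frequencies uniform on `maf_range` (default 0.05–0.5), no linkage
disequilibrium (the emulated instruments are independent genome-wide
hits). Hard calls are degenerate probability triples; an optional
`imputation_noise` mixes triples toward the population genotype
distribution. Panels default to 69 education and 44 myopia variants.

**Structural model** (centred form; U ~ N(0,1) is a latent confounder):

    EDU* = Σ w_i(d_i − 2p_i) + a_E(age−55) + c_E·U + ε_E
    EDUyears = code(EDU*)                     (degree→21, floor 15)
    MSE* = β_EM(EDUyears − μ_E) + Σ w_k(d_k − 2p_k) + Σ δ_i(d_i − 2p_i)
           + a_M(age−55) + c_M·U + ε_M

Per-variant effects w are drawn normal and rescaled jointly so each
allele score explains its configured variance fraction in expectation
(defaults 0.0071 for education, 0.0432 for MSE — the instrument
strengths of the emulated study); residual variances are solved so the
marginal trait variances hit the configured SDs. The reverse scenario
swaps the roles symmetrically; if both causal effects are nonzero the
linear system is solved in reduced form on the latents and flagged
`simultaneous` in the returned truth.

Two generator choices deserve explanation:

* **The causal effect acts on the *coded* years of education.** The
  analysis variable is the questionnaire coding (degree holders 21,
  completion ages floored at 15), and that coded quantity — not a
  continuous latent — is the real-world exposure "years spent in
  education". Had the effect been placed on the latent, the 2SLS
  estimand on the coded variable would be β divided by the coding's
  damping factor (~0.9), i.e. the generator would not mean what its
  configuration says. The continuous latent serves only to generate the
  questionnaire response. A side effect is that the coded variable's
  variance (≈ 5.2 y²) is smaller than the latent's (6.25), and the
  score's R² on the coded variable is ~8% below the configured value —
  a realistic questionnaire-measurement attenuation, inside the
  generator's ±20% calibration contract.
* **Confounder calibration.** Trait SDs are not published for the
  emulated cohort; the defaults SD_EDU = 2.5 y, SD_MSE = 2.7 D are
  config-exposed conventions. The confounder paths default to
  c_E = 1.0 y/SD (fixed a priori) and c_M = 0.51 D/SD, the latter
  calibrated by measuring the linear response of the covariate-adjusted
  observational slope so that OLS attenuates to ≈ −0.18 D/y while the
  causal effect is −0.27 D/y — the headline observational-vs-causal
  contrast that defines the scenario. One latent confounder cannot match
  both directions' observational slopes simultaneously under the coded
  education variance; the forward direction is prioritised and the
  reverse observational slope comes out ≈ −0.10 y/D rather than −0.15.

**Pleiotropy.** `pleiotropy_mode` plants per-variant direct effects δ on
the outcome for the instrument variants of the active causal direction:
`balanced` draws them zero-mean normal (InSIDE holds, IVW unbiased),
`directional` draws half-normal so all share one sign (biasing IVW,
detectable by the Egger intercept). `pleiotropy_sd` is in dioptres per
allele.

**Measurement layer.** Refractive error is observed only through
repeated per-eye autorefraction readings: each eye's true MSE is the
participant's latent MSE plus a between-eye offset (SD 0.15 D),
decomposed into sphere and minus-cylinder (cylinder ≤ 0, the
autorefractor convention that keeps the MSE formula sign-stable), and
each of the repeats (default 2) adds instrument noise (SD 0.25 D) with
5% of readings flagged unreliable. Education is observed through the
questionnaire: degree holders are not asked the completion age. Every
participant has a baseline visit only. Exclusion structure: per-eye-
condition flags (~8% of participants in total), 5% born outside
England/Scotland/Wales, 2% missing education.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: linkage disequilibrium and winner's-
curse-inflated discovery weights; population structure (principal
components are injected as independent covariates, not computed from
genotypes); genotyping batch effects; selection into the cohort
(participation bias); non-normal trait tails; and any nonlinearity of
the education–myopia dose–response beyond the questionnaire coding.

## Phenotype derivation

MSE = sphere + 0.5 × cylinder. Aggregation keeps the baseline visit,
drops unreliable-flagged readings, averages sphere and cylinder per eye
across repeats *first* and applies the formula to the averaged powers
(numerically identical to averaging per-reading MSEs, by linearity, but
the stated order is what is implemented and tested), then averages the
available eyes; a participant with one measurable eye keeps that eye's
value, and a participant with none is dropped. Education: degree → 21
years; reported completion ages below 15 floored at 15; the dichotomous
recoding is "completed after age 16". Exclusions are attributed
first-match in a fixed order (eye condition → country → missing
education → missing refraction → missing genotype) so the per-reason
counts are deterministic and sum to the number excluded.

## Harmonisation conventions

Dosage = 2·P(aa) + P(Aa) on the effect allele. Panel variants are
oriented to the cohort's counted allele: identical allele sets keep or
flip (d → 2−d) the dosage; allele sets that match only under base
complement are treated as strand flips; palindromic variants (A/T, C/G)
with cohort MAF in [0.42, 0.5] — or unknown frequency — are dropped as
strand-ambiguous, a convention (logged, adjustable) rather than a
reproduction of the emulated study, which does not state its rule.
Missing per-participant dosages are imputed with 2 × the cohort
effect-allele frequency, keeping n constant. Instrument strength:
partial R² is the incremental R² over the covariate-only model and
F = R²_p/(1−R²_p)·(n−p−1) with p counting score plus covariates; a
perfect fit reports F = +inf rather than erroring.

## Numerical and testing conventions

* All randomness flows from one seeded `numpy` Generator per entry
  point; identical configurations are byte-identical end to end.
* Genotype probability triples must sum to 1 within 1e-9; dosage
  conversion tolerates 1e-6.
* Egger's design is declared unidentifiable when all oriented exposure
  associations are equal to relative precision 1e-12. 2SLS refuses
  instruments with first-stage F below 1e-6.
* The weighted-mode grid spans the ratio range ± 3 bandwidths; identical
  ratios (zero bandwidth) return the common ratio directly.
* Replicate-based calibration tests (Durbin–Wu–Hausman type-I error, CI
  coverage, family-wise null behaviour) use a reduced scenario — 8
  education + 6 myopia variants, n = 800–1500, education-score R² 0.03 —
  chosen so 500 replicates run in seconds while keeping the instrument
  strong enough that weak-instrument bias is negligible (F ≈ 25–45).
  Study-scale checks (n = 50 000–60 000, full panels) run once per
  suite.
* The pipeline writes full-precision TSV/JSON artefacts; display
  rounding is left to readers of the tables.

## Known limitations

* Split-sample estimators are attenuated at this study's instrument
  strength (see above); the one-sample 2SLS is the primary estimate.
* The weighted-median duplication invariance is exact for non-pivotal
  variants; duplicating the pivotal variant can move the interpolated
  crossing by a sliver of its weight.
* The simultaneous-causation scenario solves the latent linear system
  and applies the education coding afterwards, so in that regime the
  forward estimand is only approximately the configured β.
* Power uses the normal approximation of the NCP chi-square (the
  continuous-outcome convention of the standard MR power calculator);
  exact small-sample power is out of scope.
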