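# Methods

## The model

A structural covariance network (SCN) describes how a morphometric
measure — here regional gray-matter (GM) volume — covaries between brain
regions across subjects. Given volumes for R regions in n healthy
subjects, each region is first residualized by ordinary least squares on
an intercept plus age, sex (0/1), education (years) and total
intracranial volume (TIV, ml), and the network edge between regions a
and b is the Pearson correlation r_ab of the residuals — i.e. a partial
correlation given the nuisance covariates. Over a 116-region
parcellation this yields R(R−1)/2 = 6,670 edges.

Group-level SCNs cannot describe a single patient. The individualized
variant (IDSCN) asks how much one subject K perturbs the healthy
template:

1. **rSCN** — the reference network over the n reference subjects.
2. **pSCN** — the same construction repeated on the n + 1 subjects
   obtained by adding K. The covariate regression is refit on all n + 1
   subjects by default (a flag applies the reference coefficients to K
   instead; the difference is O(1/n)).
3. **ΔSCN = pSCN − rSCN**, standardized per edge into

       Z = ΔSCN / ((1 − r²) / (n − 1)),

   where r is the reference edge correlation. (1 − r²)/(n − 1) is the
   scale of the change one added subject can induce in a sample
   correlation, so Z is a unit-scale edge weight. Positive Z: the edge
   covariance is stronger in K than in the reference population;
   negative: weaker. The formula divides by (1 − r²)/(n − 1) itself,
   not its square root; a square-root variant is available behind a
   flag for sensitivity analysis, default off.

Two-sided p-values are read from the standard normal, and a patient's
*differential edges* are those passing the Bonferroni threshold
α / 6,670 (α = 0.05). Healthy controls get their own networks by
leave-one-out by default: the template excludes the subject and the
perturbed network re-adds them (n is then the leave-one-out cohort
size). A flag disables this, in which case the subject stays in the
template and the perturbation duplicates them.

Downstream, the per-subject edge weights Z feed an unpaired two-sample
t-test per edge between patients and controls (pooled-variance Student
by default, Welch by flag), Bonferroni-corrected over all edges; an
incidence map counts how many patients individually flag each edge.
Clinically, the total CSVD MRI burden counts one point for each of four
markers present (lacunes, microbleeds, white-matter hyperintensities,
enlarged perivascular spaces; 0–4), and Spearman rank correlations
relate burden and the differential edge's Z to HAMD depression scores
at a configured corrected threshold (default 0.005 for the two
analyses, kept as a configured constant rather than recomputed as
α/m = 0.025; the mismatch is logged).

## Calibration of the null Z — what holds and what does not

Writing the added subject's residual scores as (x, y) for an edge with
reference correlation r, the influence-function expansion gives

    Δr ≈ [xy − r(x² + y²)/2] / (n + 1),

so Z ≈ xy − r(x²+y²)/2 up to O(1/n): a *product* of two near-normal
scores, not a normal variable. Empirically (n_ref = 200, 20 regions,
healthy held-out subjects) the package measures grand mean ≈ 0.0,
pooled SD ≈ 0.97 and excess kurtosis ≈ 6 — centered and unit-scale, as
the Z construction intends, but with exponential rather than Gaussian
tails.

The consequence: normal-tail p-values are accurate in the bulk but
anti-conservative far in the tail, exactly where Bonferroni operates.
At the per-subject threshold 0.05/190 the true per-edge exceedance is
roughly 1% rather than 2.6×10⁻⁴, and the measured probability that a
*null* subject shows at least one "significant" edge is ≈ 0.5, not
0.05. This is intrinsic to the statistic, not to sample size or the
generator, and the package implements the method exactly as defined;
the test suite records the failure openly
(`test_single_subject_bonferroni_detection_controls_familywise_error`)
rather than hiding it. Per-subject differential edges should therefore
be read as a descriptive ranking, not as calibrated inferences. The
group-level t-test on Z does not rely on the normal approximation (only
on between-group exchangeability) and its family-wise error is
controlled (measured ≈ 0.01 at Bonferroni 0.05 over 500 null
repetitions).

## The synthetic cohort generator

No public data accompany this design, so the generator is a first-class
component with known ground truth. Per subject:

    volume_r = base_r · (TIV/1435) + β_age(age−65) + β_sex·sex
               + β_edu(edu−12) + σ_s·z_r + σ_n·ε_r

with z ~ N(0, C) for a block correlation matrix C, σ_s = 0.5 ml
structural scale and σ_n = 0.15 ml independent noise (observable
correlations are C attenuated by σ_s²/(σ_s²+σ_n²) ≈ 0.92; the
attenuated matrix is the reported ground truth). Defaults chosen once
to mirror a small elderly case-control morphometry study: 34 reference
subjects, 22 patients; age ~ N(65, 7²) clipped to 50–80, education
6–20 years, sex balanced Bernoulli, TIV ~ N(1435, 133²) ml; base
volumes uniform 4–14 ml; age slope −0.03 ml/yr, volumes proportional
to TIV so residualization is non-trivial. The default correlation
structure is modular — blocks of four regions at r = 0.3, between-block
0.05 — plus, on the 116-region parcellation, one strongly coupled
caudate–cerebellar pair (Caudate_L, Cerebelum_6_R) at r = 0.7 that
serves as the canonical aberration site. Identical specs (including
the seed) reproduce cohorts bit-for-bit; all randomness flows through
one seeded generator.

**Aberration mechanism.** An injected edge (i, j, δ, sign) shifts the
patient's residuals at *both* regions by δ residual SDs each, in
opposite directions relative to the sign of the pair's true correlation
(sign = +1 weakens/reverses the pair's covariance, −1 strengthens it);
the overall side alternates with patient index so group marginal means
stay balanced. δ = 0 leaves the patient exactly a healthy draw. A
one-sided alternative — displacing region j from its conditional
expectation given region i — was implemented first and rejected on
pilot evidence: a single y-only outlier moves a sample correlation by
at most ~|x|/√n however large the displacement, so at n_ref = 34 its
|Z| saturates near |x|·√n and essentially never tops a 6,670-edge
network (0/100 recovery even at extreme magnitudes). Breaking a
*strong* edge is also the detectable scenario: the 1/(1 − r²) weight
in Z rewards deviations on high-r edges, which is why the canonical
aberration site is the r = 0.7 pair rather than an uncorrelated one —
and it matches the disease picture of weakened structural covariance.

**Calibrated magnitudes.** Two recovery experiments use their own
displacement, calibrated once by pilot simulation and then frozen:

- δ = 3.5 per region for single-patient recovery: the injected edge
  attains the top |Z| and passes Bonferroni in ≈ 99% of seeds
  (n_ref = 34, 116 regions).
- δ = 2.0 for a group-shared edge (also the `default_cohort_spec`
  setting): large enough for every patient to carry a detectable
  deviation, small enough that the outlier does not bleed into the
  perturbed regions' other edges at group level. A large shared δ
  inflates the patient-group variance of every edge touching the two
  perturbed regions (an outlier inflates the region's sample variance
  in the perturbed network, shrinking all its correlations), which the
  n = 56 group test detects as spurious collateral edges.

The group-recovery experiment evaluates the t-test with the Welch
variant: the injected variance inflation violates the pooled test's
equal-variance assumption precisely at edges touching the perturbed
regions, making the pooled test anti-conservative there (uniqueness of
the injected edge ≈ 0.6–0.9 pooled vs ≈ 0.97–1.0 Welch in pilot runs).
The pipeline default remains the classical pooled test.

**Clinical link.** A latent severity s ~ N(0,1) per patient drives
HAMD and the four markers through Gaussian channels of correlation
λ = `clinical_link`: HAMD = 8 + ⌊exp(0.640 + 1.053·g)⌋ capped at 52
(mean ≈ 10.8, SD ≈ 4.4, floor 8 since patient inclusion requires
HAMD > 7), and marker m is present when λs + √(1−λ²)ε_m exceeds a
probit cut-off placed at prevalence 0.92/0.80/0.50/0.45 (WMH, lacune,
EPVS, CMB). Controls get HAMD ~ min(Poisson(0.3), 7) and no markers.
λ is calibrated so the *population* Spearman correlation between the
0–4 burden and HAMD is 0.70 at the default λ = 0.85; the n = 22
estimate then averages ≈ 0.69 with sampling SD ≈ 0.12.

**What the generator does not emulate.** Gaussian volumes with linear
covariate effects and a modular correlation matrix; no image-level
artifacts, no scanner or site effects, no non-linear age effects, no
lesion geometry, no comorbidity structure, and aberrations are
edge-sparse by construction (a diffuse mode is expressible via many
injected edges but is not the default). Passing recovery tests
therefore demonstrates that the pipeline's statistics behave as
designed under a faithful covariance model — not that real CSVD
patients present such clean single-edge deviations.

## Numerical choices

- OLS via `numpy.linalg.lstsq`; the design must be full rank, and a
  constant covariate is reported by name. Reference cohorts need
  n ≥ 7 so residual degrees of freedom stay positive after the
  4-covariate + intercept fit.
- Edges are stored as dense symmetric matrices plus the canonical
  upper-triangle (i < j, 0-based) vectorization; diagonal Z is 0 and
  diagonal p is 1 by convention.
- |r| = 1 on any reference off-diagonal edge is a hard error
  (degenerate template), as is a zero-variance region.
- Significance orderings break ties lexicographically by region pair
  for determinism; Bonferroni is applied as p < α/m threshold
  comparison.
- Chi-square tests are Pearson without continuity correction (the
  variant that reproduces SPSS's printed line for the published 2×2
  tables); Yates correction is available by flag.
- Tables are written with `%.17g` so a write/read cycle is bit-exact
  (`float_precision="round_trip"` on read).
- Problem sizes in the statistical tests (e.g. 500 null repetitions for
  family-wise error, 50–100 seeds for recovery rates, n_ref = 200 and
  20 regions for calibration) were chosen to keep each check's binomial
  or Monte-Carlo uncertainty well below the margin it asserts.

## Known limitations

- Per-subject edge p-values are anti-conservative in the far tail (see
  calibration section); only group-level inference is calibrated.
- The leave-one-out choice for controls changes n by one between
  groups; both handling modes are runnable but not separately
  validated against each other at scale.
- `two_sample_t_from_summary` reproduces decisions ("p < 0.001") from
  rounded published summaries, but printed two-decimal p-values of
  marginal tests are generally not exactly recoverable from rounded
  means and SDs.
- The burden score treats the four markers as exchangeable presence
  flags; published severity-weighted variants (count thresholds per
  marker) are expressible through `MarkerThresholds` but not the
  default.
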