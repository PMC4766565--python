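# Methods

`bpmr` implements the analysis chain of a multi-ethnic population study of
blood pressure (BP) and retinal vascular caliber, from raw clinical
measurements to instrumental-variable causal estimates, and pairs it with a
synthetic cohort generator whose ground truth makes every stage testable.

## Phenotype derivation

**Blood pressure.** BP is measured twice, five minutes apart; a third
reading is taken when the first two differ by more than 10 mmHg systolic
*or* 5 mmHg diastolic. The subject's SBP/DBP is the mean of the two closest
readings. Two points in this protocol are under-specified and are resolved
as follows:

* *Trigger logic.* The protocol sentence can be read as requiring both
  differences ("and") or either ("either threshold exceeded"). We default
  to OR — a reading pair discordant on either component is unreliable, and
  the MESA protocol this measurement scheme follows re-measures on either
  discrepancy. The literal AND variant is available
  (`needs_third_reading(..., rule="and")`).
* *Closeness metric.* With three readings, "the two closest" is undefined
  for a bivariate quantity. We minimise |ΔSBP| + |ΔDBP| jointly over the
  three pairs, breaking ties toward the earliest pair in measurement order.
  Applying the rule jointly (not per component) keeps the chosen SBP and
  DBP from the same pair of physiological states.

Mean arterial pressure is MAP = SBP/3 + 2·DBP/3.

**Retinal caliber.** CRAE/CRVE summarise the six largest arteriolar and
venular widths by the revised Knudtson-Parr-Hubbard iterative procedure:
sort descending, pair the largest with the smallest, combine each pair as
k·√(w₁² + w₂²) (k = 0.88 arterioles, 0.95 venules), carry the median of odd
counts, and repeat (6→3→2→1). For six equal widths w the chain closes to
k²·√(4k² + 2)·w ≈ 1.74843·w (arterioles), which the tests pin to 1e-10.
The result is order-invariant and homogeneous of degree one; both are
tested as properties. The constants are exposed for sensitivity analysis.

**Status flags.** Hypertension = prior diagnosis or anti-hypertensive
medication. Diabetes = diagnosis, medication, or casual glucose ≥ 11.1
mmol/L (inclusive). A missing glucose with both flags false yields a
missing flag, never false.

## Genetics

Dosages are risk-allele counts (0/1/2, NaN missing), re-oriented on read
when a VCF's REF/ALT order differs from the panel; alleles matching neither
panel allele are a hard error. QC removes SNPs with call rate < 95%,
MAF < 0.1%, or Hardy-Weinberg p < 1e-6; all three comparisons are strict,
and removal reasons are reported per SNP in filter order (call rate, MAF,
HWE). HWE defaults to the 1-df chi-square goodness-of-fit test (the
chip-era convention); the exact heterozygote-enumeration test is available
via `method="exact"`. Monomorphic SNPs get p = 1 by convention so they fall
to the MAF filter with the more informative reason.

Ancestry PCA standardises each SNP column by its estimated allele
frequency (centre 2p̂, scale √(2p̂(1−p̂)); missing values mean-imputed)
and takes the SVD. Signs are fixed by making each component's
largest-magnitude SNP loading positive, which makes scores deterministic
and row-order invariant.

GRS construction mirrors the two-step protocol: within ±100 kb of each
index SNP (1-based, inclusive), the candidate most associated with the
phenotype (linear regression of phenotype on dosage, stratum-adjusted in
pooled estimation) is selected; its β is the weight; p-value ties break to
the smaller position. The score is Σβ·dosage. Missing dosages default to
expected-dosage imputation (2p̂); complete-case is available. Weights are
estimated **in-sample** by default, matching the original protocol; because
in-sample weighting makes the weighted score behave like a many-weak-
instruments estimator (biasing 2SLS toward OLS by roughly k/(n·R²) of the
confounding gap), a `split_sample` mode estimates weights on a random half
and runs the causal models on the held-out half. Validation studies in the
test suite use the split-sample mode so that bias measured there reflects
the estimator, not the weighting shortcut.

## Causal models

* **Model 1** (OLS): caliber ~ BP + age + gender + ethnicity.
* **Model 2** (OLS): Model 1 + household income, BMI, total cholesterol,
  glucose, creatinine, hypertension status, diabetes status, smoking,
  alcohol. Published descriptions of this adjustment set differ on two
  covariates (presence-of-condition vs medication/history indicators); we
  default to the presence flags, with the alternative list selectable
  (`model2_covariates="footnote"`).
* **Model 3** (Mendelian randomisation): 2SLS with the phenotype-matched
  GRS as instrument, adjusting for age, gender and the first five genetic
  PCs. Stage 1 regresses exposure on instrument + covariates; stage 2
  regresses outcome on the predicted exposure + covariates. Standard
  errors use stage-2 residuals recomputed with the *observed* exposure —
  the standard 2SLS correction (naive second-stage OLS SEs are wrong).
  With a single instrument and no covariates the estimator reduces to the
  Wald ratio cov(z,y)/cov(z,x), pinned in tests to 1e-10. The first-stage
  partial F is attached to every IV fit; F below 10 raises a recorded
  warning, not an error.

Effect sizes are reported per 10 mmHg by rescaling the fitted coefficient
at reporting time (algebraically identical to pre-dividing the exposure,
with cleaner diagnostics). OLS p-values come from the t reference
distribution, 2SLS and meta-analysis from the normal; CIs are β ± 1.96·se.

Whether the original analysis pooled all ethnicities with PCs or
meta-analysed per-ethnicity IV fits is ambiguous; both are implemented.
The default (`model3_mode="meta"`) fits 2SLS per ethnic stratum and pools
by inverse-variance fixed effects (β* = Σwβ/Σw, w = 1/se², se* = 1/√Σw),
reporting Cochran's Q and I²; `model3_mode="pooled"` runs one 2SLS with the
PCs carrying ancestry. DerSimonian-Laird random effects is available.

The pleiotropy check regresses each traditional biomarker (total
cholesterol, glucose, creatinine) on each GRS; under the exclusion
restriction these are null, and the test suite verifies the check is
calibrated (≈5% of null p-values below 0.05) and powerful against an
injected GRS→biomarker path.

## Synthetic cohort generator

The generator is the study's statistical structure with knobs:

* Three strata ("malay", "indian", "chinese") with distinct allele
  frequencies at ten biallelic SNPs (spread ≈ 0.1–0.15 across strata so
  ancestry PCA has signal to exercise the PC-adjustment path).
* Additive SNP effects on latent SBP (≈1.0–1.8 mmHg/allele) and DBP
  (≈0.6–1.0). These are *illustrative*: no per-ethnicity effect sizes are
  published for these loci, and single-SNP GWAS effects are smaller; they
  are sized so the 10-SNP score explains ≈5% of MAP variance (first-stage
  F in the hundreds at n ≈ 5000), i.e. a clearly strong instrument, so
  estimator validation is not dominated by weak-instrument artefacts.
* Measured confounders (age, BMI, smoking) affecting both BP and caliber,
  plus one standard-normal unmeasured confounder with positive loadings on
  SBP/DBP (8/4 mmHg per SD) and on CRAE/CRVE (2.5/3 μm per SD). The
  unmeasured path makes covariate-adjusted OLS biased toward zero (the
  configured truth is negative) by a predictable sign — the textbook
  confounding the MR design removes.
* A linear causal effect of one BP phenotype (default MAP) on caliber:
  −0.26 μm/mmHg for CRAE and −0.09 for CRVE, i.e. −2.6 and −0.9 per
  10 mmHg, magnitudes in the range population studies report.
* Two BP readings per subject (SD 4 mmHg each), with a third generated
  exactly when the repeat rule — evaluated by calling the phenotypes
  module's own rule, not a copy — fires on the first two.
* Six arteriolar and six venular widths per subject, obtained by inverting
  the Knudtson chain for equal widths and jittering each first-round pair
  along an angle θ ≤ π/4 (widths √2·w·cosθ, √2·w·sinθ). This perturbation
  preserves both the sort-and-pair structure and each pair's combined
  value, so the phenotype module's caliber computation reproduces the
  latent caliber exactly — the generator cannot compensate for a wrong
  caliber implementation.
* Optional violations: a direct standardised-GRS→caliber path
  (`pleiotropy_effect`, μm per SD) and direct GRS→biomarker paths
  (`grs_to_confounder`) for studying exclusion-restriction failures.
* Genotype missingness (default 2%) applied after latent phenotypes are
  formed, and an optional `candidates_per_locus` that adds null SNPs
  inside each ±100 kb window to exercise per-locus selection.

Baselines and intercepts are set so cohort means land near realistic
values (SBP ≈ 139, DBP ≈ 79, MAP ≈ 99 mmHg; CRAE ≈ 141, CRVE ≈ 212 μm;
hypertension ≈ 50%). Identical config + seed is bit-identical.

**What the generator does not emulate:** linkage disequilibrium beyond the
index SNPs, per-stratum effect-size heterogeneity, non-linear BP-caliber
relations, measurement error in covariates, image-grading artefacts, and
selection into the cohort. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the assumed linear-additive
structure — not that real retinal data satisfy that structure.

## Validation summary (what the test suite computes)

* Closed-form anchors: MAP group cells recompute from printed group means;
  pooled prevalences recompute from per-stratum counts; the equal-width
  Knudtson chain matches its hand-iterated closed form to 1e-10.
* Oracle equivalences: OLS vs a normal-equations solve (1e-8); 2SLS vs the
  Wald ratio (1e-10); fixed-effects pooling vs explicit inverse-variance
  arithmetic (1e-12).
* Parameter recovery: over 200 simulated cohorts (analysis n ≈ 5000,
  confounding on, pleiotropy off, split-sample GRS), the mean 2SLS
  estimate falls within 5% of the configured effect and 95% CIs cover the
  truth in ≥85% of runs, while OLS is biased toward zero.
* Calibration: the pleiotropy check's null rejection rate over 200 cohorts
  stays in [0.02, 0.09] at α = 0.05.
* Scaling: the Monte-Carlo SD of the 2SLS estimate halves when the sample
  size quadruples (√n consistency), within 25%.

Monte-Carlo problem sizes (200 replicates at n ≈ 5000 for recovery,
n = 450 for null calibration, 100 replicates for the scaling law) were
chosen to make the binomial/Monte-Carlo error of each checked quantity
small relative to its tolerance while keeping the suite fast.

## Numerical and degenerate-input choices

Design matrices expand categoricals to dummies (first level dropped) and
are rank-checked before fitting; collinear columns are named in the error.
Stratified fits auto-drop covariates constant within a stratum, with a log
note. Constant instruments and constant pleiotropy-check responses are
errors. Monomorphic SNPs: HWE p = 1 (the MAF filter removes them). PCA
scale factors are floored at 1e-12 to survive near-monomorphic columns.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; the split-sample partition derives its stream
from the run seed plus a fixed offset so it is independent of the
generator's draws.

## Known limitations

In-sample GRS weighting (the default, faithful to the protocol) leaves a
finite-sample bias toward OLS that the split-sample mode avoids at the
cost of half the sample. The meta and pooled variants of the MR tier give
the same answer only under cross-stratum homogeneity; Q and I² are
reported so users can see when they do not. The pipeline's file-input path
expects the documented column dictionary and a panel TSV; it does not
harmonise arbitrary external GWAS formats.
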