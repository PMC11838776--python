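# Methods

## The model

`ptspo` treats regional TSPO quantification as a probabilistic
classification problem. For each (subject, region) pair the model computes

    logit(p_TSPO) = β₀ + Σⱼ βⱼ Xⱼ  [+ u_dataset],

where p_TSPO is the probability that the region expresses TSPO above its
constitutive level. The approach rests on four assumptions: (i) the PET
signal is monotone in tissue tracer concentration; (ii) that concentration
mixes contributions from inflammation status, perfusion/delivery, and
blood–brain extraction; (iii) explicit covariates (age, sex, genotype, dose
per weight, regional K₁) absorb the *constitutive* sources of variability,
so that what remains loads on the inflammation axis; (iv) coefficients are
common to all cortex and cerebellum (CC) regions — the model is trained
once and applied to every CC region.

Training labels are anatomical: regions with constitutively low expression
(occipital cortex, dorsal and ventrolateral cerebellum) are class 0 and
high-expression regions (thalamus, pallidum) class 1. Prediction is then an
indirect quantification: an unlabelled cortical region whose TAC "looks
like" a high-expression region under the model gets a high p_TSPO.

### Predictors

* **TAC samples.** The regional TAC is converted to SUV
  (`activity · weight / dose`, g/mL convention) and linearly interpolated at
  [1.25, 4.5, 13.5, 30, 50, 75] min against frame mid-times. The sparse grid
  limits collinearity between neighbouring frames. Schedules shorter than
  the grid (60-min protocols) raise an error by default; the documented
  reduced grid {1.25, 13.5, 50} min remains servable.
* **K₁** from the 1T1K-IDIF stage (below).
* **Covariates.** age (years), sex (male=1), genotype (HAB=1, MAB=0), and
  injected dose over weight (MBq/kg). For tracers insensitive to the rs6971
  polymorphism the genotype column is fixed to 1 upstream.

All regressors are min–max normalized to [0, 1]; bounds are computed on the
labelled training rows (a pooling switch extends them to all rows) and
persisted in the model bundle. Prediction-time values outside the training
range are *not* clipped — clipping would destroy the monotonicity of the
linear predictor in the raw feature.

### Fitting

The plain fit is IRLS maximum likelihood with optional ridge penalty
(intercept unpenalized). Convergence: relative deviance change < 1e-10 or
100 iterations. A deviance indistinguishable from zero, or scaled
coefficients beyond 5·10², triggers a separation error naming the diverging
feature; the workflows therefore fit with a default ridge of 1e-4, which is
inert on well-posed designs and keeps (quasi-)separated ones finite.
Standard errors come from the inverse Fisher information; Wald z statistics
are reported and labelled as such (dispersion fixed at 1).

The hierarchical variant adds a Gaussian random intercept per dataset
(scanner/protocol batch) and maximizes the Laplace-approximate marginal
likelihood over (β, log σ): the per-dataset intercept mode is found by a 1-D
Newton iteration, and the outer optimization uses L-BFGS-B with log σ
bounded in [log 1e-3, log 10]. After fitting, the mean of the intercept
modes is shifted into β₀ so the reported offsets are centred. Fixed-effect
standard errors use a central-difference Hessian of the marginal
log-likelihood. One dataset degenerates exactly to the plain fit (verified
to 1e-8). A quadrature cross-check was considered unnecessary for a single
scalar random effect; the recovery simulations in the test suite play that
role.

### Feature selection

Bidirectional stepwise from the intercept-only model with the
deviance-difference χ²(1) test (p_enter = 0.05, p_remove = 0.10; a
forward-only flag exists). The search runs on 100 bootstrap resamples drawn
at the *subject* level — a subject's regional rows move together because
they share covariates — and features selected in strictly more than 80% of
iterations are retained. Stepwise candidate fits carry a 1e-6 ridge so a
transiently separated resample cannot abort the search; at that magnitude
the deviance test is unaffected. Resamples containing one outcome class are
skipped and counted.

### Training protocol

Subjects are split 80/20 with stratification over sex, genotype, age class
(< 30 vs ≥ 30 years; the boundary age 30 goes to the older stratum) and
dataset, by largest-remainder quotas with seeded tie-breaking. Selection
runs on the training side; the final (hierarchical where applicable) fit is
evaluated by ROC on the held-out labelled rows. Because the published
operating threshold p_TH is not fixed by the method, both the p = 0.5
operating point and the Youden-optimal point are reported in the bundle.
Healthy-control quantification uses leave-one-subject-out refits.

## Input function and K₁

The IDIF is extracted by intensity thresholding of the early-window sum
image (quantile threshold) followed by retention of the candidate voxels
whose TACs correlate best with the candidate mean — both the correlation
statistic and the retention fraction are configuration, since only the
mechanism is fixed. The mean blood TAC is fitted with a piecewise model:
linear rise from injection to the empirical peak, tri-exponential decay
afterwards, consistent with a bolus injection. The rise-shape choice
matters little because the K₁ stage consumes the *running integral* of the
input, which is dominated by the post-peak decay. Fitting is
variable-projection weighted least squares (amplitudes solved linearly at
each step, rates optimized in log space) with duration weights and 20
log-spaced multi-starts (seeded jitter); parameters are canonicalized with
rates in decreasing order.

K₁ is the duration-weighted least-squares slope of early tissue activity
against the frame-averaged running integral of the fitted input, using
frames with mid-time inside the window — 4 min for PBR28-like tracers,
5 min for DPA-714/PK11195-like ones, reflecting each tracer's kinetics and
time resolution. The irreversible single-compartment model contains no
blood-volume term; vb and a delay term exist as off-by-default options. On
model-matched data the estimator is exact (the regressor is frame-averaged
exactly as the data are); with realistic reversible kinetics it is biased
low, and the bias shrinks monotonically as the window shortens — both
properties are exercised in the tests.

## Forward simulators

One- and two-tissue compartment curves are computed by *analytic*
convolution of the bi-exponential impulse response with the piecewise
input, with closed-form handling of the θ → 0 and θ → λ confluent limits;
frame values are time averages over the frame interval via composite
12-point Gauss–Legendre panels (≤ 0.5 min, split at the input peak), which
is exact to well below 1e-8 for these smooth curves. An independent stiff
ODE integration agrees to better than 1e-6 relative. Measured activity is
(1 − vb)·C_tissue + vb·C_blood.

## The synthetic study

The generator emulates the statistical structure the method assumes, not
PET physics:

* **Cohorts** of 60 subjects across 3 datasets; age uniform 22–65 y, sexes
  balanced, 70% HAB, dose 330 ± 30 MBq, weight 75 ± 12 kg.
* **Input**: tri-exponential, amplitudes (10, 3.5, 0.8) SUV scaled by
  dose/weight, rates (3, 0.35, 0.02) /min, peak at 0.75 min.
* **Kinetics**: K₁ ≈ 0.10 mL/cm³/min with 5%/8% regional/subject spread;
  k₂ = K₁/8 — the large apparent distribution volume reflects modelling
  against a whole-blood IDIF without metabolite correction, where apparent
  efflux is small; k₄ = 0.033 /min; binding k₃ = 0.06 · expression score,
  modulated by genotype (MAB = 0.5 × HAB), a mild age slope (+0.5%/year
  from 45), a log-normal 20% between-subject constitutive-binding spread
  (the tracer's well-known unexplained inter-individual variability), and a
  cohort-level multiplier for disease (+30%) or blocking (−60%) conditions.
* **Expression map**: deterministic scores with thalamus/pallidum analogues
  on top (1.8–2.0), occipital/cerebellar analogues at the bottom
  (0.08–0.16) and unlabelled cortex spread between 0.3 and 1.0.
* **Batch effects**: per-dataset log-scale sensitivity factors (±0.12)
  applied multiplicatively to blood and tissue alike — exactly the
  random-intercept structure of the hierarchical model.
* **Noise**: zero-mean Gaussian with variance ∝ activity / frame duration
  (count-statistics heuristic), scale 0.35, giving late-frame CV ≈ 5–10%;
  TACs are clipped at zero. `noise_seed` redraws only the noise (test–retest
  scans share all structure); `anatomy_seed` shares the expression map and
  regional delivery pattern across cohorts (case–control designs).

What the generator does **not** emulate: image-domain effects (PSF,
scatter, motion, partial volume), metabolite kinetics, IDIF extraction
noise (the generated blood curves are noiseless), frame-to-frame correlated
noise, and regional covariate interactions. Passing tests therefore
demonstrate the statistical machinery under the stated assumptions, not
performance on real scans. Two visible consequences: synthetic
low/high-region separation is cleaner than in clinical data (held-out AUC
≈ 0.99 and expression concordance ρ ≈ 0.98, versus markedly lower
published real-data analogues), and synthetic test–retest ICC is *lower*
than the real-data readout, because after covariate removal the
between-subject variance left in a homogeneous healthy cohort is small
relative to propagated frame noise. The acceptance script therefore
computes test–retest reproducibility on a patient-style cohort
(binding +30%, between-subject binding spread 0.35, n = 10), mirroring the
population in which that readout is defined.

The **rat phantom** is a 13-ROI bilateral roster. Intracerebral-endotoxin
animals (n = 4) carry a 2.5× binding elevation in seven right-hemisphere
ROIs around the injection track; intraperitoneal animals (n = 8) a global
1.4× elevation; vehicle animals (n = 8) baseline. The rodent pipeline
screens training ROIs by paired t-tests on hemispheric TAC AUC with
Benjamini–Hochberg FDR (q = 0.05), drops age/sex/genotype from the
predictors, screens the remainder by Wald |z| > 1.96 (keeping the single
strongest predictor if none passes on the 4-animal training set), and
compares per-ROI p_TSPO between systemic-endotoxin and vehicle groups by
rank-sum tests with FDR.

## Evaluation battery

* **ROC** via threshold sweep; trapezoid AUC (equal to the Mann–Whitney
  concordance probability, ties counting one half).
* **Δ_P**: relative-frequency histograms of p_TSPO on [0, 1] with bin width
  0.05 (the published histograms do not state a binning; 0.05 makes the 0.5
  boundary a bin edge), deviation = case − control per bin,
  Δ_P = 100 × Σ over bins with lower edge ≥ 0.5. Antisymmetric under cohort
  swap by construction.
* **Group tests**: Wilcoxon rank-sum (unpaired) or signed-rank (paired),
  exact null for ≤ 25 per group without ties, normal approximation with tie
  correction otherwise; identical paired cohorts return p = 1.
* **ICC**: ICC(A,1) — two-way, absolute agreement, single measure — from
  the mean-squares decomposition; the specific form is stated explicitly
  because "ICC" alone is ambiguous. Degenerate tables return NaN, never a
  fabricated value. Summary: fraction of ROIs with ICC ≥ 0.7.
* **Expression concordance**: Spearman rank correlation between
  across-subject mean CC p_TSPO and the regional expression score (rank
  correlation because expression is meaningful only ordinally); Pearson is
  available as an option.
* **FDR**: Benjamini–Hochberg step-up.

## Numerical choices and degenerate inputs

* Tolerances: IRLS 1e-10 relative deviance; inner Newton 1e-12; tri-exp
  least squares xtol/ftol 1e-14.
* Ties in the stratified split and any randomized start jitter are driven
  by explicit seeds; identical seeds give bit-identical outputs.
* Degenerate cases fail loudly: single-class designs, constant features,
  rank-deficient designs, empty blood-voxel candidate sets, grids outside
  the sampled range, ICC with zero between-subject variance, ROC with one
  class.
* The problem sizes used by the default test-suite and acceptance runs
  (60-subject cohorts, 100 bootstrap iterations, 1000-repetition FDR null)
  were chosen so a complete run takes seconds to a couple of minutes on a
  single CPU while keeping every Monte-Carlo margin comfortable.

## Known limitations

* The anatomical label set and the 116-of-125 ROI roster of the original
  atlas are user configuration; the packaged regional expression table is a
  synthetic stand-in for a transcriptome-derived map, not a redistribution
  of one.
* The hierarchical fit supports a single grouping factor with a scalar
  random intercept; crossed or nested designs are out of scope.
* Coefficients are global across CC regions by assumption (iv); regionally
  varying coefficients, covariate interactions and voxel-wise maps are
  deliberate non-goals.
* The IDIF stage models extraction and fitting, not carotid segmentation
  quality; on real data the K₁ stage inherits whatever bias the IDIF
  carries.
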