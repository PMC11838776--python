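# ptspo — blood-free, reference-free TSPO PET quantification

Dynamic PET of the 18 kDa translocator protein (TSPO) is the workhorse for
imaging neuroinflammation, but its quantification is notoriously hard: full
kinetic modelling needs arterial blood sampling with metabolite and plasma
protein-binding corrections, no brain region is free enough of TSPO to serve
as a reference, the rs6971 polymorphism splits subjects into high/mixed
affinity binder classes (HAB/MAB), and the signal carries large unexplained
inter-individual variability.

`ptspo` implements an alternative: a logistic model that maps a region's raw
time-activity curve (TAC) plus kinetic and subject covariates directly to
the **probability of TSPO overexpression**,

```
ln( p / (1 - p) ) = β₀ + Σⱼ βⱼ Xⱼ          p ≡ p_TSPO ∈ [0, 1]
```

with predictors Xⱼ: the SUV-normalized TAC interpolated on a sparse grid
([1.25, 4.5, 13.5, 30, 50, 75] min), the regional delivery rate K₁ estimated
non-invasively (single irreversible compartment fitted on the first minutes
against an image-derived input function), and age, sex, TSPO genotype and
injected dose over body weight. Training labels come from anatomy: regions
with constitutively low expression (occipital, dorsal/ventrolateral
cerebellum) are outcome 0, high-expression regions (thalamus, pallidum)
outcome 1. A per-dataset Gaussian random intercept (hierarchical fit,
Laplace-approximate ML) absorbs scanner/protocol batch effects. Feature
selection is bootstrap-stabilized stepwise-by-deviance: only predictors
selected in >80% of 100 subject-level resamples are kept. Cohorts are
compared through relative-probability histograms of regional p_TSPO and the
percent excess mass above 0.5, Δ_P.

The package is intended for PET methodologists: it provides the full
pipeline (TAC/NIfTI I/O, IDIF extraction and tri-exponential fitting,
compartmental simulators, design assembly, plain and hierarchical fits,
selection, evaluation statistics, a rat endotoxin-lesion variant) plus a
synthetic-cohort generator so that every stage is testable without access to
clinical scan archives.

## Worked example

```python
from ptspo import CohortConfig, cc_roi_ids, delta_p, generate_cohort
from ptspo.workflows import design_from_cohort, train_model

hc = generate_cohort(CohortConfig(seed=11))          # 60 subjects, 3 scanners
design, spec = design_from_cohort(hc)                # SUV, grid, K1, covariates
trained = train_model(design, spec, hc.subjects, seed=1, n_boot=100)
print(trained.selection.retained)
print(trained.results.summary())
```

```
['tac13.5', 'tac75']
p_TSPO logistic model (hierarchical, Laplace)
================================================================
coef                  estimate     std err     Wald z     P>|z|
----------------------------------------------------------------
intercept             -16.1673      4.8919      -3.30   0.00095
tac13.5               -56.7814     18.6529      -3.04   0.00233
tac75                 114.7824     31.6036       3.63  0.000281
----------------------------------------------------------------
deviance 3.1371   iterations 22   converged True
between-dataset intercept SD 1.4056
dataset offsets  datasetA: +1.033, datasetB: -0.083, datasetC: -0.949
Wald z statistics reported (not t); dispersion fixed at 1.
```

The bootstrap selection kept a mid-scan and a late TAC sample; the late
sample carries a positive coefficient (more retained tracer, higher
p_TSPO), the earlier one a negative sign, and the random intercepts soak up
the three simulated scanner sensitivities. On held-out subjects the model
separates low- from high-expression regions with AUC 0.992.

Applying the trained model to a simulated disease cohort whose binding is
30% elevated and comparing regional p_TSPO against the healthy controls:

```python
dis = generate_cohort(CohortConfig(seed=12, anatomy_seed=11,
                                   binding_multiplier=1.3))
d_dis, _ = design_from_cohort(dis, spec=spec, fit_bounds=False)
cc = cc_roi_ids()
hc_pt = trained.bundle.predict(design[design.roi_id.isin(cc)])
dis_pt = trained.bundle.predict(d_dis[d_dis.roi_id.isin(cc)])
cmp = delta_p(dis_pt.p_tspo, hc_pt.p_tspo)
print(f"Delta_P = {cmp.delta_p:+.1f}%   rank-sum p = {cmp.test.p_value:.3g}")
```

```
Delta_P = +13.3%   rank-sum p = 4.69e-25
```

Δ_P > 0 means the case group has more relative probability mass at
p_TSPO > 0.5 than the controls — a regional excess of probable TSPO
overexpression.

A command-line interface wraps the same workflows
(`ptspo simulate|train|predict|loo|compare|rat`); each subcommand takes a
YAML config and writes CSV/JSON outputs plus a reproducibility manifest.

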