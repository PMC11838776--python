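"""End-to-end workflows: training with stratified split + bootstrap feature
selection, leave-one-out prediction of healthy controls, cohort comparison,
and the rat endotoxin pipeline. The CLI is a thin wrapper over these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PTSPOError
from .evaluation import (GroupComparison, RocCurve, delta_p, fdr_adjust,
                         group_test, hemispheric_auc_screen, roc_analysis)
from .features import FeatureSpec, build_design, to_suv
from .idif import BloodCurve, TriExpFit
from .io import ExpressionMap, RegionalTAC, SubjectRecord
from .kinetics import estimate_k1_1t1k
from .model import ModelBundle, TSPOLogit, TSPOLogitResults, predict_ptspo
from .selection import SelectionReport, bootstrap_selection
from .simulate import RAT_ROIS, Cohort, RatStudy

__all__ = ["stratified_split", "estimate_cohort_k1", "train_model",
            "TrainResult", "loo_predict", "compare_cohorts", "rat_pipeline",
            "RatPipelineResult", "design_from_cohort"]

#: Default ridge used for final fits: zero-cost on well-posed designs,
#: rescues (quasi-)separated training classes, which clean synthetic
#: low/high regions routinely produce.
DEFAULT_RIDGE = 1e-4


# ---------------------------------------------------------------------------
# stratified subject split
# ---------------------------------------------------------------------------

def stratified_split(subjects: list[SubjectRecord], test_fraction: float = 0.2,
                     seed: int = 0, age_cut: float = 30.0,
                     ) -> tuple[list[str], list[str]]:
    """80/20-style split balanced over sex, genotype, age class (younger
    than ``age_cut`` vs at least ``age_cut``) and dataset.

    Per-stratum test quotas use largest-remainder apportionment of
    ``round(test_fraction * n)`` total test subjects; ties and within-stratum
    choices are broken by a seeded shuffle. Strata with a single subject
    degrade gracefully with a warning.
    """
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(subjects)))
    strata: dict[tuple, list[str]] = {}
    for s in sorted(subjects, key=lambda s: s.subject_id):
        key = (s.sex, s.genotype, s.age >= age_cut, s.dataset_id)
        strata.setdefault(key, []).append(s.subject_id)
    singletons = [k for k, v in strata.items() if len(v) < 2]
    if singletons:
        warnings.warn(f"{len(singletons)} stratum(s) with < 2 subjects; "
                      "stratification degrades to near-random there", stacklevel=2)
    keys = sorted(strata)
    ideal = {k: test_fraction * len(strata[k]) for k in keys}
    quota = {k: int(np.floor(ideal[k])) for k in keys}
    shortfall = n_test - sum(quota.values())
    remainders = sorted(keys, key=lambda k: (-(ideal[k] - quota[k]), rng.random()))
    for k in remainders[:max(shortfall, 0)]:
        quota[k] += 1
    test_ids: list[str] = []
    for k in keys:
        members = list(strata[k])
        rng.shuffle(members)
        test_ids += members[:min(quota[k], len(members))]
    # top up / trim if rounding against stratum sizes left a mismatch
    train_ids = [s.subject_id for s in subjects if s.subject_id not in set(test_ids)]
    while len(test_ids) > n_test:
        train_ids.append(test_ids.pop())
    pool = [sid for sid in train_ids]
    while len(test_ids) < n_test and pool:
        pick = pool[int(rng.integers(len(pool)))]
        pool.remove(pick)
        train_ids.remove(pick)
        test_ids.append(pick)
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# cohort-level K1 and design assembly
# ---------------------------------------------------------------------------

def estimate_cohort_k1(tacs: list[RegionalTAC],
                       blood: dict[str, BloodCurve | TriExpFit],
                       window_minutes: float = 4.0) -> dict[tuple[str, str], float]:
    """1T1K-IDIF K1 per (subject, ROI)."""
    k1s = {}
    for tac in tacs:
        est = estimate_k1_1t1k(tac, blood[tac.subject_id], window_minutes)
        k1s[(tac.subject_id, tac.roi_id)] = est.k1
    return k1s


def design_from_cohort(cohort: Cohort, spec: FeatureSpec | None = None,
                       window_minutes: float = 4.0,
                       fit_bounds: bool | None = None,
                       ) -> tuple[pd.DataFrame, FeatureSpec]:
    """TAC -> SUV -> sparse grid -> covariates -> normalized design frame."""
    k1s = estimate_cohort_k1(cohort.tacs, cohort.blood_fits, window_minutes)
    return build_design(cohort.tacs, k1s, cohort.subject_map, spec=spec,
                        labels=cohort.expression, fit_bounds=fit_bounds)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    bundle: ModelBundle
    results: TSPOLogitResults
    selection: SelectionReport
    roc: RocCurve | None
    train_subjects: list[str]
    test_subjects: list[str]
    design: pd.DataFrame
    spec: FeatureSpec


def train_model(design: pd.DataFrame, spec: FeatureSpec,
                subjects: list[SubjectRecord], *, seed: int = 0,
                test_fraction: float = 0.2, n_boot: int = 100,
                freq_threshold: float = 0.80, ridge: float = DEFAULT_RIDGE,
                hierarchical: bool | None = None, run_selection: bool = True,
                ) -> TrainResult:
    """Stratified split -> bootstrap stepwise selection on the training set
    -> final (hierarchical when several datasets) fit -> held-out ROC."""
    labelled = design[design["outcome"].notna()]
    if labelled.empty or labelled["outcome"].nunique() < 2:
        raise InsufficientDataError("training requires labelled low/high ROIs")
    train_ids, test_ids = stratified_split(subjects, test_fraction, seed=seed)
    train_rows = design[design["subject_id"].isin(train_ids)]
    test_rows = design[design["subject_id"].isin(test_ids)]

    scope = spec.feature_names
    if run_selection and n_boot > 0:
        report = bootstrap_selection(train_rows, scope, n_iter=n_boot,
                                     freq_threshold=freq_threshold, seed=seed)
        retained = report.retained
        if not retained:
            warnings.warn("bootstrap selection retained no feature; "
                          "keeping the full scope", stacklevel=2)
            retained = list(scope)
    else:
        report = SelectionReport(pd.Series(1.0, index=pd.Index(scope, name="feature")),
                                 freq_threshold, 0, 0, seed)
        retained = list(scope)
    spec.selected = {f: (f in retained) for f in scope}

    model = TSPOLogit.from_design(train_rows, features=retained, feature_spec=spec)
    results = model.fit(ridge=ridge, hierarchical=hierarchical)
    roc = None
    test_labelled = test_rows[test_rows["outcome"].notna()]
    if not test_labelled.empty and test_labelled["outcome"].nunique() == 2:
        scores = results.predict(test_labelled)
        roc = roc_analysis(scores, test_labelled["outcome"].to_numpy())
    bundle = results.to_bundle(feature_spec=spec, seed=seed)
    if roc is not None:
        bundle.extras["holdout_auc"] = roc.auc
        sens, espec = roc.operating_point(0.5)
        thr, ysens, yspec = roc.youden_point()
        bundle.extras["operating_points"] = {
            "p_th_0.5": {"sensitivity": sens, "specificity": espec},
            "youden": {"p_th": thr, "sensitivity": ysens, "specificity": yspec}}
    return TrainResult(bundle, results, report, roc, train_ids, test_ids,
                       design, spec)


# ---------------------------------------------------------------------------
# leave-one-out prediction
# ---------------------------------------------------------------------------

def loo_predict(design: pd.DataFrame, spec: FeatureSpec, cc_rois: list[str], *,
                ridge: float = DEFAULT_RIDGE, hierarchical: bool | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject: refit the model on every other subject's labelled rows,
    then predict p_TSPO for that subject's cortex + cerebellum ROIs.

    Returns the p_TSPO table and the per-fold coefficient table (for
    stability diagnostics). Non-convergent folds are flagged and skipped.
    """
    subjects = sorted(design["subject_id"].unique())
    if len(subjects) < 3:
        raise InsufficientDataError("leave-one-out requires >= 3 subjects")
    features = spec.active_features
    tables, coef_rows = [], []
    for sid in subjects:
        train = design[design["subject_id"] != sid]
        try:
            model = TSPOLogit.from_design(train, features=features, feature_spec=spec)
            res = model.fit(ridge=ridge, hierarchical=hierarchical)
        except PTSPOError as exc:
            warnings.warn(f"fold {sid}: fit failed ({exc}); fold skipped", stacklevel=2)
            continue
        target = design[(design["subject_id"] == sid)
                        & design["roi_id"].isin(cc_rois)]
        tables.append(predict_ptspo(res, target, dataset_policy="match"))
        coef_rows.append(pd.Series(res.params, name=sid))
    if not tables:
        raise InsufficientDataError("every leave-one-out fold failed")
    coefs = pd.DataFrame(coef_rows)
    coefs.index.name = "left_out_subject"
    return pd.concat(tables, ignore_index=True), coefs


def coefficient_cv(coefs: pd.DataFrame) -> pd.Series:
    """Across-fold coefficient of variation (%) per model coefficient."""
    return (coefs.std(ddof=1) / coefs.mean().abs() * 100.0).rename("cv_percent")


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def compare_cohorts(case_ptspo: pd.DataFrame, control_ptspo: pd.DataFrame,
                    lobes: dict[str, str] | None = None, paired: bool = False,
                    bin_width: float = 0.05) -> dict[str, GroupComparison]:
    """Whole-CC, per-lobe and cerebellum comparisons of p_TSPO distributions.

    Input tables carry subject_id, roi_id, p_tspo. Without a lobe table only
    the whole-CC comparison is computed (with a warning).
    """
    out = {"cc": delta_p(case_ptspo["p_tspo"].to_numpy(),
                         control_ptspo["p_tspo"].to_numpy(),
                         bin_width=bin_width, paired=paired, label="cc")}
    if lobes is None:
        warnings.warn("no lobe table supplied; whole-cortex comparison only",
                      stacklevel=2)
        return out
    for lobe in ("frontal", "temporal", "parietal", "occipital", "cerebellum"):
        rois = [r for r, l in lobes.items() if l == lobe]
        case = case_ptspo[case_ptspo["roi_id"].isin(rois)]["p_tspo"].to_numpy()
        ctrl = control_ptspo[control_ptspo["roi_id"].isin(rois)]["p_tspo"].to_numpy()
        if case.size and ctrl.size:
            out[lobe] = delta_p(case, ctrl, bin_width=bin_width, paired=paired,
                                label=lobe)
    return out


# ---------------------------------------------------------------------------
# rat pipeline
# ---------------------------------------------------------------------------

RAT_GRID = (1.25, 4.5, 13.5, 30.0, 50.0)
RAT_COVARIATES = ("k1", "dose_over_weight")


@dataclass
class RatPipelineResult:
    screen: pd.DataFrame            # hemispheric AUC screen per base ROI
    training_rois: list[str]
    results: TSPOLogitResults
    retained_features: list[str]
    per_roi: pd.DataFrame           # ip-LPS vs vehicle tests per ROI
    ptspo: dict[str, pd.DataFrame]  # p_TSPO per group


def _rat_suv_pairs(study: RatStudy) -> tuple[dict, dict]:
    ipsi, contra = {}, {}
    for scan in study.scans["ic-LPS"]:
        for tac in scan.tacs:
            base, side = RatStudy.hemisphere(tac.roi_id)
            target = ipsi if side == "R" else contra  # injection into the right striatum
            target.setdefault(base, []).append(to_suv(tac, scan.subject))
    return ipsi, contra


def _rat_design(study: RatStudy, groups: list[str], spec: FeatureSpec,
                labels: ExpressionMap | None, window: float,
                fit_bounds: bool) -> pd.DataFrame:
    tacs, subjects, blood = [], {}, {}
    for g in groups:
        for scan in study.scans[g]:
            tacs.extend(scan.tacs)
            subjects[scan.subject.subject_id] = scan.subject
            blood[scan.subject.subject_id] = scan.blood_fit
    k1s = estimate_cohort_k1(tacs, blood, window)
    design, _ = build_design(tacs, k1s, subjects, spec=spec, labels=labels,
                             fit_bounds=fit_bounds)
    return design


def rat_pipeline(study: RatStudy, *, q: float = 0.05, window_minutes: float = 5.0,
                 wald_z: float = 1.96, ridge: float = DEFAULT_RIDGE,
                 ) -> RatPipelineResult:
    """Focal-lesion training-ROI screen -> reduced logistic model -> Wald
    predictor screening -> per-ROI ip-endotoxin vs vehicle comparison."""
    if len(study.scans["ic-LPS"]) < 3:
        raise InsufficientDataError("the hemispheric screen needs >= 3 lesioned animals")
    ipsi, contra = _rat_suv_pairs(study)
    screen = hemispheric_auc_screen(ipsi, contra, q=q)
    selected = screen[screen["selected"]]["roi_id"].tolist()
    if not selected:
        raise InsufficientDataError("no ROI passed the hemispheric AUC screen")
    labels = ExpressionMap(
        scores={f"{r}_{s}": 0.0 for r in RAT_ROIS for s in ("L", "R")},
        class_labels={**{f"{r}_R": "high" for r in selected},
                      **{f"{r}_L": "low" for r in selected}})
    spec = FeatureSpec(grid_minutes=RAT_GRID, covariates=RAT_COVARIATES)
    train_design = _rat_design(study, ["ic-LPS"], spec, labels, window_minutes,
                               fit_bounds=True)
    model = TSPOLogit.from_design(train_design, features=spec.feature_names,
                                  feature_spec=spec, use_groups=False)
    full = model.fit(ridge=ridge)
    retained = full.wald_screen(wald_z)
    if not retained:  # keep the single strongest predictor
        retained = [full.zvalues.drop("intercept").abs().idxmax()]
    spec.selected = {f: (f in retained) for f in spec.feature_names}
    reduced = TSPOLogit.from_design(train_design, features=retained,
                                    feature_spec=spec, use_groups=False).fit(ridge=ridge)

    ptspo = {}
    for g in ("ip-LPS", "vehicle"):
        design = _rat_design(study, [g], spec, None, window_minutes, fit_bounds=False)
        ptspo[g] = predict_ptspo(reduced, design)
    per_roi_rows = []
    for roi in sorted(ptspo["vehicle"]["roi_id"].unique()):
        a = ptspo["ip-LPS"].query("roi_id == @roi")["p_tspo"].to_numpy()
        b = ptspo["vehicle"].query("roi_id == @roi")["p_tspo"].to_numpy()
        t = group_test(a, b, paired=False)
        per_roi_rows.append({"roi_id": roi, "mean_ip": a.mean(), "mean_vehicle": b.mean(),
                             "statistic": t.statistic, "p": t.p_value})
    per_roi = pd.DataFrame(per_roi_rows)
    p_adj, reject = fdr_adjust(per_roi["p"].to_numpy(), q=q)
    per_roi["p_fdr"] = p_adj
    per_roi["elevated"] = reject & (per_roi["mean_ip"] > per_roi["mean_vehicle"])
    return RatPipelineResult(screen, selected, reduced, retained, per_roi, ptspo)
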