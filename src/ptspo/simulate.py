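"""Synthetic cohorts with the statistical structure the method assumes.

Human cohorts
-------------
Each subject gets covariates (age, sex, TSPO genotype, injected dose,
weight, dataset assignment), a dose-scaled tri-exponential whole-blood input
and, per brain region, a two-tissue-compartment TAC whose binding rate k3
scales with the regional expression score, the genotype (mixed-affinity
binders bind a configurable factor less than high-affinity binders), a mild
age slope and a cohort-wide binding multiplier (disease or blocking
conditions). Scanner batch effects are multiplicative log-scale sensitivity
factors shared by blood and tissue — exactly the structure the hierarchical
model's random intercept is meant to absorb. Frame noise is zero-mean
Gaussian with variance proportional to activity over frame duration (the
usual count-statistics heuristic), tuned to a late-frame coefficient of
variation near 5-10% at default settings.

Rat phantoms
------------
A 13-ROI bilateral roster. Intracerebral-endotoxin animals carry a focal
lesion (elevated k3) in a configured subset of right-hemisphere ROIs;
intraperitoneal-endotoxin animals a global mild elevation; vehicle animals
baseline. Ground truth is returned for every scan.

Everything is deterministic under ``seed``; ``noise_seed`` lets callers
redraw only the measurement noise (test-retest scans share structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .idif import BloodCurve, TriExpFit
from .io import ExpressionMap, RegionalTAC, SubjectRecord
from .kinetics import CompartmentParams, frame_average, tissue_curve
from .schedule import PRESET_SCHEDULES, FrameSchedule

__all__ = ["RegionSpec", "CohortConfig", "Cohort", "RatConfig", "RatStudy",
           "default_human_regions", "generate_expression_map",
           "generate_cohort", "generate_rat_phantom", "lobe_map",
           "cc_roi_ids", "RAT_ROIS", "RAT_LESION_ROIS"]


@dataclass(frozen=True)
class RegionSpec:
    name: str
    lobe: str          # frontal | temporal | parietal | occipital | cerebellum | subcortical
    class_label: str   # 'low' | 'high' | 'unlabelled'


def default_human_regions() -> list[RegionSpec]:
    """30-region roster: thalamic/pallidal high-expression training regions,
    occipital + dorsal/ventrolateral cerebellar low-expression training
    regions, and unlabelled cortex/cerebellum (the CC prediction domain)."""
    regions: list[RegionSpec] = []
    for side in ("l", "r"):
        regions += [
            RegionSpec(f"thalamus_{side}", "subcortical", "high"),
            RegionSpec(f"pallidum_{side}", "subcortical", "high"),
            RegionSpec(f"occipital_inf_{side}", "occipital", "low"),
            RegionSpec(f"cerebellum_dorsal_{side}", "cerebellum", "low"),
            RegionSpec(f"cerebellum_ventrolateral_{side}", "cerebellum", "low"),
            RegionSpec(f"frontal_sup_{side}", "frontal", "unlabelled"),
            RegionSpec(f"frontal_mid_{side}", "frontal", "unlabelled"),
            RegionSpec(f"cingulate_ant_{side}", "frontal", "unlabelled"),
            RegionSpec(f"temporal_sup_{side}", "temporal", "unlabelled"),
            RegionSpec(f"temporal_mid_{side}", "temporal", "unlabelled"),
            RegionSpec(f"insula_{side}", "temporal", "unlabelled"),
            RegionSpec(f"parietal_sup_{side}", "parietal", "unlabelled"),
            RegionSpec(f"parietal_inf_{side}", "parietal", "unlabelled"),
            RegionSpec(f"occipital_mid_{side}", "occipital", "unlabelled"),
            RegionSpec(f"cerebellum_crus_{side}", "cerebellum", "unlabelled"),
        ]
    return regions


def lobe_map(regions: list[RegionSpec] | None = None) -> dict[str, str]:
    return {r.name: r.lobe for r in (regions or default_human_regions())}


def cc_roi_ids(regions: list[RegionSpec] | None = None) -> list[str]:
    """Cortex + cerebellum ROIs — the prediction domain of the model."""
    cc_lobes = {"frontal", "temporal", "parietal", "occipital", "cerebellum"}
    return [r.name for r in (regions or default_human_regions()) if r.lobe in cc_lobes]


@dataclass
class CohortConfig:
    """Generative settings of a synthetic human cohort (study conditions)."""

    seed: int
    n_subjects: int = 60
    datasets: dict[str, float] = field(
        default_factory=lambda: {"datasetA": -0.12, "datasetB": 0.0, "datasetC": 0.12})
    schedule: FrameSchedule = field(
        default_factory=lambda: PRESET_SCHEDULES["pbr28_90min"])
    regions: list[RegionSpec] = field(default_factory=default_human_regions)
    # genotype / demographics
    genotype_hab_fraction: float = 0.7
    mab_binding_factor: float = 0.5   # multiplicative on k3 for MABs
    age_range: tuple[float, float] = (22.0, 65.0)
    age_slope: float = 0.005          # fractional k3 change per year from age 45
    sex_male_fraction: float = 0.5
    sex_binding_factor: float = 1.0   # k3 multiplier for females (1 = no effect)
    dose_mean: float = 330.0          # MBq
    dose_sd: float = 30.0
    weight_mean: float = 75.0         # kg
    weight_sd: float = 12.0
    # kinetics
    k1_base: float = 0.10             # mL/cm^3/min
    k1_region_sd: float = 0.05        # relative spread of regional delivery
    k1_subject_sd: float = 0.08       # relative spread of subject perfusion
    vnd: float = 8.0                  # K1/k2 apparent distribution volume of the
                                      # free compartment against whole-blood IDIF
    k3_scale: float = 0.06            # 1/min per unit expression score
    subject_binding_sd: float = 0.2   # log-scale between-subject spread of
                                      # constitutive binding (the large
                                      # unexplained inter-individual TSPO
                                      # variability the tracer is known for)
    k4: float = 0.033                 # 1/min
    vb: float = 0.0
    binding_multiplier: float = 1.0   # cohort-level k3 factor (disease/blocking)
    # blood input (SUV units, scaled by dose/weight into kBq/mL)
    blood_amplitudes_suv: tuple = (10.0, 3.5, 0.8)
    blood_rates: tuple = (3.0, 0.35, 0.02)
    blood_peak_time: float = 0.75     # minutes
    scan_jitter_sd: float = 0.05      # log-scale per-scan sensitivity jitter
    # noise
    noise_scale: float = 0.35         # sd = noise_scale * sqrt(activity / duration)
    noise_seed: int | None = None     # redraw only measurement noise (test-retest)
    anatomy_seed: int | None = None   # share expression map / regional delivery
                                      # across cohorts (case-control designs)
    group_label: str = "HC"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for frac in (self.genotype_hab_fraction, self.sex_male_fraction):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        labels = {r.class_label for r in self.regions}
        if "low" not in labels or "high" not in labels:
            raise ConfigError("region roster needs at least one low and one high region")
        if self.n_subjects < 1 or len(self.datasets) < 1:
            raise ConfigError("need >= 1 subject and >= 1 dataset")


def generate_expression_map(regions: list[RegionSpec], seed: int) -> ExpressionMap:
    """Deterministic regional expression scores: high-labelled regions
    (thalamus/pallidum analogues) on top, low-labelled (occipital/cerebellar
    analogues) at the bottom, unlabelled cortex in between with spread."""
    if not regions:
        raise ConfigError("empty region roster")
    rng = np.random.default_rng([seed, 0xE])
    scores, labels = {}, {}
    for r in sorted(regions, key=lambda r: r.name):
        if r.class_label == "high":
            s = 1.8 + 0.2 * rng.random()
        elif r.class_label == "low":
            s = 0.08 + 0.08 * rng.random()
        else:
            s = 0.30 + 0.70 * rng.random()
        scores[r.name] = float(s)
        labels[r.name] = r.class_label
    return ExpressionMap(scores, labels)


@dataclass
class Cohort:
    """Synthetic cohort: measured data plus full generating ground truth."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    tacs: list[RegionalTAC]
    blood_curves: dict[str, BloodCurve]
    blood_fits: dict[str, TriExpFit]     # true (sensitivity-scaled) input models
    expression: ExpressionMap
    truth: pd.DataFrame                  # per (subject, roi): kinetic parameters

    @property
    def subject_map(self) -> dict[str, SubjectRecord]:
        return {s.subject_id: s for s in self.subjects}


def generate_cohort(config: CohortConfig) -> Cohort:
    rng = np.random.default_rng([config.seed, 1])
    noise_rng = np.random.default_rng(
        [config.noise_seed if config.noise_seed is not None else config.seed, 2])
    anatomy = config.anatomy_seed if config.anatomy_seed is not None else config.seed
    anatomy_rng = np.random.default_rng([anatomy, 5])
    regions = sorted(config.regions, key=lambda r: r.name)
    emap = generate_expression_map(regions, anatomy)
    region_k1_factor = {r.name: max(0.2, 1 + config.k1_region_sd
                                    * anatomy_rng.standard_normal())
                        for r in regions}
    dataset_names = sorted(config.datasets)
    sched = config.schedule

    subjects, tacs, truth_rows = [], [], []
    blood_curves, blood_fits = {}, {}
    for i in range(config.n_subjects):
        sid = f"sub{i:03d}"
        age = float(rng.uniform(*config.age_range))
        sex = "male" if rng.random() < config.sex_male_fraction else "female"
        genotype = "HAB" if rng.random() < config.genotype_hab_fraction else "MAB"
        dose = float(max(10.0, rng.normal(config.dose_mean, config.dose_sd)))
        weight = float(max(5e-2, rng.normal(config.weight_mean, config.weight_sd)))
        dataset = dataset_names[i % len(dataset_names)]
        subj = SubjectRecord(sid, age, sex, genotype, dose, weight,
                             dataset_id=dataset, group_label=config.group_label)
        subjects.append(subj)

        sensitivity = float(np.exp(config.datasets[dataset]
                                   + config.scan_jitter_sd * noise_rng.standard_normal()))
        suv_to_kbq = dose / weight  # kBq/mL per SUV unit
        blood = TriExpFit(np.asarray(config.blood_amplitudes_suv) * suv_to_kbq * sensitivity,
                          np.asarray(config.blood_rates), config.blood_peak_time)
        blood_fits[sid] = blood
        blood_curves[sid] = BloodCurve(sched, blood(sched.mid_times), source="simulated")

        k1_subject = max(0.2, 1 + config.k1_subject_sd * rng.standard_normal())
        subject_binding = float(np.exp(config.subject_binding_sd
                                       * rng.standard_normal()))
        geno_factor = 1.0 if genotype == "HAB" else config.mab_binding_factor
        sex_factor = 1.0 if sex == "male" else config.sex_binding_factor
        age_factor = max(0.1, 1 + config.age_slope * (age - 45.0))
        for r in regions:
            K1 = config.k1_base * region_k1_factor[r.name] * k1_subject
            k2 = K1 / config.vnd
            k3 = (config.k3_scale * emap.scores[r.name] * subject_binding
                  * geno_factor * sex_factor * age_factor
                  * config.binding_multiplier)
            params = CompartmentParams(K1=K1, k2=k2, k3=k3, k4=config.k4, vb=config.vb)
            clean = frame_average(tissue_curve(params, blood), sched,
                                  breakpoints=(blood.peak_time,))
            noise = (config.noise_scale
                     * np.sqrt(np.clip(clean, 1e-3, None) / sched.durations)
                     * noise_rng.standard_normal(sched.n_frames))
            activity = np.clip(clean + noise, 0.0, None)
            tacs.append(RegionalTAC(r.name, sid, sched, activity))
            truth_rows.append({
                "subject_id": sid, "roi_id": r.name, "dataset_id": dataset,
                "class_label": r.class_label, "K1": K1, "k2": k2, "k3": k3,
                "k4": config.k4, "vb": config.vb, "sensitivity": sensitivity,
                "expression": emap.scores[r.name]})
    return Cohort(config, subjects, tacs, blood_curves, blood_fits, emap,
                  pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# rat endotoxin phantoms
# ---------------------------------------------------------------------------

RAT_ROIS = ("cortex", "basal_ganglia", "hippocampus", "thalamus", "cerebellum",
            "corpus_callosum", "amygdala", "septal_area", "ventricles",
            "white_matter", "hypothalamus", "midbrain", "pons")

#: Default focal-lesion extent after intracerebral endotoxin injection into
#: the right dorsal striatum: seven ROIs around the injection track.
RAT_LESION_ROIS = ("cortex", "basal_ganglia", "corpus_callosum", "amygdala",
                   "septal_area", "ventricles", "white_matter")


@dataclass
class RatConfig:
    """Generative settings of the rat endotoxin study phantom."""

    seed: int
    n_ic: int = 4          # intracerebral endotoxin (focal lesion), >= 3 required
    n_ip: int = 8          # intraperitoneal endotoxin (global elevation)
    n_vehicle: int = 8
    rois: tuple = RAT_ROIS
    lesion_rois: tuple = RAT_LESION_ROIS
    lesion_multiplier: float = 2.5   # k3 factor in ipsilateral lesion ROIs
    ip_multiplier: float = 1.4       # global k3 factor for ip-endotoxin animals
    schedule: FrameSchedule = field(
        default_factory=lambda: PRESET_SCHEDULES["dpa714_60min"])
    dose_mean: float = 20.0          # MBq
    dose_sd: float = 2.0
    weight_mean: float = 0.32        # kg
    weight_sd: float = 0.03
    k1_base: float = 0.12
    k1_spread: float = 0.06
    vnd: float = 2.0
    k3_base: float = 0.035           # baseline binding rate, 1/min
    k3_region_sd: float = 0.15       # relative regional spread
    k4: float = 0.04
    noise_scale: float = 1.1
    noise_seed: int | None = None
    blood_amplitudes_suv: tuple = (11.0, 3.5, 1.2)
    blood_rates: tuple = (3.5, 0.4, 0.025)
    blood_peak_time: float = 0.6

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if len(self.rois) != 13:
            raise ConfigError("the rat roster is the 13-ROI bilateral atlas")
        unknown = set(self.lesion_rois) - set(self.rois)
        if unknown:
            raise ConfigError(f"lesion ROIs not in roster: {sorted(unknown)}")


@dataclass
class RatScan:
    subject: SubjectRecord
    tacs: list[RegionalTAC]
    blood_curve: BloodCurve
    blood_fit: TriExpFit
    group: str      # 'ic-LPS' | 'ip-LPS' | 'vehicle'


@dataclass
class RatStudy:
    config: RatConfig
    scans: dict[str, list[RatScan]]   # keyed by group
    truth: pd.DataFrame

    @staticmethod
    def hemisphere(roi_id: str) -> tuple[str, str]:
        """Split 'cortex_R' into ('cortex', 'R')."""
        base, side = roi_id.rsplit("_", 1)
        return base, side


def generate_rat_phantom(config: RatConfig) -> RatStudy:
    rng = np.random.default_rng([config.seed, 3])
    noise_rng = np.random.default_rng(
        [config.noise_seed if config.noise_seed is not None else config.seed, 4])
    sched = config.schedule
    region_factor = {roi: max(0.2, 1 + config.k3_region_sd * rng.standard_normal())
                     for roi in config.rois}
    k1_factor = {roi: max(0.2, 1 + config.k1_spread * rng.standard_normal())
                 for roi in config.rois}
    scans: dict[str, list[RatScan]] = {"ic-LPS": [], "ip-LPS": [], "vehicle": []}
    truth_rows = []
    counter = 0
    for group, n in (("ic-LPS", config.n_ic), ("ip-LPS", config.n_ip),
                     ("vehicle", config.n_vehicle)):
        for _ in range(n):
            sid = f"rat{counter:03d}"
            counter += 1
            dose = float(max(1.0, rng.normal(config.dose_mean, config.dose_sd)))
            weight = float(max(0.1, rng.normal(config.weight_mean, config.weight_sd)))
            subj = SubjectRecord(sid, age=0.25, sex="male", genotype="HAB",
                                 injected_dose=dose, weight=weight,
                                 dataset_id="rat", group_label=group)
            suv_to_kbq = dose / weight
            blood = TriExpFit(np.asarray(config.blood_amplitudes_suv) * suv_to_kbq,
                              np.asarray(config.blood_rates), config.blood_peak_time)
            animal_factor = max(0.2, 1 + 0.05 * rng.standard_normal())
            tac_list = []
            for roi in config.rois:
                for side in ("L", "R"):
                    k3 = config.k3_base * region_factor[roi] * animal_factor
                    if group == "ip-LPS":
                        k3 *= config.ip_multiplier
                    if group == "ic-LPS" and side == "R" and roi in config.lesion_rois:
                        k3 *= config.lesion_multiplier
                    K1 = config.k1_base * k1_factor[roi]
                    params = CompartmentParams(K1=K1, k2=K1 / config.vnd,
                                               k3=k3, k4=config.k4)
                    clean = frame_average(tissue_curve(params, blood), sched,
                                          breakpoints=(blood.peak_time,))
                    noise = (config.noise_scale
                             * np.sqrt(np.clip(clean, 1e-3, None) / sched.durations)
                             * noise_rng.standard_normal(sched.n_frames))
                    roi_id = f"{roi}_{side}"
                    tac_list.append(RegionalTAC(roi_id, sid, sched,
                                                np.clip(clean + noise, 0.0, None)))
                    truth_rows.append({"subject_id": sid, "group": group,
                                       "roi_id": roi_id, "K1": K1, "k3": k3,
                                       "lesioned": (group == "ic-LPS" and side == "R"
                                                    and roi in config.lesion_rois)})
            scans[group].append(RatScan(subj, tac_list,
                                        BloodCurve(sched, blood(sched.mid_times),
                                                   source="simulated"),
                                        blood, group))
    return RatStudy(config, scans, pd.DataFrame(truth_rows))
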