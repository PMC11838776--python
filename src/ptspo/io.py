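"""Readers/writers for TAC tables, subject metadata and regional expression
maps, plus ROI mean-TAC extraction from 4-D dynamic volumes.

Conventions
-----------
* Activity concentration: kBq/mL. Injected dose: MBq. Weight: kg. Time: min.
  Any unit conversion happens at this I/O boundary only.
* TAC tables: long format with columns
  ``subject_id, roi_id, frame_index, activity`` (one row per frame), with the
  frame schedule supplied separately (CSV with ``start_minutes,
  duration_minutes`` columns, or YAML with those keys, or a
  :class:`~ptspo.schedule.FrameSchedule`). A wide layout (one row per
  (subject, ROI), one column per frame) is accepted as a convenience.
* Voxel indexing is 0-based; atlas label 0 is background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CovariateError, DimensionError, FormatError, ScheduleError
from .schedule import FrameSchedule

__all__ = [
    "RegionalTAC",
    "SubjectRecord",
    "ExpressionMap",
    "read_schedule",
    "write_schedule",
    "read_tac_table",
    "write_tac_table",
    "read_subject_table",
    "write_subject_table",
    "read_expression_map",
    "write_expression_map",
    "extract_roi_tacs",
    "tacs_to_frame",
    "load_volume",
]


@dataclass
class RegionalTAC:
    """Mean activity-concentration time course of one ROI of one subject."""

    roi_id: str
    subject_id: str
    schedule: FrameSchedule
    activity: np.ndarray  # kBq/mL per frame
    units: str = "kBq/mL"

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise FormatError(
                f"TAC {self.subject_id}/{self.roi_id}: activity length {act.size} "
                f"!= {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(act)):
            raise FormatError(f"TAC {self.subject_id}/{self.roi_id}: non-finite activity")
        self.activity = act

    def scaled(self, factor: float, units: str | None = None) -> "RegionalTAC":
        return RegionalTAC(self.roi_id, self.subject_id, self.schedule,
                           self.activity * factor, units or self.units)


@dataclass
class SubjectRecord:
    """Subject covariates and linkage used by the logistic model."""

    subject_id: str
    age: float                 # years
    sex: str                   # 'male' | 'female'
    genotype: str              # 'HAB' | 'MAB'
    injected_dose: float       # MBq
    weight: float              # kg
    dataset_id: str = "dataset1"
    group_label: str = "HC"

    def __post_init__(self):
        if self.age <= 0:
            raise CovariateError(f"{self.subject_id}: age must be > 0")
        if self.injected_dose <= 0 or self.weight <= 0:
            raise CovariateError(f"{self.subject_id}: dose and weight must be > 0")
        if self.sex not in ("male", "female"):
            raise CovariateError(f"{self.subject_id}: sex must be 'male' or 'female'")
        if self.genotype not in ("HAB", "MAB"):
            raise CovariateError(f"{self.subject_id}: genotype must be 'HAB' or 'MAB'")

    @property
    def dose_over_weight(self) -> float:
        """Injected dose per body weight (MBq/kg)."""
        return self.injected_dose / self.weight


@dataclass
class ExpressionMap:
    """Regional target-expression scores with training-class labels.

    ``class_label`` is 'low', 'high' or 'unlabelled'; low/high regions define
    the outcome-0/outcome-1 training classes of the logistic model.
    """

    scores: dict[str, float]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for roi, s in self.scores.items():
            if not np.isfinite(s):
                raise FormatError(f"expression score for {roi} is not finite")
        for roi, lab in self.class_labels.items():
            if lab not in ("low", "high", "unlabelled"):
                raise FormatError(f"bad class label {lab!r} for {roi}")

    def label(self, roi_id: str) -> str:
        return self.class_labels.get(roi_id, "unlabelled")

    @property
    def low_rois(self) -> list[str]:
        return sorted(r for r, l in self.class_labels.items() if l == "low")

    @property
    def high_rois(self) -> list[str]:
        return sorted(r for r, l in self.class_labels.items() if l == "high")

    def to_frame(self) -> pd.DataFrame:
        rois = sorted(self.scores)
        return pd.DataFrame(
            {"roi_id": rois,
             "expression": [self.scores[r] for r in rois],
             "class_label": [self.label(r) for r in rois]}
        )


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def read_schedule(path: str | Path) -> FrameSchedule:
    """Read a frame schedule from CSV (start_minutes, duration_minutes) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
        try:
            return FrameSchedule(np.asarray(payload["start_minutes"], float),
                                 np.asarray(payload["duration_minutes"], float))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"schedule YAML {path} missing keys") from exc
    df = pd.read_csv(path)
    missing = {"start_minutes", "duration_minutes"} - set(df.columns)
    if missing:
        raise FormatError(f"schedule file {path} missing columns {sorted(missing)}")
    return FrameSchedule(df["start_minutes"].to_numpy(float),
                         df["duration_minutes"].to_numpy(float))


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump({
            "start_minutes": schedule.start_times.tolist(),
            "duration_minutes": schedule.durations.tolist(),
        }))
    else:
        pd.DataFrame({"start_minutes": schedule.start_times,
                      "duration_minutes": schedule.durations}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TAC tables
# ---------------------------------------------------------------------------

_LONG_COLS = ["subject_id", "roi_id", "frame_index", "activity"]


def read_tac_table(path: str | Path, schedule: FrameSchedule | str | Path,
                   layout: str = "long") -> list[RegionalTAC]:
    """Read a TAC table. ``schedule`` may be a FrameSchedule or a sidecar path.

    ``layout='long'`` expects columns subject_id, roi_id, frame_index,
    activity; ``layout='wide'`` expects subject_id, roi_id, then one column
    per frame (any names, in frame order).
    """
    if not isinstance(schedule, FrameSchedule):
        schedule = read_schedule(schedule)
    # round_trip parsing keeps activities bit-exact across write/read cycles
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        missing = set(_LONG_COLS) - set(df.columns)
        if missing:
            raise FormatError(f"TAC table missing columns {sorted(missing)}")
        tacs = []
        for (sid, roi), grp in df.groupby(["subject_id", "roi_id"], sort=True):
            grp = grp.sort_values("frame_index")
            idx = grp["frame_index"].to_numpy()
            if idx.size != schedule.n_frames or not np.array_equal(idx, np.arange(schedule.n_frames)):
                raise FormatError(
                    f"TAC {sid}/{roi}: frame indices do not cover 0..{schedule.n_frames - 1}")
            tacs.append(RegionalTAC(str(roi), str(sid), schedule,
                                    grp["activity"].to_numpy(float)))
        return tacs
    if layout == "wide":
        if df.shape[1] != 2 + schedule.n_frames:
            raise FormatError(
                f"wide TAC table has {df.shape[1] - 2} frame columns, "
                f"schedule declares {schedule.n_frames}")
        return [RegionalTAC(str(row.iloc[1]), str(row.iloc[0]), schedule,
                            row.iloc[2:].to_numpy(float))
                for _, row in df.iterrows()]
    raise FormatError(f"unknown layout {layout!r}")


def tacs_to_frame(tacs: Iterable[RegionalTAC]) -> pd.DataFrame:
    """Long-format DataFrame view of a TAC collection."""
    rows = []
    for tac in tacs:
        for i, a in enumerate(tac.activity):
            rows.append((tac.subject_id, tac.roi_id, i, a))
    return pd.DataFrame(rows, columns=_LONG_COLS)


def write_tac_table(tacs: Sequence[RegionalTAC], path: str | Path,
                    schedule_path: str | Path | None = None) -> None:
    tacs_to_frame(tacs).to_csv(path, index=False)
    if schedule_path is not None and len(tacs):
        write_schedule(tacs[0].schedule, schedule_path)


# ---------------------------------------------------------------------------
# subject metadata
# ---------------------------------------------------------------------------

_SUBJ_COLS = ["subject_id", "age", "sex", "genotype", "injected_dose",
              "weight", "dataset_id", "group_label"]


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_SUBJ_COLS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"subject table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), age=float(row["age"]),
            sex=str(row["sex"]), genotype=str(row["genotype"]),
            injected_dose=float(row["injected_dose"]), weight=float(row["weight"]),
            dataset_id=str(row.get("dataset_id", "dataset1")),
            group_label=str(row.get("group_label", "HC"))))
    return records


def write_subject_table(subjects: Iterable[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(s, c) for c in _SUBJ_COLS} for s in subjects]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# expression maps
# ---------------------------------------------------------------------------

def read_expression_map(path: str | Path) -> ExpressionMap:
    df = pd.read_csv(path)
    missing = {"roi_id", "expression"} - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing columns {sorted(missing)}")
    labels = {}
    if "class_label" in df.columns:
        labels = dict(zip(df["roi_id"].astype(str), df["class_label"].astype(str)))
    return ExpressionMap(dict(zip(df["roi_id"].astype(str), df["expression"].astype(float))),
                         labels)


def write_expression_map(emap: ExpressionMap, path: str | Path) -> None:
    emap.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI extraction from 4-D volumes
# ---------------------------------------------------------------------------

def load_volume(path: str | Path):
    """Load a NIfTI-1 volume (4-D dynamic image, 3-D label atlas or mask)."""
    import nibabel as nib

    return nib.load(str(path))


def _as_array(img):
    """Accept a nibabel spatial image or a plain ndarray."""
    if hasattr(img, "get_fdata"):
        return np.asanyarray(img.dataobj)
    return np.asarray(img)


def extract_roi_tacs(image4d, atlas_labels, gm_mask, schedule: FrameSchedule,
                     subject_id: str = "subject",
                     roi_names: Mapping[int, str] | None = None,
                     ) -> tuple[list[RegionalTAC], list[int]]:
    """Mean TAC per atlas label restricted to a grey-matter mask.

    Returns ``(tacs, excluded_labels)`` where excluded labels had no voxel
    surviving the mask (reported, never silently dropped).
    """
    img = _as_array(image4d).astype(float)
    atlas = _as_array(atlas_labels)
    mask = _as_array(gm_mask).astype(bool)
    if img.ndim != 4:
        raise DimensionError(f"dynamic image must be 4-D, got {img.ndim}-D")
    if atlas.shape != img.shape[:3] or mask.shape != img.shape[:3]:
        raise DimensionError(
            f"atlas {atlas.shape} / mask {mask.shape} do not match image grid {img.shape[:3]}")
    if img.shape[3] != schedule.n_frames:
        raise ScheduleError(
            f"image has {img.shape[3]} frames, schedule declares {schedule.n_frames}")
    atlas = atlas.astype(int)
    tacs: list[RegionalTAC] = []
    excluded: list[int] = []
    for label in np.unique(atlas):
        if label == 0:  # background
            continue
        sel = (atlas == label) & mask
        if not sel.any():
            excluded.append(int(label))
            warnings.warn(f"ROI label {label}: no voxels inside grey-matter mask",
                          stacklevel=2)
            continue
        roi_id = roi_names[int(label)] if roi_names else str(int(label))
        tacs.append(RegionalTAC(roi_id, subject_id, schedule, img[sel].mean(axis=0)))
    return tacs, excluded
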