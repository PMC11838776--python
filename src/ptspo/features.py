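"""Design-matrix assembly for the logistic model.

Per (subject, ROI) row the predictors are:

* the SUV-normalized TAC linearly interpolated on a sparse time grid
  (default [1.25, 4.5, 13.5, 30, 50, 75] min, chosen to limit collinearity
  between neighbouring frames),
* the regional delivery rate K1,
* subject covariates: age, sex, TSPO genotype, injected dose over weight.

All regressors are min-max normalized to [0, 1]; the bounds are computed
from the training rows and persisted in :class:`FeatureSpec` so that
prediction-time rows are transformed identically. Out-of-range prediction
rows are *not* clipped — the linear predictor stays monotone in the raw
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CovariateError, GridError, PTSPOError
from .io import ExpressionMap, RegionalTAC, SubjectRecord
from .kinetics import K1Estimate

__all__ = ["FeatureSpec", "DEFAULT_GRID", "to_suv", "sample_on_grid",
           "build_design", "META_COLUMNS"]

DEFAULT_GRID = (1.25, 4.5, 13.5, 30.0, 50.0, 75.0)
DEFAULT_COVARIATES = ("k1", "age", "sex", "genotype", "dose_over_weight")

#: Non-feature columns of a design frame.
META_COLUMNS = ["subject_id", "roi_id", "dataset_id", "outcome"]

SEX_CODES = {"male": 1.0, "female": 0.0}
GENOTYPE_CODES = {"HAB": 1.0, "MAB": 0.0}


def tac_feature_name(minutes: float) -> str:
    return f"tac{minutes:g}"


@dataclass
class FeatureSpec:
    """Feature roster, sparse time grid, persisted min-max bounds and the
    active-feature mask of a trained model."""

    grid_minutes: tuple = DEFAULT_GRID
    covariates: tuple = DEFAULT_COVARIATES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    selected: dict[str, bool] = field(default_factory=dict)
    extrapolation: str = "error"   # 'error' | 'nearest'
    pool_bounds: bool = False      # bounds from all rows instead of labelled only

    def __post_init__(self):
        grid = tuple(float(g) for g in self.grid_minutes)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise PTSPOError("grid_minutes must be strictly increasing")
        self.grid_minutes = grid
        for name, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise PTSPOError(f"degenerate bounds for feature {name!r}")

    @property
    def feature_names(self) -> list[str]:
        return [tac_feature_name(g) for g in self.grid_minutes] + list(self.covariates)

    @property
    def active_features(self) -> list[str]:
        if not self.selected:
            return self.feature_names
        return [f for f in self.feature_names if self.selected.get(f, False)]

    # -- normalization ------------------------------------------------------
    def fit_bounds(self, df: pd.DataFrame) -> None:
        rows = df if self.pool_bounds else df[df["outcome"].notna()]
        if rows.empty:
            rows = df
        for name in self.feature_names:
            lo, hi = float(rows[name].min()), float(rows[name].max())
            if not hi > lo:
                raise PTSPOError(f"degenerate feature {name!r}: min == max == {lo}")
            self.bounds[name] = (lo, hi)

    def normalize(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.bounds:
            raise PTSPOError("normalization bounds not fitted")
        out = df.copy()
        for name in self.feature_names:
            lo, hi = self.bounds[name]
            out[name] = (df[name] - lo) / (hi - lo)
        return out

    def denormalize(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name in self.feature_names:
            lo, hi = self.bounds[name]
            out[name] = df[name] * (hi - lo) + lo
        return out

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = {k: list(v) for k, v in self.bounds.items()}
        d["grid_minutes"] = list(self.grid_minutes)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(grid_minutes=tuple(d["grid_minutes"]),
                   covariates=tuple(d["covariates"]),
                   bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
                   selected=dict(d.get("selected", {})),
                   extrapolation=d.get("extrapolation", "error"),
                   pool_bounds=bool(d.get("pool_bounds", False)))


def to_suv(tac: RegionalTAC, subject: SubjectRecord) -> RegionalTAC:
    """SUV(t) = concentration / (injected dose per gram of body mass).

    With activity in kBq/mL, dose in MBq and weight in kg this is
    ``activity * weight / dose`` (the g/mL-convention dimensionless SUV).
    """
    if subject.injected_dose <= 0 or subject.weight <= 0:
        raise CovariateError(f"{subject.subject_id}: non-positive dose or weight")
    return tac.scaled(subject.weight / subject.injected_dose, units="SUV")


def sample_on_grid(tac: RegionalTAC, grid_minutes: Sequence[float],
                   extrapolation: str = "error") -> np.ndarray:
    """Linear interpolation of the TAC at the grid points, against frame
    mid-times. Grid points outside [first mid, last mid] raise
    :class:`~ptspo.errors.GridError` by default, or take the nearest frame
    value when ``extrapolation='nearest'``."""
    mids = tac.schedule.mid_times
    grid = np.asarray(grid_minutes, dtype=float)
    outside = (grid < mids[0] - 1e-9) | (grid > mids[-1] + 1e-9)
    if outside.any():
        if extrapolation == "error":
            bad = grid[outside]
            raise GridError(
                f"grid point(s) {bad.tolist()} outside the sampled range "
                f"[{mids[0]:.3g}, {mids[-1]:.3g}] min of {tac.subject_id}/{tac.roi_id}")
        if extrapolation != "nearest":
            raise PTSPOError(f"unknown extrapolation policy {extrapolation!r}")
        import warnings
        warnings.warn(f"grid points {grid[outside].tolist()} held at nearest frame",
                      stacklevel=2)
    return np.interp(grid, mids, tac.activity)


def build_design(tacs: Iterable[RegionalTAC],
                 k1s: Mapping[tuple[str, str], "K1Estimate | float"],
                 subjects: Mapping[str, SubjectRecord],
                 spec: FeatureSpec | None = None,
                 labels: ExpressionMap | None = None,
                 fit_bounds: bool | None = None,
                 suv_input: bool = False) -> tuple[pd.DataFrame, FeatureSpec]:
    """Assemble the design frame: one row per (subject, ROI).

    Rows from low/high-labelled ROIs get outcome 0/1; unlabelled ROIs get
    outcome ``NaN`` and are carried for prediction. In fit mode (``spec``
    without bounds, or ``fit_bounds=True``) min-max bounds are computed from
    the labelled training rows (all rows when ``spec.pool_bounds``); in apply
    mode stored bounds are reused and out-of-range values are kept unclipped.
    """
    spec = spec or FeatureSpec()
    if fit_bounds is None:
        fit_bounds = not spec.bounds
    rows = []
    for tac in sorted(tacs, key=lambda t: (t.subject_id, t.roi_id)):
        sid, roi = tac.subject_id, tac.roi_id
        if sid not in subjects:
            raise CovariateError(f"no covariates for subject {sid!r}")
        subj = subjects[sid]
        suv = tac if suv_input else to_suv(tac, subj)
        samples = sample_on_grid(suv, spec.grid_minutes, spec.extrapolation)
        key = (sid, roi)
        if key not in k1s:
            raise CovariateError(f"no K1 estimate for {key}")
        k1 = k1s[key]
        k1 = k1.k1 if isinstance(k1, K1Estimate) else float(k1)
        label = labels.label(roi) if labels is not None else "unlabelled"
        outcome = {"low": 0.0, "high": 1.0}.get(label, np.nan)
        row = {"subject_id": sid, "roi_id": roi, "dataset_id": subj.dataset_id,
               "outcome": outcome}
        row.update({tac_feature_name(g): v for g, v in zip(spec.grid_minutes, samples)})
        row.update({"k1": k1, "age": float(subj.age),
                    "sex": SEX_CODES[subj.sex],
                    "genotype": GENOTYPE_CODES[subj.genotype],
                    "dose_over_weight": subj.dose_over_weight})
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + spec.feature_names)
    if df.empty:
        raise PTSPOError("no design rows assembled")
    if fit_bounds:
        spec.fit_bounds(df)
    return spec.normalize(df), spec
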