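"""Image-derived input function (IDIF) extraction and tri-exponential fitting.

The whole-blood input is recovered without arterial sampling: carotid-siphon
voxels are segmented on an early-window intensity image, refined by keeping
the voxels whose time courses correlate best with the candidate mean, and the
resulting mean blood TAC is fitted with a piecewise model — a linear rise
from injection to the empirical peak followed by a tri-exponential decay

    C_b(t) = A1 e^{-l1 (t - t_peak)} + A2 e^{-l2 (t - t_peak)} + A3 e^{-l3 (t - t_peak)}

for t >= t_peak. The fitted curve (not the raw frame samples) feeds the K1
estimator, so the running integral of the input is analytic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, ExtractionError, FitError, InsufficientDataError
from .io import _as_array
from .schedule import FrameSchedule

__all__ = ["BloodCurve", "TriExpFit", "select_blood_voxels", "fit_triexp"]


@dataclass
class BloodCurve:
    """Whole-blood activity concentration per frame (kBq/mL)."""

    schedule: FrameSchedule
    activity: np.ndarray
    source: str = "image-derived"  # 'image-derived' | 'simulated' | 'file'

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise DataError("blood activity length must match the schedule")
        if not np.all(np.isfinite(act)):
            raise DataError("blood activity contains non-finite values")
        self.activity = act

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"mid_minutes": self.schedule.mid_times,
                      "activity_kBq_per_mL": self.activity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, schedule: FrameSchedule) -> "BloodCurve":
        df = pd.read_csv(path)
        return cls(schedule, df.iloc[:, 1].to_numpy(float), source="file")

    def running_integral(self, t) -> np.ndarray:
        """Trapezoidal integral of the frame-sampled curve from t=0, with the
        curve assumed zero at injection."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        knots = np.concatenate([[0.0], self.schedule.mid_times])
        vals = np.concatenate([[0.0], self.activity])
        cum = np.concatenate([[0.0], np.cumsum(np.diff(knots) * (vals[:-1] + vals[1:]) / 2)])
        out = np.interp(t, knots, cum)
        # beyond the last mid-time, extend with the last value held constant
        beyond = t > knots[-1]
        if np.any(beyond):
            out[beyond] = cum[-1] + vals[-1] * (t[beyond] - knots[-1])
        return out


@dataclass
class TriExpFit:
    """Piecewise linear-rise / tri-exponential-decay input model.

    Amplitudes in kBq/mL, rates in 1/min; canonical ordering l1 > l2 > l3 > 0.
    The curve rises linearly from (0, 0) to (peak_time, sum(A)) and decays as
    the sum of three exponentials afterwards.
    """

    amplitudes: np.ndarray   # A1..A3
    rates: np.ndarray        # l1..l3
    peak_time: float         # minutes
    rss: float = np.nan      # weighted residual sum of squares of the fit

    def __post_init__(self):
        A = np.asarray(self.amplitudes, dtype=float)
        lam = np.asarray(self.rates, dtype=float)
        if A.size != lam.size:
            raise FitError("amplitudes and rates must have the same length")
        order = np.argsort(lam)[::-1]  # canonical: fastest rate first
        self.amplitudes = A[order]
        self.rates = lam[order]
        if np.any(self.rates <= 0):
            raise FitError("decay rates must be positive")

    @property
    def peak_value(self) -> float:
        return float(self.amplitudes.sum())

    def __call__(self, t) -> np.ndarray:
        """Instantaneous blood concentration at times ``t`` (minutes)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        tp = self.peak_time
        rising = (t >= 0) & (t < tp)
        if tp > 0:
            out[rising] = self.peak_value * t[rising] / tp
        post = t >= tp
        u = t[post] - tp
        out[post] = np.sum(self.amplitudes[:, None] * np.exp(-self.rates[:, None] * u[None, :]),
                           axis=0)
        return out

    def running_integral(self, t) -> np.ndarray:
        """Analytic integral of the curve from 0 to each ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tp, P = self.peak_time, self.peak_value
        out = np.zeros_like(t)
        pre = (t > 0) & (t < tp)
        if tp > 0:
            out[pre] = P * t[pre] ** 2 / (2 * tp)
        post = t >= tp
        u = t[post] - tp
        rise_area = P * tp / 2
        decay = np.sum((self.amplitudes / self.rates)[:, None]
                       * (-np.expm1(-self.rates[:, None] * u[None, :])), axis=0)
        out[post] = rise_area + decay
        return out

    @property
    def total_integral(self) -> float:
        """Integral on [0, inf): finite because all rates are positive."""
        return float(self.peak_value * self.peak_time / 2
                     + np.sum(self.amplitudes / self.rates))

    def to_dict(self) -> dict:
        return {"amplitudes": self.amplitudes.tolist(), "rates": self.rates.tolist(),
                "peak_time": self.peak_time, "rss": float(self.rss)}

    @classmethod
    def from_dict(cls, d: dict) -> "TriExpFit":
        return cls(np.asarray(d["amplitudes"]), np.asarray(d["rates"]),
                   float(d["peak_time"]), float(d.get("rss", np.nan)))


# ---------------------------------------------------------------------------
# blood-voxel selection
# ---------------------------------------------------------------------------

def select_blood_voxels(image4d, schedule: FrameSchedule, early_window: float = 2.0,
                        threshold_quantile: float = 0.99,
                        correlation_keep_fraction: float = 0.5) -> np.ndarray:
    """Candidate blood voxels: intensity threshold on the early-window sum,
    then retention of the fraction with highest correlation to the candidate
    mean TAC.

    Returns an ``(n, 3)`` array of voxel indices (0-based), deterministically
    ordered by descending correlation.
    """
    if not 0 < threshold_quantile < 1:
        raise ExtractionError("threshold_quantile must be in (0, 1)")
    if not 0 < correlation_keep_fraction <= 1:
        raise ExtractionError("correlation_keep_fraction must be in (0, 1]")
    img = _as_array(image4d).astype(float)
    early = schedule.mid_times <= early_window
    if not early.any():
        raise ExtractionError("early window contains no frames")
    early_sum = img[..., early].sum(axis=-1)
    thr = np.quantile(early_sum, threshold_quantile)
    candidates = np.argwhere(early_sum > thr)
    if candidates.shape[0] == 0:
        raise ExtractionError(
            f"no voxels above the early-window intensity threshold ({thr:.3g})")
    tacs = img[tuple(candidates.T)]                   # (n_candidates, n_frames)
    mean_tac = tacs.mean(axis=0)
    mean_c = mean_tac - mean_tac.mean()
    tacs_c = tacs - tacs.mean(axis=1, keepdims=True)
    denom = np.sqrt((tacs_c ** 2).sum(axis=1) * (mean_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, tacs_c @ mean_c / denom, -np.inf)
    n_keep = max(1, int(np.ceil(correlation_keep_fraction * candidates.shape[0])))
    # stable deterministic order: correlation descending, then voxel index
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0], -corr))
    return candidates[order[:n_keep]]


def mean_blood_curve(image4d, voxels: np.ndarray, schedule: FrameSchedule) -> BloodCurve:
    """Mean TAC over a voxel index set."""
    img = _as_array(image4d).astype(float)
    return BloodCurve(schedule, img[tuple(np.asarray(voxels).T)].mean(axis=0))


# ---------------------------------------------------------------------------
# tri-exponential fitting
# ---------------------------------------------------------------------------

def _design(lam: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(u, lam))


def fit_triexp(blood: BloodCurve, n_exp: int = 3, n_starts: int = 20,
               negative_tolerance: float = 1e-6, seed: int = 0) -> TriExpFit:
    """Weighted least-squares tri-exponential fit of the post-peak decay.

    Variable projection: decay rates are optimized in log space while the
    amplitudes are solved by weighted linear least squares at every step.
    Weights are the frame durations (longer frames carry more counts).
    Multi-start over ``n_starts`` log-spaced rate initializations with a
    seeded jitter; the best (lowest weighted RSS) solution is returned.
    """
    t = blood.schedule.mid_times
    y = blood.activity
    scale = np.max(np.abs(y))
    if scale > 0 and np.min(y) < -negative_tolerance * scale:
        raise DataError("blood curve has negative activity beyond tolerance")
    peak_idx = int(np.argmax(y))
    t_peak = float(t[peak_idx])
    post = np.flatnonzero(t >= t_peak)
    if post.size < 2 * n_exp + 1:
        raise InsufficientDataError(
            f"need >= {2 * n_exp + 1} post-peak samples, have {post.size}")
    u = t[post] - t_peak
    yp = y[post]
    w = blood.schedule.durations[post]
    sw = np.sqrt(w)

    def solve_amplitudes(lam):
        E = _design(lam, u)
        A, *_ = np.linalg.lstsq(E * sw[:, None], yp * sw, rcond=None)
        return A, E

    def residual(log_lam):
        A, E = solve_amplitudes(np.exp(log_lam))
        return (E @ A - yp) * sw

    rng = np.random.default_rng(seed)
    # log-spaced base rates spanning fast bolus clearance to slow washout
    base = np.log(np.array([3.0, 0.3, 0.02])[:n_exp])
    best = None
    for k in range(n_starts):
        jitter = rng.normal(scale=0.5, size=n_exp) if k else np.zeros(n_exp)
        x0 = base + jitter
        try:
            sol = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14,
                                max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitError("tri-exponential fit failed for every initialization")
    rss, log_lam = best
    lam = np.exp(log_lam)
    A, _ = solve_amplitudes(lam)
    return TriExpFit(A, lam, t_peak, rss=rss)
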