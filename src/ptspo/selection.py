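"""Bootstrap-stabilized stepwise feature selection by model deviance.

A bidirectional stepwise search (enter if the deviance-drop test against
chi-square(1) has p < p_enter, remove if p > p_remove) is repeated on
subject-level bootstrap resamples; only features selected in strictly more
than ``freq_threshold`` of the iterations are retained. Resampling moves all
of a subject's ROI rows together because rows within a subject share
covariates and are therefore correlated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import CollinearityError, FitError, InsufficientDataError
from .model import TSPOLogit

__all__ = ["SelectionReport", "stepwise_deviance", "bootstrap_selection"]

log = logging.getLogger(__name__)

#: Small ridge used inside stepwise candidate fits so that transient
#: separation in a resample cannot abort the search; at this magnitude the
#: deviance is indistinguishable from the unpenalized one for testing.
_STEP_RIDGE = 1e-6


def _fit_deviance(design: pd.DataFrame, features: list[str]) -> float | None:
    rows = design[design["outcome"].notna()]
    y = rows["outcome"].to_numpy()
    X = rows[features].to_numpy(float) if features else np.empty((len(rows), 0))
    try:
        model = TSPOLogit(y, X, feature_names=features)
        return model.fit(ridge=_STEP_RIDGE).deviance
    except (CollinearityError, FitError, np.linalg.LinAlgError):
        return None


def stepwise_deviance(design: pd.DataFrame, scope: list[str],
                      p_enter: float = 0.05, p_remove: float = 0.10,
                      forward_only: bool = False, max_steps: int = 100,
                      ) -> list[str]:
    """Deviance-criterion stepwise selection from the intercept-only model.

    Deterministic given the design. Candidates whose fit is non-identifiable
    (e.g. a duplicate of an already-entered column) are skipped with a log
    entry, so exactly one member of a duplicated pair can enter.
    """
    rows = design[design["outcome"].notna()]
    if rows["outcome"].nunique() < 2:
        raise InsufficientDataError("stepwise selection needs both outcome classes")
    selected: list[str] = []
    dev = _fit_deviance(design, selected)
    for _ in range(max_steps):
        changed = False
        # forward sweep
        best = None
        for cand in scope:
            if cand in selected:
                continue
            dnew = _fit_deviance(design, selected + [cand])
            if dnew is None:
                log.info("stepwise: skipping non-identifiable candidate %r", cand)
                continue
            drop = dev - dnew
            if best is None or drop > best[1]:
                best = (cand, drop, dnew)
        if best is not None:
            cand, drop, dnew = best
            if chi2.sf(max(drop, 0.0), df=1) < p_enter:
                selected.append(cand)
                dev = dnew
                changed = True
        # backward sweep
        if not forward_only and selected:
            worst = None
            for cand in selected:
                reduced = [f for f in selected if f != cand]
                dnew = _fit_deviance(design, reduced)
                if dnew is None:
                    continue
                rise = dnew - dev
                if worst is None or rise < worst[1]:
                    worst = (cand, rise, dnew)
            if worst is not None:
                cand, rise, dnew = worst
                if chi2.sf(max(rise, 0.0), df=1) > p_remove:
                    selected.remove(cand)
                    dev = dnew
                    changed = True
        if not changed:
            break
    return selected


@dataclass
class SelectionReport:
    """Per-feature bootstrap selection frequencies and the retained set."""

    frequencies: pd.Series
    threshold: float
    n_iterations: int
    n_skipped: int
    seed: int
    per_iteration: list[list[str]] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        # strict inequality: a feature at exactly the threshold is dropped
        return [f for f, v in self.frequencies.items() if v > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        df = self.frequencies.rename("frequency").rename_axis("feature").reset_index()
        df["retained"] = df["frequency"] > self.threshold
        return df


def bootstrap_selection(design: pd.DataFrame, scope: list[str],
                        n_iter: int = 100, freq_threshold: float = 0.80,
                        seed: int = 0, p_enter: float = 0.05,
                        p_remove: float = 0.10, forward_only: bool = False,
                        ) -> SelectionReport:
    """Stepwise selection on ``n_iter`` subject-level bootstrap resamples.

    Iterations whose resample contains a single outcome class are skipped and
    counted; a warning is emitted if more than 10% are skipped.
    """
    if n_iter < 1:
        raise InsufficientDataError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = np.asarray(sorted(design["subject_id"].unique()))
    by_subject = dict(tuple(design.groupby("subject_id", sort=True)))
    counts = pd.Series(0.0, index=pd.Index(scope, name="feature"))
    per_iteration: list[list[str]] = []
    n_skipped = 0
    for _ in range(n_iter):
        draw = rng.choice(subjects, size=subjects.size, replace=True)
        boot = pd.concat([by_subject[s] for s in draw], ignore_index=True)
        labelled = boot[boot["outcome"].notna()]
        if labelled["outcome"].nunique() < 2:
            n_skipped += 1
            per_iteration.append([])
            continue
        chosen = stepwise_deviance(boot, scope, p_enter=p_enter,
                                   p_remove=p_remove, forward_only=forward_only)
        per_iteration.append(chosen)
        counts[chosen] += 1
    n_used = n_iter - n_skipped
    if n_used == 0:
        raise InsufficientDataError("every bootstrap resample lacked an outcome class")
    if n_skipped > 0.10 * n_iter:
        warnings.warn(f"{n_skipped}/{n_iter} bootstrap iterations skipped "
                      "(single-class resamples)", stacklevel=2)
    return SelectionReport(frequencies=counts / n_used, threshold=freq_threshold,
                           n_iterations=n_iter, n_skipped=n_skipped, seed=seed,
                           per_iteration=per_iteration)
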