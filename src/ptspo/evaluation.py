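"""Evaluation battery for p_TSPO quantification.

Contains the classification ROC, the relative-probability histogram /
deviation-distribution machinery with the Delta_P summary, Wilcoxon group
tests, test-retest ICC, concordance of mean p_TSPO with the regional
expression map, Benjamini-Hochberg FDR, and the hemispheric TAC-AUC screen
used to pick training ROIs in the rat endotoxin experiment.

Delta_P is the percent excess relative probability of p_TSPO above 0.5 in
the case group versus controls: with relative-frequency histograms h_case
and h_ctrl on [0, 1],

    Delta_P = 100 * sum_{bins with lower edge >= 0.5} (h_case - h_ctrl).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InsufficientDataError, PTSPOError
from .io import ExpressionMap, RegionalTAC

__all__ = ["RocCurve", "roc_analysis", "GroupComparison", "delta_p",
           "group_test", "TestResult", "icc_absolute_agreement",
           "icc_test_retest", "expression_concordance",
           "hemispheric_auc_screen", "fdr_adjust"]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Threshold sweep of a binary classifier based on a continuous score."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def operating_point(self, threshold: float = 0.5) -> tuple[float, float]:
        """(sensitivity, specificity) of classifying score > threshold."""
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.sensitivity[i]), float(self.specificity[i])

    def youden_point(self) -> tuple[float, float, float]:
        """(threshold, sensitivity, specificity) maximizing sens + spec - 1."""
        j = self.sensitivity + self.specificity - 1
        i = int(np.argmax(j))
        return (float(self.thresholds[i]), float(self.sensitivity[i]),
                float(self.specificity[i]))


def roc_analysis(scores, labels) -> RocCurve:
    """ROC over the unique scores; AUC by trapezoid (equals the
    Mann-Whitney concordance probability, ties counting one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        raise InsufficientDataError("ROC undefined with a single class")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
                    auc=float(_trapezoid_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# group comparison: histograms, Delta_P, Wilcoxon
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    name: str            # 'rank-sum' | 'signed-rank' | 't-paired' ...
    statistic: float
    p_value: float


def group_test(cohort_a, cohort_b, paired: bool = False) -> TestResult:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) two-sided test.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise (scipy's 'auto' policy,
    which switches at n = 25 for the signed-rank and n = 8 per group for
    the rank-sum test... the exact method is requested explicitly below for
    <= 25 per group when no ties are present).
    """
    a = np.asarray(cohort_a, dtype=float)
    b = np.asarray(cohort_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty cohort")
    if paired:
        if a.size != b.size:
            raise PTSPOError("paired test requires equal-length, matched cohorts")
        d = a - b
        if np.allclose(d, 0):
            return TestResult("signed-rank", 0.0, 1.0)
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
        return TestResult("signed-rank", float(res.statistic), float(res.pvalue))
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("rank-sum", float(res.statistic), float(res.pvalue))


@dataclass
class GroupComparison:
    """Case-vs-control comparison of per-ROI p_TSPO distributions."""

    bin_edges: np.ndarray
    hist_case: np.ndarray       # relative probability, sums to 1
    hist_control: np.ndarray
    deviation: np.ndarray       # case - control per bin, sums to 0
    delta_p: float              # percent
    test: TestResult
    cohens_d: float | None = None
    label: str = ""


def _relative_histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    return counts / values.size


def delta_p(case, control, bin_width: float = 0.05, paired: bool = False,
            label: str = "", with_effect_size: bool = True) -> GroupComparison:
    """Relative-probability histograms, their bin-by-bin deviation
    (case minus control) and the Delta_P percent summary."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InsufficientDataError("empty cohort")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ConfigError("bin width must partition [0, 1] exactly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h_case = _relative_histogram(case, edges)
    h_ctrl = _relative_histogram(control, edges)
    dev = h_case - h_ctrl
    upper = edges[:-1] >= 0.5 - 1e-12   # bins with lower edge >= 0.5
    dp = 100.0 * float(dev[upper].sum())
    test = group_test(case, control, paired=paired)
    d = None
    if with_effect_size:
        sp = np.sqrt(((case.size - 1) * case.var(ddof=1)
                      + (control.size - 1) * control.var(ddof=1))
                     / max(case.size + control.size - 2, 1))
        d = float((case.mean() - control.mean()) / sp) if sp > 0 else np.nan
    return GroupComparison(edges, h_case, h_ctrl, dev, dp, test, d, label)


# ---------------------------------------------------------------------------
# test-retest ICC
# ---------------------------------------------------------------------------

def icc_absolute_agreement(test, retest) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measure intraclass
    correlation from the mean-squares decomposition of an n x 2 table.

    Returns NaN (flagged, never fabricated) when the decomposition is
    degenerate (zero between-subject variance).
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("ICC needs at least 2 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_test_retest(test_table: pd.DataFrame, retest_table: pd.DataFrame,
                    value_col: str = "p_tspo", icc_threshold: float = 0.7,
                    ) -> tuple[pd.DataFrame, float]:
    """Per-ROI ICC(A,1) between matched test and retest p_TSPO tables
    (columns subject_id, roi_id, ``value_col``) and the fraction of ROIs at
    or above ``icc_threshold``. ROIs with a degenerate decomposition carry
    ICC NaN and are excluded from the summary fraction."""
    t = test_table.set_index(["subject_id", "roi_id"])[value_col]
    r = retest_table.set_index(["subject_id", "roi_id"])[value_col]
    common = t.index.intersection(r.index)
    if common.empty:
        raise InsufficientDataError("no matched (subject, ROI) pairs")
    t, r = t[common], r[common]
    records = []
    for roi in sorted({roi for _, roi in common}):
        sel = [ix for ix in common if ix[1] == roi]
        records.append({"roi_id": roi, "n_subjects": len(sel),
                        "icc": icc_absolute_agreement(t[sel].to_numpy(),
                                                      r[sel].to_numpy())})
    df = pd.DataFrame(records)
    valid = df["icc"].dropna()
    if valid.empty:
        raise InsufficientDataError("ICC undefined for every ROI")
    fraction = float((valid >= icc_threshold).mean())
    return df, fraction


# ---------------------------------------------------------------------------
# expression concordance
# ---------------------------------------------------------------------------

def expression_concordance(mean_ptspo: pd.Series | dict,
                           expression: ExpressionMap,
                           method: str = "spearman") -> tuple[float, float]:
    """Rank correlation between across-subject mean p_TSPO per ROI and the
    regional expression score, over the ROIs common to both."""
    if isinstance(mean_ptspo, dict):
        mean_ptspo = pd.Series(mean_ptspo)
    common = sorted(set(mean_ptspo.index) & set(expression.scores))
    if len(common) < 5:
        raise InsufficientDataError(
            f"need >= 5 common ROIs for concordance, have {len(common)}")
    p = mean_ptspo[common].to_numpy(float)
    e = np.array([expression.scores[r] for r in common])
    if method == "spearman":
        rho, pval = stats.spearmanr(p, e)
    elif method == "pearson":
        rho, pval = stats.pearsonr(p, e)
    else:
        raise ConfigError(f"unknown correlation method {method!r}")
    return float(rho), float(pval)


# ---------------------------------------------------------------------------
# FDR and the rat hemispheric screen
# ---------------------------------------------------------------------------

def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise PTSPOError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def tac_auc(tac: RegionalTAC) -> float:
    """Trapezoidal area under the TAC against frame mid-times."""
    return float(np.trapezoid(tac.activity, tac.schedule.mid_times))


def hemispheric_auc_screen(ipsi_tacs: dict[str, list[RegionalTAC]],
                           contra_tacs: dict[str, list[RegionalTAC]],
                           q: float = 0.05) -> pd.DataFrame:
    """Training-ROI screen for the focal-lesion (intracerebral endotoxin)
    animals: per homologous ROI pair, paired t-test of the per-animal TAC
    AUC between hemispheres, then BH-FDR. Significant ROIs become the
    high-expression (ipsilateral) / low-expression (contralateral) training
    classes.

    ``ipsi_tacs``/``contra_tacs`` map a base ROI name to the per-animal SUV
    TACs of that ROI in each hemisphere, in matched animal order.
    """
    rois = sorted(set(ipsi_tacs) & set(contra_tacs))
    skipped = sorted(set(ipsi_tacs) ^ set(contra_tacs))
    if skipped:
        warnings.warn(f"unpaired ROIs excluded from the screen: {skipped}",
                      stacklevel=2)
    records = []
    for roi in rois:
        ai = np.array([tac_auc(t) for t in ipsi_tacs[roi]])
        ac = np.array([tac_auc(t) for t in contra_tacs[roi]])
        if ai.size != ac.size:
            raise PTSPOError(f"ROI {roi}: unmatched animal counts across hemispheres")
        if ai.size < 3:
            raise InsufficientDataError("hemispheric screen needs >= 3 animals")
        if np.allclose(ai, ac):
            t_stat, p = 0.0, 1.0   # identical hemispheres: nothing to select
        else:
            t_stat, p = stats.ttest_rel(ai, ac)
        records.append({"roi_id": roi, "auc_ipsi": ai.mean(), "auc_contra": ac.mean(),
                        "t": float(t_stat), "p": float(p)})
    df = pd.DataFrame(records)
    p_adj, reject = fdr_adjust(df["p"].to_numpy(), q=q)
    df["p_fdr"] = p_adj
    df["selected"] = reject
    return df
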