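"""ROC, Delta_P, Wilcoxon wrappers, ICC, concordance, FDR and the
hemispheric screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptspo import (RegionalTAC, delta_p, expression_concordance, fdr_adjust,
                   group_test, hemispheric_auc_screen, icc_absolute_agreement,
                   icc_test_retest, roc_analysis)
from ptspo.errors import InsufficientDataError, PTSPOError
from ptspo.io import ExpressionMap
from ptspo.schedule import FrameSchedule

from .oracles import concordance_auc


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0
        thr, sens, spec = roc.youden_point()
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 50)
        # ties on purpose: quantized scores
        scores = np.round(rng.random(50) + 0.4 * labels, 1)
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(concordance_auc(scores, labels),
                                        abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 4000)
        scores = rng.random(4000)
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 60)
        scores = rng.normal(size=60) + labels
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(InsufficientDataError):
            roc_analysis([0.1, 0.2], [1, 1])

    def test_sensitivity_monotone_and_endpoints(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 30)
        scores = rng.normal(size=30) + 0.5 * labels
        roc = roc_analysis(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert roc.sensitivity[0] == 0.0 and roc.sensitivity[-1] == 1.0


class TestDeltaP:
    def test_identical_cohorts_zero(self):
        x = np.linspace(0, 1, 40)
        cmp = delta_p(x, x)
        assert cmp.delta_p == 0.0
        assert cmp.hist_case.sum() == pytest.approx(1.0, abs=1e-12)
        assert cmp.deviation.sum() == pytest.approx(0.0, abs=1e-12)

    def test_full_displacement_is_plus_minus_100(self):
        hi, lo = np.full(30, 0.9), np.full(30, 0.1)
        assert delta_p(hi, lo).delta_p == pytest.approx(100.0)
        assert delta_p(lo, hi).delta_p == pytest.approx(-100.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry_under_cohort_swap(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(25), rng.random(35)
        assert delta_p(a, b).delta_p == pytest.approx(-delta_p(b, a).delta_p,
                                                      abs=1e-12)

    def test_bin_width_must_partition_unit_interval(self):
        from ptspo.errors import ConfigError
        with pytest.raises(ConfigError):
            delta_p([0.5], [0.5], bin_width=0.07)

    def test_boundary_bin_convention(self):
        """Mass exactly at 0.5 counts toward the upper (>= 0.5) bins."""
        assert delta_p(np.full(10, 0.5), np.full(10, 0.45)).delta_p == \
            pytest.approx(100.0)


class TestGroupTest:
    def test_identical_paired_cohorts_p_one(self):
        x = np.linspace(0.1, 0.9, 12)
        res = group_test(x, x, paired=True)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_rank_sum_small_sample(self):
        res = group_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0          # U statistic, complete reversal
        assert res.p_value == pytest.approx(0.1)  # 2/20 label assignments

    def test_shifted_cohorts_detected(self):
        rng = np.random.default_rng(12)
        a = rng.normal(1.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        assert group_test(a, b).p_value < 0.01
        assert group_test(a, b, paired=True).p_value < 0.01

    def test_paired_requires_matched_lengths(self):
        with pytest.raises(PTSPOError):
            group_test([1, 2, 3], [1, 2], paired=True)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        assert icc_absolute_agreement(x, x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(21)
        a, b = rng.random(4000), rng.random(4000)
        assert abs(icc_absolute_agreement(a, b)) < 0.05

    def test_matches_mean_squares_oracle(self):
        """Hand-computed two-way ANOVA decomposition on a fixed 2 x 10 table."""
        rng = np.random.default_rng(33)
        t = rng.random(10)
        r = t + rng.normal(0, 0.1, 10) + 0.05
        x = np.column_stack([t, r])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2
               ).sum() / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute_agreement(t, r) == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(41)
        t = rng.random(15)
        r = 0.8 * t + rng.normal(0, 0.05, 15)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(15), 2),
            "rater": np.repeat(["test", "retest"], 15),
            "score": np.concatenate([t, r])})
        icc_table = pingouin.intraclass_corr(df, targets="subject",
                                             raters="rater", ratings="score")
        ref = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc_absolute_agreement(t, r) == pytest.approx(ref, abs=1e-8)

    def test_degenerate_table_flagged_not_fabricated(self):
        assert np.isnan(icc_absolute_agreement(np.zeros(5), np.zeros(5)))

    def test_per_roi_summary_fraction(self):
        rng = np.random.default_rng(51)
        rows = []
        for roi, rel in (("good", 0.01), ("bad", 10.0)):
            base = rng.random(12)
            for i, v in enumerate(base):
                rows.append({"subject_id": f"s{i}", "roi_id": roi, "p_tspo": v})
        test = pd.DataFrame(rows)
        retest = test.copy()
        retest["p_tspo"] = retest["p_tspo"] + rng.normal(
            0, np.where(retest["roi_id"] == "good", 0.01, 10.0))
        table, frac = icc_test_retest(test, retest)
        assert set(table["roi_id"]) == {"good", "bad"}
        assert frac == pytest.approx(0.5)


class TestConcordanceAndFdr:
    def test_monotone_transform_of_expression(self):
        emap = ExpressionMap({f"r{i}": float(i) for i in range(8)})
        mean_p = pd.Series({f"r{i}": 1 / (1 + np.exp(-i)) for i in range(8)})
        rho, _ = expression_concordance(mean_p, emap)
        assert rho == pytest.approx(1.0)
        rev = pd.Series({f"r{i}": -float(i) for i in range(8)})
        assert expression_concordance(rev, emap)[0] == pytest.approx(-1.0)

    def test_too_few_rois(self):
        emap = ExpressionMap({"a": 1.0, "b": 2.0})
        with pytest.raises(InsufficientDataError):
            expression_concordance(pd.Series({"a": 0.1, "b": 0.2}), emap)

    def test_bh_stepup_arithmetic(self):
        p_adj, reject = fdr_adjust([0.01, 0.02, 0.03], q=0.05)
        assert reject.all()          # 0.03 <= (3/3) * 0.05
        p_adj, reject = fdr_adjust([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()
        p_adj, reject = fdr_adjust([0.03], q=0.05)
        assert p_adj[0] == pytest.approx(0.03)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(PTSPOError):
            fdr_adjust([0.5, 1.2])

    def test_adjusted_values_monotone_in_raw(self):
        rng = np.random.default_rng(61)
        p = np.sort(rng.random(30))
        p_adj, _ = fdr_adjust(p)
        assert np.all(np.diff(p_adj) >= -1e-12)


class TestHemisphericScreen:
    def _tacs(self, values, n_animals=4):
        sched = FrameSchedule.from_durations([1.0] * 6)
        return [RegionalTAC("r", f"a{i}", sched, np.full(6, v))
                for i, v in zip(range(n_animals), values)]

    def test_identical_hemispheres_select_nothing(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        ipsi = {"cortex": self._tacs(vals), "thalamus": self._tacs(vals)}
        contra = {"cortex": self._tacs(vals), "thalamus": self._tacs(vals)}
        screen = hemispheric_auc_screen(ipsi, contra)
        assert not screen["selected"].any()

    def test_elevated_roi_detected(self):
        base = [1.0, 1.1, 0.9, 1.05]
        up = [3.0, 3.2, 2.9, 3.1]
        ipsi = {"lesion": self._tacs(up), "spared": self._tacs(base)}
        contra = {"lesion": self._tacs(base), "spared": self._tacs(base)}
        screen = hemispheric_auc_screen(ipsi, contra).set_index("roi_id")
        assert bool(screen.loc["lesion", "selected"])
        assert not bool(screen.loc["spared", "selected"])

    def test_single_animal_is_precondition_error(self):
        ipsi = {"cortex": self._tacs([1.0], n_animals=1)}
        contra = {"cortex": self._tacs([1.0], n_animals=1)}
        with pytest.raises(InsufficientDataError):
            hemispheric_auc_screen(ipsi, contra)

    def test_unpaired_roi_excluded_with_warning(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        ipsi = {"cortex": self._tacs(vals), "extra": self._tacs(vals)}
        contra = {"cortex": self._tacs(vals)}
        with pytest.warns(UserWarning, match="unpaired"):
            screen = hemispheric_auc_screen(ipsi, contra)
        assert list(screen["roi_id"]) == ["cortex"]
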