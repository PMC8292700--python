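"""QA orchestration: classification rules, report contents, cohort stats."""

import numpy as np
import pytest

from conftest import ARC_SECONDS
from vmatqa import (JitterSpec, QaLimits, QaReport, classify, cohort_stats,
                    ontreatment_qa, pearson_category, pretreatment_qa,
                    simulate_delivery)
from vmatqa.dose_engine import EngineConfig, compute_dose
from vmatqa.exceptions import ValidationError
from vmatqa.qa_pipeline import (GAMMA_VOLUMES, REPORT_METRICS,
                                default_qa_config, default_tps_config)


def _report(gpr, dmean):
    return QaReport(
        mode="pretreatment",
        gamma_pct={"overall": gpr, "PTV": gpr, "rectum": gpr, "bladder": gpr},
        metric_diff_pct={"PTV": {"Dmean": dmean}},
        metrics_reference={}, metrics_evaluated={},
        prescription_gy=2.0, passed=False, reasons=[])


class TestClassify:
    @pytest.mark.parametrize("gpr,dmean,expect_pass,expect_reason", [
        (89.9, 0.1, False, "GPR"),       # below the 90% pass limit
        (95.0, 2.1, False, "Dmean"),     # beyond the 2% dose tolerance
        (90.0, 2.0, True, None),         # boundaries are inclusive
        (100.0, 0.0, True, None),
        (89.0, -3.0, False, None),       # both rules violated
    ])
    def test_limit_rules(self, gpr, dmean, expect_pass, expect_reason):
        passed, reasons = classify(_report(gpr, dmean), QaLimits())
        assert passed is expect_pass
        if expect_reason:
            assert any(expect_reason in r for r in reasons)
        if gpr < 90.0 and abs(dmean) > 2.0:
            assert len(reasons) == 2  # every violated rule is listed


class TestPretreatmentQa:
    def test_self_comparison_is_perfect_pass(self, demo_plan, phantom,
                                             structures, fast_cfg, demo_dose):
        report = pretreatment_qa(demo_plan, phantom, structures, demo_dose,
                                 cfg=fast_cfg)
        assert report.passed
        for key in ("overall", *GAMMA_VOLUMES):
            assert report.gamma_pct[key] == 100.0
        for roi, metrics in report.metric_diff_pct.items():
            for name, diff in metrics.items():
                assert diff == 0.0, (roi, name)

    def test_report_carries_the_clinical_metric_set(self, demo_plan, phantom,
                                                    structures, fast_cfg,
                                                    demo_dose):
        report = pretreatment_qa(demo_plan, phantom, structures, demo_dose,
                                 cfg=fast_cfg)
        assert set(report.metric_diff_pct) == set(REPORT_METRICS)
        for roi, names in REPORT_METRICS.items():
            assert tuple(report.metric_diff_pct[roi]) == names

    def test_independent_recalculation_passes_on_default_fixture(
            self, demo_plan, phantom, structures):
        tps = default_tps_config(4.0, seed=0, mu_samples=96)
        qa = default_qa_config(4.0, seed=1, mu_samples=96)
        reference = compute_dose(demo_plan, phantom, tps)
        report = pretreatment_qa(demo_plan, phantom, structures, reference,
                                 cfg=qa)
        assert report.passed
        assert report.gamma_pct["overall"] >= 90.0
        assert abs(report.ptv_dmean_diff_pct) <= 2.0


class TestOntreatmentQa:
    def test_zero_jitter_closure_matches_pretreatment_self_check(
            self, demo_plan, phantom, structures, fast_cfg, demo_dose,
            zero_jitter):
        log = simulate_delivery(demo_plan, zero_jitter, ARC_SECONDS)
        report = ontreatment_qa(demo_plan, log, phantom, structures,
                                demo_dose, cfg=fast_cfg)
        assert report.passed
        assert report.gamma_pct["overall"] == 100.0
        for roi, metrics in report.metric_diff_pct.items():
            for name, diff in metrics.items():
                assert abs(diff) < 0.01, (roi, name)

    def test_jittered_delivery_still_passes_and_tracks_pretreatment(
            self, demo_plan, phantom, structures):
        """Tolerance-bounded jitter perturbs the delivered dose by well
        under the gamma criteria, so on-treatment GPR stays within a
        whisker of (and statistically below) the pretreatment GPR."""
        tps = default_tps_config(4.0, seed=0, mu_samples=96)
        qa = default_qa_config(4.0, seed=1, mu_samples=96)
        reference = compute_dose(demo_plan, phantom, tps)
        pre = pretreatment_qa(demo_plan, phantom, structures, reference,
                              cfg=qa)
        gprs = []
        for seed in range(3):
            log = simulate_delivery(demo_plan, JitterSpec(seed=seed),
                                    ARC_SECONDS)
            on = ontreatment_qa(demo_plan, log, phantom, structures,
                                reference, cfg=qa)
            assert on.passed
            gprs.append(on.gamma_pct["overall"])
        assert np.mean(gprs) <= pre.gamma_pct["overall"] + 0.25

    def test_pure_jitter_degradation_is_bounded_but_nonzero(
            self, demo_plan, phantom, fast_cfg, demo_dose):
        log = simulate_delivery(demo_plan, JitterSpec(seed=4), ARC_SECONDS)
        from vmatqa import log_to_plan
        delivered = compute_dose(log_to_plan(log, demo_plan), phantom,
                                 fast_cfg)
        dev = np.abs(delivered.dose - demo_dose.dose).max()
        assert 0.0 < dev < 0.01 * demo_dose.dose.max()


class TestCohortStats:
    def _degenerate_reports(self, n=4):
        return [_report(99.0, 0.5) for _ in range(n)]

    def test_identical_paired_samples_reported_degenerate(self):
        pre = self._degenerate_reports()
        on = self._degenerate_reports()
        summary = cohort_stats(pre, on)
        row = summary.table.loc["gpr_overall"]
        assert np.isnan(row.p_value)
        assert row.r_category == "degenerate"
        assert row.pre_mean == row.on_mean == 99.0

    def test_varying_cohort_gets_p_and_r(self):
        rng = np.random.default_rng(3)
        pre = [_report(97.0 + rng.uniform(0, 2), 0.5 + rng.uniform(0, 0.5))
               for _ in range(8)]
        on = [_report(r.gamma_pct["overall"] - rng.uniform(0, 0.5),
                      r.metric_diff_pct["PTV"]["Dmean"] + rng.uniform(0, 0.1))
              for r in pre]
        summary = cohort_stats(pre, on)
        row = summary.table.loc["gpr_overall"]
        assert 0.0 <= row.p_value <= 1.0
        assert row.pearson_r > 0.9
        assert row.r_category == "strong"

    def test_wilcoxon_alternative_runs(self):
        rng = np.random.default_rng(4)
        pre = [_report(97.0 + rng.uniform(0, 2), 0.5) for _ in range(6)]
        on = [_report(r.gamma_pct["overall"] - rng.uniform(0.1, 0.5), 0.5)
              for r in pre]
        summary = cohort_stats(pre, on, method="wilcoxon")
        assert summary.method == "wilcoxon"
        assert 0.0 <= summary.table.loc["gpr_overall"].p_value <= 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cohort_stats(self._degenerate_reports(4),
                         self._degenerate_reports(3))

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValidationError):
            cohort_stats(self._degenerate_reports(2),
                         self._degenerate_reports(2))


class TestPearsonCategories:
    @pytest.mark.parametrize("r,category", [
        (0.39, "weak"), (0.40, "moderate"), (0.70, "moderate"),
        (0.71, "strong"), (0.97, "strong"), (-0.5, "moderate"),
        (float("nan"), "degenerate"),
    ])
    def test_category_boundaries(self, r, category):
        assert pearson_category(r) == category
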