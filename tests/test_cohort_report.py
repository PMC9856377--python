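"""Group statistics and pipeline orchestration tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epibarrier import (
    ValidationError,
    analyze_cohort,
    default_config,
    run_pipeline,
    significance_label,
    simulate_cohort,
    ttest_from_summary,
    two_group_ttest,
)


class TestTwoGroupTtest:
    def test_identical_groups(self):
        c = two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t_statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)
        assert c.label == "n.s."

    def test_baseline_isc_summaries_pooled(self):
        # printed group summaries: pooled t ~ 1.95, p ~ 0.072 on df = 14
        c = ttest_from_summary(138, 75, 10, 74, 35, 6)
        assert c.t_statistic == pytest.approx(1.9466, abs=2e-3)
        assert c.p_value == pytest.approx(0.072, abs=2e-3)
        assert c.label == "n.s."

    def test_widely_separated_groups_three_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        c = two_group_ttest(a, b)
        assert c.p_value < 0.001
        assert c.label == "***"

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(2, 20, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n1)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n2)
            ours = two_group_ttest(a, b, variant="pooled")
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-8)
            ours_w = two_group_ttest(a, b, variant="welch")
            ref_w = stats.ttest_ind(a, b, equal_var=False)
            assert ours_w.t_statistic == pytest.approx(ref_w.statistic, abs=1e-10)
            assert ours_w.p_value == pytest.approx(ref_w.pvalue, abs=1e-8)

    def test_summary_path_matches_raw_path(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 2, 12)
        b = rng.normal(4, 1, 8)
        raw = two_group_ttest(a, b)
        summ = ttest_from_summary(a.mean(), a.std(ddof=1), a.size,
                                  b.mean(), b.std(ddof=1), b.size)
        assert summ.t_statistic == pytest.approx(raw.t_statistic, abs=1e-12)
        assert summ.p_value == pytest.approx(raw.p_value, abs=1e-12)

    def test_degenerate_zero_sd_distinct_means(self):
        c = ttest_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert c.p_value == 0.0
        assert c.label == "***"

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            two_group_ttest([1.0], [1.0, 2.0])

    @settings(max_examples=100, derandomize=True)
    @given(p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_label_thresholds_consistent(self, p):
        label = significance_label(p)
        if p < 0.001:
            assert label == "***"
        elif p < 0.01:
            assert label == "**"
        elif p < 0.05:
            assert label == "*"
        else:
            assert label == "n.s."


@pytest.fixture(scope="module")
def report():
    cohort, _ = simulate_cohort(default_config(seed=7), include_de=True)
    return analyze_cohort(cohort)


class TestPipeline:
    def test_all_metrics_reported(self, report):
        metrics = set(report.comparisons["metric"])
        assert {"baseline_isc", "delta_isc_bumetanide", "j_na", "r_epi",
                "p_fluorescein", "p_fd4", "ttj_ratio", "surface_ratio",
                "apoptosis_rate"} <= metrics

    def test_directional_pattern_of_study_conditions(self, report):
        """Lower Cl- secretion, unchanged R_epi/J_Na, higher permeability."""
        bum = report.comparison("delta_isc_bumetanide")
        assert bum["mean_ibsm"] < bum["mean_control"]
        assert bum["p_value"] < 0.05
        fluo = report.comparison("p_fluorescein")
        assert fluo["mean_ibsm"] > fluo["mean_control"]
        assert report.comparison("r_epi")["p_value"] >= 0.05
        assert report.comparison("j_na")["p_value"] >= 0.05

    def test_labels_consistent_with_p(self, report):
        for _, row in report.comparisons.iterrows():
            assert row["label"] == significance_label(row["p_value"])

    def test_regulator_table_present(self, report):
        assert report.regulators is not None
        assert (report.regulators["overlap_p"].diff().dropna() >= 0).all()

    def test_summary_renders(self, report):
        text = report.summary()
        assert "delta_isc_bumetanide" in text
        assert "upstream regulators" in text

    def test_report_written_to_disk(self, tmp_path, report):
        out = report.write(tmp_path / "report")
        assert (out / "metrics_per_subject.tsv").exists()
        assert (out / "group_comparisons.tsv").exists()
        assert (out / "summary.json").exists()

    def test_run_pipeline_from_directory(self, tmp_path):
        cohort, _ = simulate_cohort(default_config(seed=3, n_control=4, n_ibsm=4),
                                    out_dir=tmp_path / "cohort", include_de=False)
        report = run_pipeline(tmp_path / "cohort", out_dir=tmp_path / "out")
        assert (tmp_path / "out" / "group_comparisons.tsv").exists()
        # loaded-from-disk analysis equals in-memory analysis
        mem = analyze_cohort(cohort)
        pd.testing.assert_frame_equal(
            report.comparisons, mem.comparisons, rtol=1e-5, atol=1e-12
        )

    def test_empty_cohort_directory_reports_nothing(self, tmp_path):
        d = tmp_path / "empty"
        (d / "subjects").mkdir(parents=True)
        report = run_pipeline(d)
        assert len(report.metrics) == 0
        assert len(report.comparisons) == 0

    def test_missing_modality_skips_metric_not_run(self, tmp_path):
        cohort, _ = simulate_cohort(default_config(seed=5, n_control=3, n_ibsm=3),
                                    include_de=False)
        for s in cohort.subjects:
            s.spectrum = None  # no impedance files for anyone
        report = analyze_cohort(cohort)
        assert "r_epi" not in set(report.comparisons["metric"])
        assert "baseline_isc" in set(report.comparisons["metric"])
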