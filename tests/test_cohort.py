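"""Cohort generator and full association analysis."""

import numpy as np
import pandas as pd
import pytest

from gratiokit.analysis import AnalysisConfig, run_full_analysis, stratify_patients
from gratiokit.cohort import CohortConfig, cohort_from_stratum_counts, simulate_cohort
from gratiokit.stats import elevated_nfl_threshold, spearman_rho


class TestSimulateCohort:
    def test_schema_and_determinism(self):
        a = simulate_cohort(20, 15, seed=5)
        b = simulate_cohort(20, 15, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["group"] == "patient").sum() == 20
        assert (a["group"] == "control").sum() == 15
        pat = a[a.group == "patient"]
        assert ((pat.g_wml > 0) & (pat.g_wml < 1)).all()
        assert (pat.lesion_vol_pct_icv >= 0).all()
        assert (a.nfl_pg_ml > 0).all()

    def test_nonpositive_counts_raise(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 10)
        with pytest.raises(ValueError):
            simulate_cohort(10, -1)

    def test_null_configuration(self):
        """Zero dependence coefficients: no patient/control NfL difference in
        expectation and near-zero NfL-volume correlation at n = 500."""
        cfg = CohortConfig(beta_volume=0.0, beta_gratio=0.0, patient_nfl_log_sd=0.45)
        c = simulate_cohort(500, 500, config=cfg, seed=13)
        pat = c[c.group == "patient"]
        ctl = c[c.group == "control"]
        # same log-normal in expectation
        assert np.log(pat.nfl_pg_ml).mean() == pytest.approx(
            np.log(ctl.nfl_pg_ml).mean(), abs=0.1
        )
        rho = spearman_rho(pat.lesion_vol_pct_icv, pat.nfl_pg_ml).statistic
        assert abs(rho) < 0.1

    def test_volume_only_association(self):
        """beta_volume > 0, beta_gratio = 0: NfL correlates with volume but
        not with g beyond its volume coupling (Monte-Carlo over replicates)."""
        cfg = CohortConfig(beta_volume=0.756, beta_gratio=0.0)
        rho_v, rho_g = [], []
        for seed in range(200):
            c = simulate_cohort(60, 10, config=cfg, seed=seed)
            pat = c[c.group == "patient"]
            rho_v.append(spearman_rho(pat.lesion_vol_pct_icv, pat.nfl_pg_ml).statistic)
            rho_g.append(spearman_rho(pat.g_wml, pat.nfl_pg_ml).statistic)
        assert np.mean(rho_v) > 0.3
        assert abs(np.mean(rho_g)) < 0.05

    def test_effect_configuration_structure(self):
        """Default conditions reproduce the qualitative pattern: the volume
        correlation dominates, and the g-ratio/NfL association concentrates
        in the substantial-load stratum."""
        c = simulate_cohort(300, 200, seed=7)
        report = run_full_analysis(c)
        rho_v = report["tests"]["nfl_vs_lesion_volume"]["statistic"]
        rho_g = report["tests"]["nfl_vs_wml_gratio"]["statistic"]
        assert rho_v > rho_g > 0
        f = report["fisher"]["load_threshold_0.5"]
        assert f["substantial_load"]["p_value"] < 0.05
        assert f["substantial_load"]["p_value"] < f["low_load"]["p_value"]


class TestStratification:
    def test_count_fixture_recovers_cells(self):
        """Record-level fixture reproduces the reference contingency tables
        and elevated proportions of 48% and 13%."""
        cohort = cohort_from_stratum_counts()
        ctl = cohort[cohort.group == "control"]
        thr = elevated_nfl_threshold(ctl.nfl_pg_ml.to_numpy())
        tables = stratify_patients(cohort, thr, load_threshold_pct=0.5)
        hi = tables.substantial_load
        lo = tables.low_load
        assert (hi.a, hi.b, hi.c, hi.d) == (11, 12, 2, 13)
        assert (lo.a, lo.b, lo.c, lo.d) == (1, 12, 3, 19)
        assert tables.n_substantial == 38 and tables.n_low == 35
        assert round(100 * hi.a / (hi.a + hi.b)) == 48
        assert round(100 * hi.c / (hi.c + hi.d)) == 13

    def test_sensitivity_thresholds_preserve_result(self):
        """Load cuts of 0.4% and 0.6% keep the substantial-load association."""
        cohort = cohort_from_stratum_counts()
        report = run_full_analysis(cohort)
        for key in ("load_threshold_0.5", "load_threshold_0.4", "load_threshold_0.6"):
            assert report["fisher"][key]["substantial_load"]["p_value"] < 0.05

    def test_median_split_uses_whole_cohort(self):
        """'Normal' is <= the all-patient median, not per-stratum medians."""
        cohort = cohort_from_stratum_counts()
        pat = cohort[cohort.group == "patient"]
        cut = pat.g_wml.median()
        tables = stratify_patients(cohort, nfl_threshold=4.5)
        assert tables.gratio_cut == pytest.approx(cut)
        n_normal = (pat.g_wml <= cut).sum()
        assert tables.low_load.c + tables.low_load.d + tables.substantial_load.c + tables.substantial_load.d == n_normal

    def test_all_low_load_gives_empty_substantial_tables(self):
        cohort = cohort_from_stratum_counts()
        tables = stratify_patients(cohort, nfl_threshold=4.5, load_threshold_pct=1e6)
        hi = tables.substantial_load
        assert (hi.a, hi.b, hi.c, hi.d) == (0, 0, 0, 0)
        assert tables.n_substantial == 0

    def test_cell_totals_sum_to_stratum_counts(self):
        c = simulate_cohort(80, 40, seed=3)
        ctl = c[c.group == "control"]
        thr = elevated_nfl_threshold(ctl.nfl_pg_ml.to_numpy())
        tables = stratify_patients(c, thr)
        lo, hi = tables.low_load, tables.substantial_load
        assert lo.total == tables.n_low
        assert hi.total == tables.n_substantial
        assert lo.total + hi.total == 80


class TestFullAnalysis:
    def test_deterministic_report(self):
        c = simulate_cohort(40, 30, seed=1)
        r1 = run_full_analysis(c)
        r2 = run_full_analysis(c)
        assert r1 == r2

    def test_report_is_json_serialisable_and_complete(self, tmp_path):
        import json

        c = simulate_cohort(40, 30, seed=2)
        r = run_full_analysis(c)
        (tmp_path / "r.json").write_text(json.dumps(r))
        for key in (
            "gratio_wml_vs_nawm_wilcoxon",
            "gratio_wml_vs_nawm_paired_t",
            "nfl_patients_vs_controls",
            "nfl_vs_lesion_volume",
            "nfl_vs_wml_gratio",
        ):
            assert key in r["tests"]
            assert 0 <= r["tests"][key]["p_value"] <= 1
        assert set(r["stratified"]) == {
            "load_threshold_0.5", "load_threshold_0.4", "load_threshold_0.6"
        }
        assert r["software"]["package"] == "gratiokit"

    def test_null_cohort_type_one_behaviour(self):
        """Null configuration: stratified Fisher rejects in <= 10% of runs."""
        cfg = CohortConfig(beta_volume=0.0, beta_gratio=0.0)
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            c = simulate_cohort(73, 63, config=cfg, seed=1000 + seed)
            r = run_full_analysis(c, AnalysisConfig(sensitivity_thresholds_pct=()))
            f = r["fisher"]["load_threshold_0.5"]
            hits += (
                f["substantial_load"]["p_value"] < 0.05 or f["low_load"]["p_value"] < 0.05
            )
        assert hits <= 10

    def test_paired_gratio_difference_detected(self):
        """A +0.036 lesion-NAWM shift at n = 73 is essentially always
        detected by the paired Wilcoxon test (Monte-Carlo)."""
        detected = 0
        for seed in range(50):
            c = simulate_cohort(73, 63, seed=seed)
            pat = c[c.group == "patient"]
            from gratiokit.stats import wilcoxon_signed_rank

            p = wilcoxon_signed_rank(pat.g_wml.to_numpy(), pat.g_nawm.to_numpy()).p_value
            detected += p < 0.001
        assert detected >= 47  # >= 95% of replicates

    def test_component_errors_carry_stage_labels(self):
        cohort = cohort_from_stratum_counts(n_controls=0)
        with pytest.raises(ValueError, match="patients and controls"):
            run_full_analysis(cohort)
        # a failing component surfaces with its stage name
        bad = cohort_from_stratum_counts()
        bad.loc[bad.group == "control", "nfl_pg_ml"] = np.nan
        with pytest.raises(RuntimeError, match="stage"):
            run_full_analysis(bad)

    def test_markdown_rendering(self):
        from gratiokit.analysis import report_to_markdown

        c = simulate_cohort(30, 20, seed=4)
        md = report_to_markdown(run_full_analysis(c))
        assert "Stratified contingency analysis" in md
        assert "Fisher p=" in md
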