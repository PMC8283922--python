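"""Synthetic cohort generator: determinism, structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from handclin import protocols, synthetic_cohort, task_metrics
from handclin.synthetic_cohort import (
    expected_trial_rows,
    export_dataset,
    noiseless_config,
    null_config,
    paper_like_config,
    read_dataset,
    sample_cohort,
    simulate_clinical_scores,
    simulate_dataset,
    simulate_session,
    simulate_session_traces,
    simulate_trials,
    top_k_of_n_normal_mean,
)


class TestCohortSampling:
    def test_same_seed_identical(self, paper_config):
        a = sample_cohort(paper_config, 5)
        b = sample_cohort(paper_config, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_default_counts_match_study_design(self, paper_config):
        df = sample_cohort(paper_config, 1)
        assert (df.group == "stroke").sum() == 30
        assert (df.group == "control").sum() == 31
        assert (df.loc[df.group == "control", "handedness"] == "right").all()
        assert df.loc[df.group == "control", ["s_motor", "s_proprio"]].eq(
            0.0).all().all()

    def test_intact_proprioception_constraint(self, paper_config):
        fracs = []
        for seed in range(40):
            df = sample_cohort(paper_config, seed)
            stroke = df[df.group == "stroke"]
            fracs.append((stroke.kUDT == 2.0).mean())
        assert max(fracs) <= 0.4 + 1e-12

    def test_clinical_score_ranges(self, paper_config):
        df = sample_cohort(paper_config, 3)
        assert df.FMA.between(0, 66).all()
        assert df.kUDT.isin([0.0, 1.0, 2.0]).all()
        assert df.MoCA.between(0, 30).all()
        assert df.MAS.between(0, 6).all()


class TestClinicalMaps:
    def test_intact_motor_gives_high_fma(self, rng):
        scores = [simulate_clinical_scores(0.0, 0.5, rng)["FMA"]
                  for _ in range(100)]
        assert np.mean(np.array(scores) >= 60) > 0.8

    def test_severe_proprioception_gives_kudt_zero(self, rng):
        scores = [simulate_clinical_scores(0.5, 1.0, rng)["kUDT"]
                  for _ in range(100)]
        assert np.mean(np.array(scores) == 0.0) > 0.9

    def test_fma_strongly_anticorrelated_with_motor_severity(self, rng):
        from scipy.stats import spearmanr
        s = rng.uniform(0, 1, 500)
        fma = [simulate_clinical_scores(si, 0.5, rng)["FMA"] for si in s]
        rho = spearmanr(s, fma)[0]
        assert rho < -0.8


class TestTrialSimulation:
    def test_trial_counts_per_task(self, paper_config):
        cohort = sample_cohort(paper_config, 2)
        subject = cohort.iloc[0]
        df = simulate_session(subject, 1, paper_config, seed=2)
        counts = df[df.side == "affected"].groupby("task").size().to_dict()
        assert counts == {"matching": 21, "reaching": 20, "rom": 6,
                          "force": 6, "tracking": 6}

    def test_determinism(self, small_config):
        a = simulate_trials(sample_cohort(small_config, 4), small_config, 4)
        b = simulate_trials(sample_cohort(small_config, 4), small_config, 4)
        pd.testing.assert_frame_equal(a, b)

    def test_row_count_formula(self, small_config):
        subjects, trials = simulate_dataset(small_config, 9)
        assert len(trials) == expected_trial_rows(small_config)

    def test_noiseless_intact_subject_is_perfect(self):
        config = noiseless_config()
        cohort = sample_cohort(config, 1)
        ctrl = cohort[cohort.group == "control"].iloc[0]
        s1 = simulate_session(ctrl, 1, config, seed=1)
        s2 = simulate_session(ctrl, 2, config, seed=1)
        table = task_metrics.extract_metric_table(s1)
        vals = table.set_index(["metric", "side"])["value"]
        for side in ("dominant", "nondominant"):
            assert vals[("AE", side)] == pytest.approx(0.0, abs=1e-12)
            assert vals[("RMSESlow", side)] == pytest.approx(0.0, abs=1e-12)
            assert vals[("RMSEFast", side)] == pytest.approx(0.0, abs=1e-12)
        # session metrics identical without noise or shift (the matching
        # angle order is re-randomized per session by protocol)
        t2 = task_metrics.extract_metric_table(s2)
        pd.testing.assert_frame_equal(
            table.drop(columns="session"), t2.drop(columns="session"))

    def test_affected_side_worse_than_less_affected(self, paper_config):
        """On average the affected side degrades more per severity."""
        cohort = sample_cohort(paper_config, 6)
        stroke = cohort[cohort.group == "stroke"]
        trials = simulate_trials(stroke.head(12), paper_config, 6)
        table = task_metrics.extract_metric_table(trials)
        t1 = table[table.session == 1]
        aff = t1[t1.side == "affected"].groupby("metric")["value"].mean()
        la = t1[t1.side == "less_affected"].groupby("metric")["value"].mean()
        worse_count = 0
        for metric in task_metrics.METRICS:
            if task_metrics.higher_is_worse(metric):
                worse_count += aff[metric] > la[metric]
            else:
                worse_count += aff[metric] < la[metric]
        assert worse_count >= 8

    def test_severity_monotonicity_noise_free(self, paper_config):
        """Expected session values degrade monotonically in severity."""
        grid = np.linspace(0, 1, 11)
        for metric in task_metrics.METRICS:
            vals = [paper_config.expected_metric_value(metric, s)
                    for s in grid]
            diffs = np.diff(vals)
            if task_metrics.higher_is_worse(metric):
                assert np.all(diffs >= -1e-12)
            else:
                assert np.all(diffs <= 1e-12)
            assert vals[0] != vals[-1]  # strictly worse across the full range

    def test_angle_magnitude_effect_on_matching_error(self, paper_config):
        """Larger presented angles produce larger matching errors."""
        cohort = sample_cohort(paper_config, 8)
        stroke = cohort[cohort.group == "stroke"]
        frames = [simulate_session(s, 1, paper_config, seed=8)
                  for _, s in stroke.iterrows()]
        df = pd.concat(frames)
        df = df[df.task == "matching"]
        err = np.abs(df.reported_deg - df.presented_deg)
        low = err[df.presented_deg <= 15].mean()
        high = err[df.presented_deg >= 25].mean()
        assert high > low


class TestCalibration:
    def test_stroke_means_near_targets(self, paper_config):
        """Affected-side session-1 metric means land within 10% of the
        configured targets over 200 simulated stroke subjects."""
        config = paper_like_config(n_stroke=200, n_control=2,
                                   n_sessions_stroke=1)
        subjects, trials = simulate_dataset(config, 13)
        table = task_metrics.extract_metric_table(trials)
        aff = table[(table.side == "affected") & (table.session == 1)]
        means = aff.groupby("metric")["value"].mean()
        for metric, model in config.metrics.items():
            assert means[metric] == pytest.approx(model.stroke_mean,
                                                  rel=0.10), metric

    def test_null_preset_groups_indistinguishable(self):
        """Zero severities with matched confounds: control vs stroke metric
        distributions agree (KS on values pooled over cohorts)."""
        from scipy.stats import ks_2samp
        config = null_config(n_stroke=15, n_control=15,
                             n_sessions_stroke=1)
        ctrl_vals, stroke_vals = {m: [] for m in config.metrics}, \
            {m: [] for m in config.metrics}
        for seed in range(10):
            subjects, trials = simulate_dataset(config, seed)
            table = task_metrics.extract_metric_table(trials)
            t1 = table[table.session == 1]
            groups = subjects.set_index("subject_id")["group"]
            t1 = t1.assign(group=groups.loc[t1.subject_id].to_numpy())
            for m in config.metrics:
                sel = t1[t1.metric == m]
                ctrl_vals[m] += list(sel[sel.group == "control"]["value"])
                stroke_vals[m] += list(sel[sel.group == "stroke"]["value"])
        pvals = [ks_2samp(ctrl_vals[m], stroke_vals[m]).pvalue
                 for m in config.metrics]
        assert min(pvals) > 0.01 / len(pvals)  # Bonferroni-adjusted floor

    def test_top3_debias_constant(self):
        """Order-statistic constant agrees with a direct simulation."""
        rng = np.random.default_rng(0)
        sim = np.sort(rng.normal(0, 1, (200_000, 10)), axis=1)[:, -3:].mean()
        assert top_k_of_n_normal_mean(10, 3) == pytest.approx(sim, abs=0.01)


class TestTraces:
    def test_reaching_trace_realizes_peak(self):
        tr = synthetic_cohort.synthesize_reaching_trace(
            300.0, "extension", 0.12, fs_hz=500.0)
        assert task_metrics.peak_velocity(tr.velocity_degps, "extension") == \
            pytest.approx(300.0, rel=1e-3)
        lo, hi = protocols.WORKSPACE_DEG
        assert tr.position_deg.min() >= lo and tr.position_deg.max() <= hi

    def test_rom_trace_realizes_range(self):
        tr = synthetic_cohort.synthesize_rom_trace(55.0, fs_hz=200.0)
        rom = tr.position_deg.max() - tr.position_deg.min()
        assert rom == pytest.approx(55.0, rel=1e-6)

    def test_force_trace_realizes_plateau(self):
        tr = synthetic_cohort.synthesize_force_trace(9.0, "flexion",
                                                     fs_hz=200.0)
        assert task_metrics.peak_force(tr.force_n, "flexion") == \
            pytest.approx(9.0, rel=1e-9)
        tr = synthetic_cohort.synthesize_force_trace(9.0, "extension",
                                                     fs_hz=200.0)
        assert task_metrics.peak_force(tr.force_n, "extension") == \
            pytest.approx(9.0, rel=1e-9)

    def test_tracking_trial_realizes_rmse(self, paper_config, rng):
        target, response = synthetic_cohort.synthesize_tracking_trial(
            12.0, severity=0.5, speed="slow", rng=rng, config=paper_config,
            fs_hz=50.0)
        rmse = task_metrics.tracking_rmse(target, response)
        assert rmse == pytest.approx(12.0, rel=0.1)

    def test_session_traces_consistent_with_scalars(self, paper_config):
        cohort = sample_cohort(paper_config, 21)
        subject = cohort[cohort.group == "stroke"].iloc[0]
        traces = simulate_session_traces(subject, 1, paper_config, seed=21)
        scalars = simulate_session(subject, 1, paper_config, seed=21,
                                   sides=("affected",))
        assert len(traces["matching"]) == 21
        assert len(traces["reaching"]) == 20
        assert len(traces["rom"]) == 6
        assert len(traces["force"]) == 6
        assert len(traces["tracking"]) == 6
        # per-trial reaching peaks extracted from traces match the scalars
        reach_scalars = scalars[scalars.task == "reaching"]["value"].to_numpy()
        peaks = [task_metrics.peak_velocity(tr.velocity_degps, d)
                 for d, tr in traces["reaching"]]
        np.testing.assert_allclose(peaks, reach_scalars, rtol=1e-3)
        # ROM traces realize the drawn per-rep ranges
        rom_scalars = scalars[scalars.task == "rom"]["value"].to_numpy()
        roms = [tr.position_deg.max() - tr.position_deg.min()
                for _, tr in traces["rom"]]
        np.testing.assert_allclose(roms, rom_scalars, rtol=1e-5)


class TestExport:
    def test_round_trip(self, small_dataset, tmp_path):
        subjects, trials = small_dataset
        export_dataset(subjects, trials, tmp_path)
        s2, t2 = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(subjects.reset_index(drop=True), s2,
                                      check_dtype=False)
        pd.testing.assert_frame_equal(trials.reset_index(drop=True), t2,
                                      check_dtype=False)

    def test_schema_complete(self, small_dataset):
        subjects, trials = small_dataset
        for col in synthetic_cohort.SUBJECT_COLUMNS:
            assert col in subjects.columns
        for col in task_metrics.TRIAL_TABLE_COLUMNS:
            assert col in trials.columns
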