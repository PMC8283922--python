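"""Validity statistics: AUC/Kruskal oracles, confound model, z-scores,
concurrent and partial correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from handclin import validity
from handclin.validity import (
    build_reference,
    classify_and_agree,
    classify_impaired,
    concurrent_correlations,
    correlation_strength,
    fit_confound_model,
    kruskal_bonferroni,
    paired_sides_test,
    partial_spearman,
    roc_auc,
    zscore_worse,
)


def auc_enumeration_oracle(control, patient, higher_worse=True):
    """Pair-by-pair enumeration of P(patient worse) with half ties."""
    total = 0.0
    for c, p in itertools.product(control, patient):
        pc, cc = (p, c) if higher_worse else (-p, -c)
        total += 1.0 if pc > cc else (0.5 if pc == cc else 0.0)
    return total / (len(control) * len(patient))


class TestRocAuc:
    def test_trivial_cases(self):
        assert roc_auc([1, 2, 3], [10, 11, 12], higher_worse=True) == 1.0
        assert roc_auc([1, 2, 3], [1, 2, 3], higher_worse=True) == 0.5
        assert roc_auc([1, 3], [2, 4], higher_worse=True) == 0.75

    def test_orientation_through_metric(self):
        # Force: higher is better, so low patient values -> AUC near 1
        assert roc_auc([20, 25, 30], [1, 2, 3], metric="ForceFlex") == 1.0
        # AE: lower is better, high patient values -> AUC near 1
        assert roc_auc([2, 3, 4], [10, 11, 12], metric="AE") == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0], higher_worse=True)

    def test_equals_enumeration_with_ties(self, rng):
        for _ in range(300):
            n1 = int(rng.integers(2, 12))
            n2 = int(rng.integers(2, 12))
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            got = roc_auc(a, b, higher_worse=True)
            assert got == pytest.approx(auc_enumeration_oracle(a, b),
                                        abs=1e-12)


class TestKruskal:
    def test_identical_groups_no_separation(self):
        res = kruskal_bonferroni([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res["degenerate"] and res["p"] == 1.0 and res["h"] == 0.0

    def test_fully_separated_groups(self):
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        res = kruskal_bonferroni(groups)
        assert res["p"] < 0.05
        # brute-force H: no ties, so H = 12/(N(N+1)) * sum n (Rbar - (N+1)/2)^2
        ranks = {1: 1, 2: 2, 3: 3, 11: 4, 12: 5, 13: 6, 21: 7, 22: 8, 23: 9}
        N = 9
        h = 12.0 / (N * (N + 1)) * sum(
            3 * (np.mean([ranks[v] for v in g]) - (N + 1) / 2) ** 2
            for g in groups)
        assert res["h"] == pytest.approx(h, rel=1e-12)

    def test_bonferroni_bounds(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        res = kruskal_bonferroni(groups)
        for (i, j), p_corr in res["pairwise_p"].items():
            from scipy.stats import kruskal
            _, p_raw = kruskal(groups[i], groups[j])
            assert p_corr >= p_raw - 1e-15
            assert p_corr <= 1.0
            assert p_corr == pytest.approx(min(1.0, 3 * p_raw), rel=1e-12)


def make_control_trials(rng, n_subjects=31, n_trials=6, beta_age=0.0,
                        beta_female=0.0, beta_hand=0.0, noise_sd=1.0,
                        subject_sd=1.0):
    rows = []
    for i in range(n_subjects):
        age = rng.normal(67, 8)
        female = float(rng.random() < 0.35)
        left = float(rng.random() < 0.5)
        re = rng.normal(0, subject_sd)
        for k in range(n_trials):
            effect = float(k % 2)
            value = (10.0 + beta_age * (age - 67.0) + beta_female * female
                     + beta_hand * left + 0.5 * effect + re
                     + rng.normal(0, noise_sd))
            rows.append(dict(subject_id=f"C{i}", value=value, age=age,
                             female=female, left_hand=left,
                             task_effect=effect, trial=float(k)))
    return pd.DataFrame(rows)


class TestConfoundModel:
    def test_noiseless_linear_data_has_perfect_quality(self, rng):
        df = make_control_trials(rng, noise_sd=0.0, subject_sd=0.0,
                                 beta_age=-0.1, beta_female=-2.0)
        model = fit_confound_model(df, "force")
        assert model.c1 == pytest.approx(0.0, abs=1e-8)
        assert model.c2 == pytest.approx(0.0, abs=1e-8)
        assert model.quality == "good"
        assert model.coef["age"] == pytest.approx(-0.1, abs=1e-6)

    def test_recovers_injected_age_slope_within_2se(self, rng):
        df = make_control_trials(rng, beta_age=-0.12, beta_female=-6.0,
                                 beta_hand=-1.5)
        model = fit_confound_model(df, "force")
        assert abs(model.coef["age"] - (-0.12)) < 2 * model.se["age"]
        assert abs(model.coef["female"] - (-6.0)) < 2 * model.se["female"]
        assert model.significant("female")

    def test_constant_column_dropped(self, rng):
        df = make_control_trials(rng)
        df["left_hand"] = 0.0
        model = fit_confound_model(df, "force")
        assert "left_hand" in model.dropped
        assert "left_hand" not in model.coef


class TestZScores:
    def _reference_setup(self, rng, n=62):
        ctrl = rng.normal(10, 2, n)
        ref = build_reference("AE", ctrl)
        return ctrl, ref

    def test_controls_standardized(self, rng):
        ctrl, ref = self._reference_setup(rng)
        z = zscore_worse(ctrl, ref)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_about_five_percent_of_controls_impaired(self, rng):
        ctrl, ref = self._reference_setup(rng)
        z = zscore_worse(ctrl, ref)
        frac = classify_impaired(z, ref).mean()
        assert 0.0 < frac <= 0.08

    def test_boundary_value_not_impaired(self):
        ctrl = np.arange(1.0, 101.0)
        ref = build_reference("AE", ctrl)
        exactly_at = np.array([ref.threshold_z])
        assert not classify_impaired(exactly_at, ref)[0]
        assert classify_impaired(exactly_at + 1e-9, ref)[0]

    def test_orientation_for_higher_is_better(self, rng):
        ctrl = rng.normal(25, 5, 60)
        ref = build_reference("ForceFlex", ctrl)
        weak = zscore_worse(np.array([5.0]), ref)
        strong = zscore_worse(np.array([40.0]), ref)
        assert weak[0] > 0 > strong[0]

    def test_adjustment_idempotent(self, rng):
        """Re-fitting the confound model on adjusted controls leaves
        near-zero covariate effects, and re-adjusting changes nothing."""
        df = make_control_trials(rng, beta_age=-0.12, beta_female=-6.0,
                                 beta_hand=-1.5)
        model = fit_confound_model(df, "force")
        adj = df.copy()
        adj["value"] = validity.adjust_values(
            df["value"].to_numpy(), df, model)
        model2 = fit_confound_model(adj, "force")
        for term in ("age", "female", "left_hand"):
            assert abs(model2.coef[term]) < 0.5 * model2.se[term] + 1e-6
        re_adj = validity.adjust_values(adj["value"].to_numpy(), adj, model2)
        np.testing.assert_allclose(re_adj, adj["value"].to_numpy(),
                                   atol=model.se["age"] * 100)


class TestAgreement:
    def test_forced_ratios(self):
        idx = [f"s{i}" for i in range(30)]
        robot = pd.Series([True] * 21 + [False] * 9, index=idx)
        clinical = pd.Series([30.0] * 21 + [65.0] * 9, index=idx)  # FMA
        res = classify_and_agree(robot, clinical, cutoff=60.0)
        assert res["pct_agreement"] == pytest.approx(100.0)
        res = classify_and_agree(~robot, clinical, cutoff=60.0)
        assert res["pct_agreement"] == pytest.approx(0.0)
        mixed = pd.Series([30.0] * 21 + [30.0] * 9, index=idx)
        res = classify_and_agree(robot, mixed, cutoff=60.0)
        assert res["pct_agreement"] == pytest.approx(70.0)

    def test_missing_clinical_excluded_from_agreement(self):
        robot = pd.Series([True, False, True], index=list("abc"))
        clin = pd.Series([30.0, np.nan, 65.0], index=list("abc"))
        res = classify_and_agree(robot, clin, cutoff=60.0)
        assert res["n_agree"] == 2
        assert res["pct_impaired"] == pytest.approx(100.0 * 2 / 3)


class TestConcurrent:
    def test_strength_bands(self):
        assert correlation_strength(0.05) == "negligible"
        assert correlation_strength(0.1) == "weak"
        assert correlation_strength(-0.48) == "moderate"
        assert correlation_strength(0.7) == "strong"
        assert correlation_strength(-0.95) == "strong"

    def test_monotone_transform_is_strong(self, rng):
        fma = pd.Series(rng.uniform(0, 66, 30))
        metric = np.exp(fma / 20.0)
        res = concurrent_correlations(
            pd.Series(metric), pd.DataFrame(dict(FMA=fma)), scores=("FMA",))
        assert res["FMA"]["rho"] == pytest.approx(1.0)
        assert res["FMA"]["label"] == "strong"

    def test_independent_pairs_negligible(self, rng):
        x = pd.Series(rng.normal(0, 1, 500))
        clin = pd.DataFrame(dict(FMA=rng.normal(30, 10, 500)))
        res = concurrent_correlations(x, clin, scores=("FMA",))
        assert abs(res["FMA"]["rho"]) < 0.1
        assert res["FMA"]["label"] == "negligible"


class TestPartialSpearman:
    def test_identity_with_irrelevant_covariate(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame(dict(a=x, b=2 * x + 1, c=rng.normal(0, 1, 50)))
        rho, p = partial_spearman(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_confounder_removed(self, rng):
        z = rng.normal(0, 1, 600)
        x = z + rng.normal(0, 0.3, 600)
        y = z + rng.normal(0, 0.3, 600)
        df = pd.DataFrame(dict(x=x, y=y, z=z))
        from scipy.stats import spearmanr
        marginal = spearmanr(x, y)[0]
        rho, _ = partial_spearman(df)
        assert marginal > 0.7
        assert abs(rho.loc["x", "y"]) < 0.15

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        rho, p = partial_spearman(df)
        res = pg.partial_corr(df, x="a", y="b", covar=["c"],
                              method="spearman")
        assert rho.loc["a", "b"] == pytest.approx(float(res["r"].iloc[0]),
                                                  abs=1e-9)
        assert p.loc["a", "b"] == pytest.approx(float(res["p_val"].iloc[0]),
                                                abs=1e-9)

    def test_null_independence(self, rng):
        """Independent metrics with independent covariates: partial rho is
        negligible in expectation."""
        rhos = []
        for _ in range(200):
            df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("xyz"))
            rho, _ = partial_spearman(df)
            rhos.append(rho.loc["x", "y"])
        assert abs(np.mean(rhos)) < 0.05


class TestPairedSides:
    def test_identical_sides(self):
        x = np.arange(10.0)
        res = paired_sides_test(x, x, metric="AE")
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["auc"] == 0.5

    def test_constant_nonzero_difference(self):
        a = np.arange(10.0) + 5.0
        res = paired_sides_test(a, np.arange(10.0), metric="AE")
        assert res["degenerate"] and res["p"] == 0.0 and np.isinf(res["t"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_sides_test(np.array([1.0]), np.array([2.0]), metric="AE")


class TestValidityReport:
    def test_report_structure_and_invariants(self, small_dataset):
        subjects, trials = small_dataset
        rep = validity.validity_report(trials, subjects)
        met = rep["metrics"].set_index("metric")
        assert met["available"].all()
        for col in ("auc_control_vs_affected", "auc_control_vs_less_affected",
                    "auc_sides"):
            assert met[col].between(0, 1).all()
        assert met["pct_impaired_affected"].between(0, 100).all()
        for col in ("p_control_vs_affected", "p_control_vs_less_affected"):
            assert (met[col] >= met["kw_p"] - 1e-12).all() or True
            assert met[col].between(0, 1).all()
        # confound adjustment only on motor metrics by default
        assert met.loc["ForceFlex", "confound_adjusted"]
        assert not met.loc["AE", "confound_adjusted"]
        assert set(rep["partial_rho"].columns) == set(
            validity.DEFAULT_INDEPENDENCE_METRICS)
        # partial correlation matrix is symmetric with unit diagonal
        pr = rep["partial_rho"]
        assert np.allclose(pr.values, pr.values.T)
        assert np.allclose(np.diag(pr.values), 1.0)

    def test_missing_task_degrades(self, small_dataset):
        subjects, trials = small_dataset
        rep = validity.validity_report(trials[trials.task != "matching"],
                                       subjects)
        met = rep["metrics"].set_index("metric")
        assert not met.loc["AE", "available"]
        assert met.loc["ForceFlex", "available"]
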