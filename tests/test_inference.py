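from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoniche import inference

from _oracles import auc_mannwhitney_oracle, levene_anova_oracle


class TestLeveneTest:
    def test_zero_spread_groups_degenerate(self):
        r = inference.levene_test({"a": [1.0, 1.0, 1.0], "b": [5.0, 5.0]})
        assert r.statistic == 0.0 and r.degenerate

    def test_matches_anova_on_absolute_deviations_oracle(self, rng):
        for center in ("mean", "median"):
            for _ in range(20):
                groups = {
                    lab: rng.normal(rng.normal(), rng.uniform(0.5, 3.0), rng.integers(5, 30))
                    for lab in "abc"
                }
                r = inference.levene_test(groups, center=center)
                w, p = levene_anova_oracle(list(groups.values()), center=center)
                assert r.statistic == pytest.approx(w, abs=1e-10)
                assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_shift_and_scale_invariance(self, rng):
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 2, 25)}
        base = inference.levene_test(groups)
        shifted = inference.levene_test({"a": groups["a"] + 100.0, "b": groups["b"]})
        scaled = inference.levene_test({k: 3.5 * v for k, v in groups.items()})
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            inference.levene_test({"a": [1.0, 2.0], "b": [1.0]})

    def test_degrees_of_freedom(self, rng):
        r = inference.levene_test({"a": rng.normal(size=10), "b": rng.normal(size=14)})
        assert r.df_num == 1 and r.df_den == 22


class TestMixedModel:
    def _balanced(self, rng, treat_effect=0.5, meso_sd=0.0, n_meso=4, n_per=10):
        rows = []
        for t, eff in (("ref", 0.0), ("stress", treat_effect)):
            for m in range(n_meso):
                u = rng.normal(0, meso_sd) if meso_sd else 0.0
                y = 1.0 + eff + u + rng.normal(0, 1.0, n_per)
                rows.append(
                    pd.DataFrame({"y": y, "treat": t, "meso": f"{t}{m}"})
                )
        return pd.concat(rows, ignore_index=True)

    def test_balanced_design_matches_ols_oracle(self, rng):
        df = self._balanced(rng, meso_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inference.fit_mixed_model(df, "y", ["C(treat)"], group="meso")
        diff = df.groupby("treat")["y"].mean()
        expected = diff["stress"] - diff["ref"]
        assert fit.params["estimate"].iloc[1] == pytest.approx(expected, abs=1e-6)
        assert fit.random_variance is not None

    def test_intercept_only_equals_mean_of_mesocosm_means(self, rng):
        df = self._balanced(rng, treat_effect=0.0, meso_sd=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inference.fit_mixed_model(df, "y", [], group="meso")
        grand = df.groupby("meso")["y"].mean().mean()
        assert fit.params["estimate"].iloc[0] == pytest.approx(grand, abs=1e-4)

    def test_aic_identity(self, rng):
        df = self._balanced(rng, meso_sd=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inference.fit_mixed_model(df, "y", ["C(treat)"], group="meso")
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_single_group_level_rejected(self, rng):
        df = self._balanced(rng).assign(meso="only")
        with pytest.raises(ValueError, match="2 levels"):
            inference.fit_mixed_model(df, "y", ["C(treat)"], group="meso")

    def test_poisson_glmm_recovers_fixed_effect(self, rng):
        # log-link: log mu = 1.0 + 0.6*x + u,  u ~ N(0, 0.3^2)
        rows = []
        for m in range(12):
            u = rng.normal(0, 0.3)
            x = rng.normal(size=40)
            y = rng.poisson(np.exp(1.0 + 0.6 * x + u))
            rows.append(pd.DataFrame({"y": y, "x": x, "meso": f"m{m}"}))
        df = pd.concat(rows, ignore_index=True)
        fit = inference.fit_mixed_model(df, "y", ["x"], group="meso", family="poisson")
        assert fit.family == "poisson" and fit.link == "log"
        assert fit.params.loc["x", "estimate"] == pytest.approx(0.6, abs=0.1)
        assert np.sqrt(fit.random_variance) == pytest.approx(0.3, abs=0.2)
        assert np.isfinite(fit.params["se"]).all()

    def test_poisson_zero_variance_matches_glm(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=300)
        y = rng.poisson(np.exp(0.5 + 0.4 * x))
        df = pd.DataFrame({"y": y, "x": x, "meso": np.tile([f"m{i}" for i in range(10)], 30)})
        fit = inference.fit_mixed_model(df, "y", ["x"], group="meso", family="poisson")
        X = sm.add_constant(x)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.params.loc["x", "estimate"] == pytest.approx(glm.params[1], abs=0.02)

    def test_non_count_response_rejected_for_poisson(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=20), "x": rng.normal(size=20),
             "meso": np.repeat(["a", "b"], 10)}
        )
        with pytest.raises(ValueError, match="counts"):
            inference.fit_mixed_model(df, "y", ["x"], group="meso", family="poisson")


class TestLinearModel:
    def test_exact_linear_recovery(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"y": 2.0 + 3.0 * x, "x": x})
        fit = inference.fit_linear_model(df, "y", ["x"])
        assert fit.params.loc["x", "estimate"] == pytest.approx(3.0, abs=1e-9)
        assert fit.resid_variance == pytest.approx(0.0, abs=1e-18)

    def test_log_link_recovery(self, rng):
        x = rng.uniform(0, 1, 400)
        y = np.exp(0.5 + 1.2 * x) + rng.normal(0, 0.05, 400)
        fit = inference.fit_linear_model(
            pd.DataFrame({"y": y, "x": x}), "y", ["x"], link="log"
        )
        assert fit.link == "log"
        assert fit.params.loc["x", "estimate"] == pytest.approx(1.2, rel=0.05)

    def test_null_slope_calibration(self, rng):
        hits = 0
        for _ in range(300):
            df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
            fit = inference.fit_linear_model(df, "y", ["x"])
            hits += fit.params.loc["x", "p"] < 0.05
        assert 0.02 <= hits / 300 <= 0.09

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"y": rng.normal(size=20), "x1": x, "x2": 2.0 * x})
        with pytest.raises(ValueError, match="x2"):
            inference.fit_linear_model(df, "y", ["x1", "x2"])


class TestAicSelection:
    def test_equal_likelihood_prefers_fewer_parameters(self, rng):
        class Stub:
            def __init__(self, k):
                self.aic = 10.0 + 2 * (k - 2)
                self.k = k

        fits = {"small": Stub(2), "big": Stub(3)}

        def fit(df, response, predictors):
            return fits["small" if len(predictors) == 1 else "big"]

        df = pd.DataFrame({"y": rng.normal(size=10), "a": rng.normal(size=10),
                           "b": rng.normal(size=10)})
        best, ranking = inference.select_by_aic(df, "y", [["a"], ["a", "b"]], fit=fit)
        assert best.k == 2
        assert len(ranking) == 2

    def test_single_candidate_returned(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30), "x": rng.normal(size=30)})
        best, ranking = inference.select_by_aic(df, "y", [["x"]])
        assert best.formula == "y ~ x"
        assert len(ranking) == 1

    def test_true_predictors_selected(self, rng):
        # strong effects are always retained; the pure-noise predictor is
        # admitted at roughly the AIC false-inclusion rate P(chi2_1 > 2)
        n = 95
        keep_true = noise_in = 0
        for _ in range(60):
            a, b, c = rng.normal(size=(3, n))
            y = 1.0 + 1.2 * a - 0.9 * b + rng.normal(0, 0.5, n)
            df = pd.DataFrame({"y": y, "a": a, "b": b, "c": c})
            best, _ = inference.select_by_aic(
                df, "y", list(inference.all_subsets(["a", "b", "c"]))
            )
            terms = {t.strip() for t in best.formula.split("~")[1].split("+")}
            keep_true += {"a", "b"} <= terms
            noise_in += "c" in terms
        assert keep_true / 60 >= 0.95
        assert noise_in / 60 <= 0.35

    def test_failing_candidate_excluded(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"y": rng.normal(size=20), "x": x, "dup": 2 * x})
        best, ranking = inference.select_by_aic(df, "y", [["x"], ["x", "dup"]])
        assert best.formula == "y ~ x"
        assert (ranking["error"] != "").any()

    def test_no_candidates_rejected(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=5)})
        with pytest.raises(ValueError):
            inference.select_by_aic(df, "y", [])


class TestLogistic:
    def _two_by_two(self):
        # predictor x=1: 40 cases / 10 controls; x=0: 10 cases / 40 controls
        y = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)]
        x = np.r_[np.ones(50), np.zeros(50)]
        return pd.DataFrame({"y": y, "x": x})

    def test_saturated_two_by_two_odds_ratio(self):
        rep = inference.fit_logistic(self._two_by_two(), "y", ["x"])
        assert rep.params.loc["x", "odds_ratio"] == pytest.approx(16.0, abs=1e-6)

    def test_label_swap_gives_reciprocal_odds_ratio(self):
        df = self._two_by_two()
        a = inference.fit_logistic(df, "y", ["x"])
        b = inference.fit_logistic(df.assign(y=1 - df["y"]), "y", ["x"])
        assert b.params.loc["x", "odds_ratio"] == pytest.approx(
            1.0 / a.params.loc["x", "odds_ratio"], rel=1e-6
        )

    def test_null_odds_ratio_recovery(self, rng):
        ors = []
        for _ in range(200):
            df = pd.DataFrame(
                {"y": rng.integers(0, 2, 100).astype(float), "x": rng.normal(size=100)}
            )
            rep = inference.fit_logistic(df, "y", ["x"])
            ors.append(rep.params.loc["x", "odds_ratio"])
        assert 0.9 <= np.mean(ors) <= 1.1

    def test_perfect_separation_warns(self):
        x = np.r_[np.linspace(-2, -1, 10), np.linspace(1, 2, 10)]
        df = pd.DataFrame({"y": (x > 0).astype(float), "x": x})
        with pytest.warns(inference.SeparationWarning):
            rep = inference.fit_logistic(df, "y", ["x"])
        assert rep.separation

    def test_one_class_rejected(self, rng):
        df = pd.DataFrame({"y": np.ones(10), "x": rng.normal(size=10)})
        with pytest.raises(ValueError, match="both classes"):
            inference.fit_logistic(df, "y", ["x"])


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        labels = np.r_[np.ones(5), np.zeros(5)]
        r = inference.roc_analysis(scores, labels)
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_auc_equals_mannwhitney_oracle(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 2, 60)
            labels[:2] = [0, 1]  # both classes
            scores = rng.normal(size=60) + 0.5 * labels
            r = inference.roc_analysis(scores, labels)
            assert r.auc == pytest.approx(
                auc_mannwhitney_oracle(scores, labels), abs=1e-12
            )

    def test_label_swap_maps_auc(self, rng):
        labels = np.r_[np.ones(30), np.zeros(30)]
        scores = rng.normal(size=60) + 0.8 * labels
        a = inference.roc_analysis(scores, labels).auc
        b = inference.roc_analysis(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            inference.roc_analysis(rng.normal(size=5), np.ones(5))


class TestClassifyStress:
    def test_report_carries_roc_operating_point(self, rng):
        n = 120
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + 1.5 * x)))
        df = pd.DataFrame({"stressed": (rng.random(n) < p).astype(float), "x": x})
        rep = inference.classify_stress(df, "stressed", ["x"])
        assert 0.5 < rep.auc <= 1.0
        assert 0.0 <= rep.sensitivity <= 1.0 and 0.0 <= rep.specificity <= 1.0
        assert rep.roc is not None and rep.cutoff is not None

    def test_standardize_leaves_auc_unchanged(self, rng):
        n = 80
        x = rng.normal(2.0, 3.0, size=n)
        y = (x + rng.normal(0, 2, n) > 2.0).astype(float)
        df = pd.DataFrame({"stressed": y, "x": x})
        raw = inference.classify_stress(df, "stressed", ["x"])
        std = inference.classify_stress(df, "stressed", ["x"], standardize=True)
        assert raw.auc == pytest.approx(std.auc, abs=1e-12)


class TestStressEndToEnd:
    def test_covariance_inflation_yields_positive_ed_coefficient(self, rng):
        """Pure covariance inflation (kappa=2, no mean shift) in the
        contaminated-sediment design is recovered as a positive stress
        coefficient on ED by the mixed model in nearly every replicate."""
        from isoniche import prep, simulate

        spec = simulate.variance_inflation_spec(2.0, experiment=1)
        hits = 0
        reps = 50
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(reps):
                sp, _ = simulate.generate_experiment(spec, rng)
                df, _ = prep.prepare_isotopes(sp)
                df = df[~df["is_initial"]].copy()
                df["stressed"] = (df["treatment"] == "exposure").astype(int)
                df["meso_group"] = df["treatment"] + ":" + df["mesocosm"]
                fit = inference.fit_mixed_model(
                    df, "ed", ["stressed"], group="meso_group"
                )
                row = fit.params.loc["stressed"]
                hits += (row["estimate"] > 0) and (row["p"] < 0.05)
        assert hits / reps >= 0.9


def test_survival_test_dispatch(rng):
    two = inference.survival_test({"a": rng.normal(size=7), "b": rng.normal(size=7)})
    three = inference.survival_test(
        {k: rng.normal(size=7) for k in "abc"}
    )
    assert two["method"] == "mann-whitney"
    assert three["method"] == "kruskal-wallis"
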