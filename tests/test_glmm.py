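import numpy as np
import pandas as pd
import pytest
from scipy import special

from endemix import glmm
from endemix.glmm import (
    CategoryThresholds,
    categorize,
    compare_models,
    error_report,
    error_report_from_counts,
    fit_glmm,
    predict_scores,
    thresholds_from_training,
    welch_t,
)


class TestWelchT:
    def test_identical_groups_zero(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # x={1,2,3}, y={4,5,6}: t = -3/sqrt(2/3) = -3.674235, df = 4
        r = welch_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert r.df == pytest.approx(4.0, abs=1e-9)
        assert r.p_value == pytest.approx(0.021312, abs=1e-5)

    def test_zero_variance_equal_means(self):
        r = welch_t([2.0, 2.0], [2.0, 2.0])
        assert r.statistic == 0.0

    def test_simulated_nn_samples_strongly_separated(self):
        """Endemic vs introduced nearest-neighbor distances at generator
        defaults give |t| > 2 in nearly every replicate."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            end = rng.normal(0.05, 0.02, 40)
            intro = rng.normal(0.18, 0.02, 40)
            if abs(welch_t(end, intro).statistic) > 2:
                hits += 1
        assert hits == 20


def irls_logistic(X, y, tol=1e-12):
    b = np.zeros(X.shape[1])
    for _ in range(200):
        p = special.expit(X @ b)
        W = p * (1 - p)
        step = np.linalg.solve(X.T @ (X * W[:, None]), X.T @ (y - p))
        b += step
        if np.abs(step).max() < tol:
            return b
    return b


def simulate_training(rng, n_orders, per_order, beta, sigma):
    rows = []
    for o in range(n_orders):
        u = rng.normal(0, sigma)
        for s in range(per_order):
            aw = rng.normal(1.0, 0.5)
            nn = rng.normal(1.0, 0.5)
            p = special.expit(beta[0] + beta[1] * aw + beta[2] * nn + u)
            rows.append(
                dict(
                    species_id=f"o{o}s{s}",
                    order=f"o{o}",
                    avg_within=aw,
                    nn_distance=nn,
                    status="endemic" if rng.random() < p else "introduced",
                )
            )
    return pd.DataFrame(rows)


class TestFitGlmm:
    def test_zero_variance_limit_matches_irls_oracle(self):
        rng = np.random.default_rng(1)
        df = simulate_training(rng, 3, 40, np.array([-0.5, 1.2, -2.0]), 0.0)
        fit = fit_glmm(df, "sim+dist", fix_sigma2=0.0)
        X = np.column_stack(
            [np.ones(len(df)), df.avg_within.to_numpy(), df.nn_distance.to_numpy()]
        )
        y = (df.status == "endemic").to_numpy(float)
        oracle = irls_logistic(X, y)
        assert np.abs(fit.beta - oracle).max() < 1e-6
        # the profiled likelihood at sigma=0 equals the logistic likelihood
        ll = float(np.sum(y * (X @ oracle) - np.logaddexp(0, X @ oracle)))
        assert fit.LL == pytest.approx(ll, abs=1e-8)

    @pytest.mark.parametrize(
        "formula,expected_K",
        [("sim+dist", 4), ("sim*dist", 5), ("dist", 3), ("sim", 3)],
    )
    def test_parameter_count_bookkeeping(self, formula, expected_K):
        rng = np.random.default_rng(2)
        df = simulate_training(rng, 4, 20, np.array([0.0, 0.5, -0.5]), 0.3)
        assert fit_glmm(df, formula).K == expected_K

    def test_aicc_identity(self):
        rng = np.random.default_rng(3)
        df = simulate_training(rng, 4, 25, np.array([0.2, 0.8, -1.0]), 0.5)
        fit = fit_glmm(df)
        n, K = fit.n, fit.K
        assert fit.AICc == pytest.approx(
            -2 * fit.LL + 2 * K + 2 * K * (K + 1) / (n - K - 1)
        )

    def test_parameter_recovery_within_three_se(self):
        """Estimates on model-generated data (40 orders x 30 species) land
        within 3 standard errors of the generating parameters."""
        rng = np.random.default_rng(42)
        beta = np.array([0.5, 1.0, -2.0])
        df = simulate_training(rng, 40, 30, beta, 0.8)
        fit = fit_glmm(df, "sim+dist")
        assert fit.converged
        assert fit.beta_se is not None
        z = (fit.beta - beta) / fit.beta_se
        assert np.abs(z).max() < 3.0

    def test_deterministic_refit(self):
        rng = np.random.default_rng(4)
        df = simulate_training(rng, 4, 25, np.array([0.0, 1.0, -1.0]), 0.4)
        f1 = fit_glmm(df)
        f2 = fit_glmm(df.copy())
        assert np.array_equal(f1.beta, f2.beta)
        assert f1.sigma2_order == f2.sigma2_order

    def test_single_order_rejected_for_mixed_model(self):
        rng = np.random.default_rng(5)
        df = simulate_training(rng, 1, 30, np.array([0.0, 1.0, -1.0]), 0.0)
        with pytest.raises(ValueError):
            fit_glmm(df)


class TestCompareModels:
    def test_published_model_table_reproduced(self):
        """Four AICc values from a barcoding training set give the printed
        differences and Akaike weights."""
        table = compare_models([136.15, 138.30, 141.38, 155.77])
        assert table["dAICc"].round(2).tolist() == [0.0, 2.15, 5.23, 19.62]
        assert table["weight"].round(2).tolist() == [0.71, 0.24, 0.05, 0.0]

    def test_single_model(self):
        table = compare_models([100.0])
        assert table["dAICc"].iloc[0] == 0.0
        assert table["weight"].iloc[0] == 1.0

    def test_weights_normalized(self):
        rng = np.random.default_rng(6)
        table = compare_models(list(rng.uniform(100, 160, 6)))
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table["AICc"].is_monotonic_increasing


class TestPredictScores:
    def fit_toy(self, sigma=0.4):
        rng = np.random.default_rng(7)
        df = simulate_training(rng, 4, 30, np.array([0.3, 0.6, -1.5]), sigma)
        return fit_glmm(df), df

    def test_zero_model_scores_half(self):
        fit, df = self.fit_toy()
        fit.beta = np.zeros_like(fit.beta)
        fit.u = {k: 0.0 for k in fit.u}
        scored = predict_scores(fit, df.rename(columns={"status": "x"}))
        assert np.allclose(scored["glmm_score"], 0.5)

    def test_negative_distance_coefficient_monotonicity(self):
        fit, df = self.fit_toy()
        j = fit.beta_names.index("nn_distance")
        assert fit.beta[j] < 0
        grid = pd.DataFrame(
            {
                "species_id": [f"g{i}" for i in range(5)],
                "order": ["o0"] * 5,
                "avg_within": [1.0] * 5,
                "nn_distance": np.linspace(0.5, 2.0, 5),
            }
        )
        s = predict_scores(fit, grid)["glmm_score"].to_numpy()
        assert np.all(np.diff(s) < 0)

    def test_singleton_species_scoreless(self):
        fit, _ = self.fit_toy()
        df = pd.DataFrame(
            {
                "species_id": ["lonely"],
                "order": ["o0"],
                "avg_within": [np.nan],
                "nn_distance": [0.2],
            }
        )
        s = predict_scores(fit, df)["glmm_score"]
        assert np.isnan(s.iloc[0])
        assert categorize(float(s.iloc[0]), _published_thresholds()) == "NA"

    def test_unseen_order_uses_population_level(self):
        fit, _ = self.fit_toy(sigma=0.8)
        row = dict(species_id=["x"], avg_within=[1.0], nn_distance=[1.0])
        known = predict_scores(fit, pd.DataFrame({**row, "order": ["o0"]}))
        unseen = predict_scores(fit, pd.DataFrame({**row, "order": ["Mystery"]}))
        X = np.array([1.0, 1.0, 1.0])
        expected = special.expit(X @ fit.beta)
        assert unseen["glmm_score"].iloc[0] == pytest.approx(expected)
        assert known["glmm_score"].iloc[0] != pytest.approx(expected)


def _published_thresholds():
    return CategoryThresholds(
        intro_mean=0.2582,
        intro_ci=(0.2291, 0.2873),
        endemic_mean=0.3839,
        endemic_ci=(0.3444, 0.4233),
    )


class TestThresholds:
    def test_constant_scores_degenerate_interval(self):
        thr = thresholds_from_training(
            [0.3, 0.3, 0.5, 0.5],
            ["introduced", "introduced", "endemic", "endemic"],
        )
        assert thr.intro_ci == pytest.approx((0.3, 0.3))
        assert thr.endemic_ci == pytest.approx((0.5, 0.5))

    def test_two_point_hand_oracle(self):
        # scores {0.2, 0.3}: mean 0.25, SD 0.0707107, SE 0.05,
        # CI = 0.25 -+ 1.95996 * 0.05
        thr = thresholds_from_training(
            [0.2, 0.3, 0.9, 1.0],
            ["introduced", "introduced", "endemic", "endemic"],
        )
        z = 1.959964
        assert thr.intro_mean == pytest.approx(0.25)
        assert thr.intro_ci[0] == pytest.approx(0.25 - z * 0.05, abs=1e-5)
        assert thr.intro_ci[1] == pytest.approx(0.25 + z * 0.05, abs=1e-5)


class TestCategorize:
    @pytest.mark.parametrize(
        "score,label",
        [
            (0.25, "GLMM-Nonnative"),
            (0.30, "GLMM-Undet"),
            (0.40, "GLMM-Native"),
            (None, "NA"),
        ],
    )
    def test_published_threshold_examples(self, score, label):
        assert categorize(score, _published_thresholds()) == label

    def test_exhaustive_and_exclusive(self):
        thr = _published_thresholds()
        labels = {categorize(s, thr) for s in np.linspace(0, 1, 201)}
        assert labels == {"GLMM-Nonnative", "GLMM-Undet", "GLMM-Native"}

    def test_overlapping_intervals_yield_undet(self, caplog):
        thr = CategoryThresholds(0.4, (0.3, 0.5), 0.45, (0.35, 0.55))
        with caplog.at_level("WARNING"):
            assert categorize(0.42, thr) == "GLMM-Undet"


class TestErrorReport:
    def test_grand_total_arithmetic(self, table3_counts):
        rep = error_report_from_counts(table3_counts)
        assert rep.error_rate("introduced") == pytest.approx(22.55, abs=0.005)
        assert rep.error_rate("endemic") == pytest.approx(22.22, abs=0.005)

    def test_per_order_rates(self, table3_counts):
        rep = error_report_from_counts(table3_counts)
        assert rep.error_rate("introduced", "Diptera") == pytest.approx(23.08, abs=0.005)
        assert rep.error_rate("endemic", "Lepidoptera") == pytest.approx(23.81, abs=0.005)
        assert rep.error_rate("introduced", "Araneae") == pytest.approx(100.0)

    def test_from_species_lists(self):
        rep = error_report(
            ["GLMM-Native", "GLMM-Nonnative", "GLMM-Undet", "NA"],
            ["introduced", "introduced", "endemic", "unknown"],
            ["Diptera"] * 4,
        )
        assert rep.error_rate("introduced") == pytest.approx(50.0)
        assert rep.error_rate("endemic") == pytest.approx(0.0)

    def test_accuracy_complement_of_mean_error(self, table3_counts):
        rep = error_report_from_counts(table3_counts)
        assert rep.accuracy() == pytest.approx(
            100 - (22.549 + 22.222) / 2, abs=0.01
        )
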