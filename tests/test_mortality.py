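"""Logistic DOR models: likelihood, ranking, odds ratios, AUC, curves."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

from snakeroad.mortality import (
    ConvergenceError,
    ModelSpec,
    STUDY_MODEL_SET,
    auc,
    auc_scores,
    cubic_spline_probability,
    fit_logistic,
    odds_ratios,
    prediction_curve,
    rank_models,
    selection_surface,
)
from snakeroad.synth import generate_atrox_adults


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def hand_nll(beta, X, y):
    eta = X @ beta
    return -np.sum(y * eta - np.logaddexp(0.0, eta))


class TestModelSpec:
    def test_formula_parsing_round_trip(self):
        spec = ModelSpec.from_formula("DOR ~ Total length + Weight + Sex")
        assert spec.terms == ("total_length", "weight", "sex")
        assert spec.label == "DOR ~ Total length + Weight + Sex"

    def test_interaction_notation(self):
        a = ModelSpec.from_formula("DOR ~ Total Length * Sex + Weight")
        b = ModelSpec.from_formula("DOR ~ total_length:sex + weight")
        assert a.terms == b.terms == ("total_length*sex", "weight")
        assert set(a.variables) == {"total_length", "sex", "weight"}

    def test_duplicate_and_unknown_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(("svl", "svl"))
        with pytest.raises(ValueError):
            ModelSpec(("girth",))

    def test_study_set_has_eleven_models(self):
        assert len(STUDY_MODEL_SET) == 11


class TestFitLogistic:
    def test_single_class_response_rejected(self, adult_table):
        flat = adult_table.assign(dor=0)
        with pytest.raises(ValueError, match="both"):
            fit_logistic(flat, ModelSpec(("total_length",)))

    def test_complete_separation_flagged_with_term(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        df = pd.DataFrame({"total_length": x, "dor": (x > 0).astype(int)})
        with pytest.raises(ConvergenceError, match="total_length"):
            fit_logistic(df, ModelSpec(("total_length",)))

    def test_aic_identity(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.loglik, abs=1e-12)
        assert fit.df == 4

    def test_loglik_matches_independent_optimizer(self):
        """IRLS maximum equals a general-purpose optimizer's on random data."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(25, 60))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            beta = rng.normal(scale=0.8, size=3)
            y = (rng.random(n) < expit(X @ beta)).astype(int)
            if y.min() == y.max():
                continue
            df = pd.DataFrame({"total_length": X[:, 1], "weight": X[:, 2], "dor": y})
            try:
                fit = fit_logistic(df, ModelSpec(("total_length", "weight")))
            except ConvergenceError:
                continue
            res = optimize.minimize(hand_nll, np.zeros(3), args=(X, y), method="BFGS",
                                    options={"gtol": 1e-10, "maxiter": 500})
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_reference_level_is_female(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "sex")))
        assert any("male" in name for name in fit.params.index)
        assert not any("female]" in name for name in fit.params.index)


class TestRankModels:
    def test_single_model(self, adult_table):
        table = rank_models(adult_table, [ModelSpec(("total_length",))])
        assert len(table) == 1 and table.loc[0, "df"] == 2

    def test_recovers_generating_structure(self):
        df = generate_atrox_adults(5000, seed=21)
        table = rank_models(df, STUDY_MODEL_SET)
        assert table.loc[0, "model"] == "DOR ~ Total length + Weight + Sex"

    def test_noise_covariate_costs_about_two_aic(self):
        """A superfluous covariate with zero effect loses by ~2 AIC at large n."""
        df = generate_atrox_adults(20_000, seed=5)
        df["weight"] = np.random.default_rng(6).normal(size=len(df))  # pure noise
        table = rank_models(df, [ModelSpec(("total_length", "sex")),
                                 ModelSpec(("total_length", "weight", "sex"))])
        small = table.set_index("model").loc["DOR ~ Total length + Sex", "aic"]
        big = table.set_index("model").loc["DOR ~ Total length + Weight + Sex", "aic"]
        # the useless parameter buys at most a chi2(1) deviance improvement
        # against a fixed +2 penalty, so the smaller model wins by up to 2
        assert small < big
        assert big - small <= 2.0 + 1e-9

    def test_ranked_ascending(self, adult_table):
        table = rank_models(adult_table, STUDY_MODEL_SET)
        assert (table["aic"].diff().dropna() >= 0).all()


class TestOddsRatios:
    def test_or_is_exp_of_estimate(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        ors = odds_ratios(fit, method="wald")
        for _, row in ors.iterrows():
            assert row.odds_ratio == pytest.approx(np.exp(row.estimate), rel=1e-12)
            assert row.ci_low < row.odds_ratio < row.ci_high

    def test_published_slope_maps_to_published_or(self):
        assert np.exp(0.0908) == pytest.approx(1.095, abs=5e-4)

    def test_profile_interval_brackets_estimate(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        prof = odds_ratios(fit, method="profile")
        wald = odds_ratios(fit, method="wald")
        for (_, p), (_, w) in zip(prof.iterrows(), wald.iterrows()):
            assert p.ci_low < p.odds_ratio < p.ci_high
            # profile and Wald agree to first order at this sample size
            assert p.ci_low == pytest.approx(w.ci_low, rel=0.2)
            assert p.ci_high == pytest.approx(w.ci_high, rel=0.2)


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert auc_scores([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_example(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.75]
        labels = [1, 1, 1, 0, 0]
        assert auc_scores(scores, labels) == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc_scores(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_scores([0.5, 0.6], [1, 1])

    def test_fit_auc_uses_fitted_probabilities(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        probs = np.asarray(fit.result.predict(fit.data))
        assert auc(fit) == pytest.approx(
            auc_scores(probs, fit.data["dor"].to_numpy()), abs=1e-12)


class TestPredictionCurve:
    @pytest.fixture(scope="class")
    def fit(self, adult_table):
        return fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))

    def test_monotone_for_positive_slope(self, fit):
        assert fit.params["total_length"] > 0
        curve = prediction_curve(fit)
        assert (np.diff(curve["prob"]) > 0).all()

    def test_probabilities_and_ci_ordered(self, fit):
        curve = prediction_curve(fit)
        assert ((curve["prob"] > 0) & (curve["prob"] < 1)).all()
        assert (curve["ci_low"] <= curve["prob"]).all()
        assert (curve["prob"] <= curve["ci_high"]).all()

    def test_extrapolation_flagged(self, fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            prediction_curve(fit, grid=np.array([0.0, 500.0]))

    def test_link_ci_matches_parametric_bootstrap(self, fit):
        """Normal link-scale interval vs simulating coefficient uncertainty."""
        grid = np.array([85.0])
        curve = prediction_curve(fit, grid=grid)
        rng = np.random.default_rng(17)
        frame = pd.DataFrame({
            "total_length": [85.0],
            "weight": [float(fit.data["weight"].mean())],
            "sex": ["female"],
        })
        from patsy import build_design_matrices

        design = fit.result.model.data.design_info
        (X,) = build_design_matrices([design], frame)
        X = np.asarray(X)
        draws = rng.multivariate_normal(fit.params.to_numpy(), fit.cov.to_numpy(), 5000)
        probs = expit(draws @ X.ravel())
        lo, hi = np.quantile(probs, [0.025, 0.975])
        assert curve.loc[0, "ci_low"] == pytest.approx(lo, abs=0.02)
        assert curve.loc[0, "ci_high"] == pytest.approx(hi, abs=0.02)


class TestCubicSpline:
    def test_constant_probabilities_give_flat_spline(self):
        x = np.linspace(50, 120, 30)
        out = cubic_spline_probability(x, np.full_like(x, 0.3), n_boot=50, seed=0)
        assert np.allclose(out["prob"], 0.3, atol=1e-9)

    def test_noiseless_monotone_input_reproduced(self):
        x = np.linspace(50, 120, 40)
        y = expit((x - 85) / 10)
        out = cubic_spline_probability(x, y, n_boot=50, seed=0, grid=x)
        assert np.max(np.abs(out["prob"].to_numpy() - y)) < 0.02

    def test_requires_ten_points(self):
        with pytest.raises(ValueError):
            cubic_spline_probability(np.arange(5), np.full(5, 0.5))

    def test_outputs_clamped_to_unit_interval(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        probs = np.asarray(fit.result.predict(fit.data))
        out = cubic_spline_probability(
            fit.data["total_length"].to_numpy(), probs, n_boot=100, seed=1)
        for col in ("prob", "ci_low", "ci_high"):
            assert out[col].between(0, 1).all()


class TestSelectionSurface:
    def test_size_independent_mortality_gives_flat_surface(self):
        # covariates carry no signal -> coefficients ~0 -> near-constant surface
        rng = np.random.default_rng(8)
        df = generate_atrox_adults(4000, seed=9)
        df["dor"] = rng.integers(0, 2, len(df))
        fit = fit_logistic(df, ModelSpec(("total_length", "weight", "sex")))
        surf = selection_surface(fit, np.linspace(60, 120, 10), np.linspace(50, 600, 10))
        assert surf["prob"].std() < 0.05
        assert surf["prob"].mean() == pytest.approx(0.5, abs=0.05)

    def test_surface_values_in_unit_interval(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        surf = selection_surface(fit, np.linspace(60, 120, 10), np.linspace(50, 600, 10))
        assert len(surf) == 100
        assert ((surf["prob"] > 0) & (surf["prob"] < 1)).all()

    def test_surface_peak_tracks_length_slope(self, adult_table):
        fit = fit_logistic(adult_table, ModelSpec(("total_length", "weight", "sex")))
        surf = selection_surface(fit, np.linspace(60, 120, 13), [300.0])
        peak = surf.loc[surf["prob"].idxmax(), "total_length"]
        assert peak == 120.0  # positive slope puts the max at the longest snakes
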