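import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from ecoshift.grid import GridSpec, RasterStack
from ecoshift.maxent import (
    Feature,
    FeatureSet,
    MaxentModel,
    MaxentSettings,
    auc_scores,
    build_features,
    env_at_points,
    fit,
    importance,
    predict,
    project,
    response_curve,
    sample_background,
)

from .conftest import make_layer, make_stack


def small_env(rng, n, names=("A", "B")):
    return pd.DataFrame({name: rng.normal(size=n) for name in names})


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

class TestSampleBackground:
    def test_exactly_n_valid_cells_returns_all(self, spec3, rng):
        stack = make_stack(spec3, {"a": rng.normal(size=(3, 3))})
        bg = sample_background(stack, 9, seed=0)
        assert len(bg) == 9

    def test_deterministic_given_seed(self, spec10, rng):
        stack = make_stack(spec10, {"a": rng.normal(size=(10, 10))})
        bg1 = sample_background(stack, 20, seed=5)
        bg2 = sample_background(stack, 20, seed=5)
        np.testing.assert_array_equal(bg1.rows, bg2.rows)
        np.testing.assert_array_equal(bg1.cols, bg2.cols)

    def test_without_replacement(self, spec10, rng):
        stack = make_stack(spec10, {"a": rng.normal(size=(10, 10))})
        bg = sample_background(stack, 50, seed=1)
        assert len(set(zip(bg.rows.tolist(), bg.cols.tolist()))) == 50

    def test_fewer_valid_than_n_warns(self, spec3, rng):
        vals = np.full((3, 3), -9999.0)
        vals[0, :] = 1.0
        stack = make_stack(spec3, {"a": vals})
        with pytest.warns(UserWarning, match="using all"):
            bg = sample_background(stack, 9, seed=0)
        assert len(bg) == 3

    def test_two_cell_grid_unbiased(self):
        # n=1 draw from a 2-cell grid: cell 0 chosen ~50% of seeds (3 sigma)
        spec = GridSpec(0, 100, 100.0, 1, 2, "X")
        stack = make_stack(spec, {"a": np.array([[1.0, 2.0]])})
        n_trials = 4000
        hits = sum(
            sample_background(stack, 1, seed=s).cols[0] == 0
            for s in range(n_trials)
        )
        sd = np.sqrt(n_trials * 0.25)
        assert abs(hits - n_trials / 2) < 3 * sd


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

class TestBuildFeatures:
    def test_auto_m5_linear_only(self, rng):
        p = small_env(rng, 5, ["A"])
        b = small_env(rng, 50, ["A"])
        fset = build_features(p, b, MaxentSettings())
        assert {f.cls for f in fset.features} == {"linear"}

    def test_auto_m201_all_classes(self, rng):
        p = small_env(rng, 201)
        b = small_env(rng, 300)
        fset = build_features(p, b, MaxentSettings(hinge_knots=5, threshold_knots=5))
        classes = {f.beta_class for f in fset.features}
        assert classes == {"linear", "quadratic", "product", "hinge", "threshold"}

    def test_categorical_three_levels(self, rng):
        p = pd.DataFrame({"soil": [1.0, 2.0, 3.0, 1.0, 2.0]})
        b = pd.DataFrame({"soil": [1.0, 2.0, 3.0] * 10})
        fset = build_features(p, b, MaxentSettings(), categorical=["soil"])
        cats = [f for f in fset.features if f.cls == "categorical"]
        assert len(cats) == 3
        assert sorted(f.level for f in cats) == [1.0, 2.0, 3.0]

    def test_features_bounded_unit_interval(self, rng):
        p = small_env(rng, 100)
        b = small_env(rng, 200)
        fset = build_features(
            p, b, MaxentSettings(hinge_knots=8, threshold_knots=8)
        )
        for env in (p, b):
            f = fset.transform(env)
            assert f.min() >= 0.0 and f.max() <= 1.0

    def test_constant_variable_warns(self, rng):
        p = pd.DataFrame({"A": np.zeros(20), "B": rng.normal(size=20)})
        b = pd.DataFrame({"A": np.zeros(30), "B": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            fset = build_features(p, b, MaxentSettings())
        assert all(f.var != "A" for f in fset.features)

    def test_out_of_range_projection_clamped(self, rng):
        p = small_env(rng, 30, ["A"])
        b = small_env(rng, 60, ["A"])
        fset = build_features(p, b, MaxentSettings(hinge_knots=4))
        wild = pd.DataFrame({"A": [1e6, -1e6]})
        f = fset.transform(wild)
        assert f.min() >= 0.0 and f.max() <= 1.0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_full_shrinkage_uniform(self, rng):
        p = small_env(rng, 30)
        b = small_env(rng, 50)
        model = fit(p, b, MaxentSettings(regularization_multiplier=1e6))
        np.testing.assert_allclose(model.weights, 0.0)
        assert model.gain == pytest.approx(0.0)
        raw = predict(model, b, "raw")
        np.testing.assert_allclose(raw, 1.0 / 50)

    def test_no_signal_zero_gain(self, rng):
        b = small_env(rng, 60, ["A"])
        model = fit(b.copy(), b, MaxentSettings(feature_classes=["linear"]))
        assert abs(model.gain) < 1e-6
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-6)

    def test_golden_section_oracle_1d(self):
        # 10-cell background, 1 linear feature, beta = 0.05, 5 presences at
        # high feature values
        b = pd.DataFrame({"A": np.linspace(0.0, 1.0, 10)})
        p = pd.DataFrame({"A": [0.8, 0.85, 0.9, 0.95, 1.0]})
        settings = MaxentSettings(
            feature_classes=["linear"], beta_override=0.05,
            convergence_threshold=1e-14, max_iterations=10000,
        )
        model = fit(p, b, settings)
        fset = model.feature_set
        f_b = fset.transform(b)[:, 0]
        pbar = fset.transform(p)[:, 0].mean()

        def gain(lam):
            return lam * pbar - logsumexp(lam * f_b) + np.log(10) - 0.05 * abs(lam)

        lo, hi = -20.0, 20.0
        invphi = (np.sqrt(5) - 1) / 2
        while hi - lo > 1e-10:
            m1 = hi - invphi * (hi - lo)
            m2 = lo + invphi * (hi - lo)
            if gain(m1) < gain(m2):
                lo = m1
            else:
                hi = m2
        lam_star = (lo + hi) / 2
        assert abs(model.weights[0] - lam_star) < 1e-4

    def test_grid_search_oracle_2d(self, rng):
        # dense lambda grid on a 2-feature, 20-background instance
        b = small_env(rng, 20)
        p = b.iloc[[0, 3, 5, 7, 11, 13, 17, 19]].reset_index(drop=True) + 0.3
        settings = MaxentSettings(
            feature_classes=["linear"], beta_override=0.1,
            convergence_threshold=1e-12, max_iterations=10000,
        )
        model = fit(p, b, settings)
        fset = model.feature_set
        f_b = fset.transform(b)
        pbar = fset.transform(p).mean(axis=0)
        grid = np.arange(-4, 4.0001, 0.02)
        lam = np.array(list(itertools.product(grid, grid)))
        gains = (
            lam @ pbar
            - logsumexp(lam @ f_b.T, axis=1)
            + np.log(20)
            - 0.1 * np.abs(lam).sum(axis=1)
        )
        assert abs(model.gain - gains.max()) < 1e-3

    def test_raw_sums_to_one(self, rng):
        p = small_env(rng, 40)
        b = small_env(rng, 100)
        model = fit(p + 0.5, b, MaxentSettings(hinge_knots=5))
        raw = predict(model, b, "raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)

    def test_gain_monotone_nondecreasing(self, rng):
        p = small_env(rng, 40) + 0.4
        b = small_env(rng, 100)
        model = fit(p, b, MaxentSettings(hinge_knots=5))
        path = np.array(model.gain_path)
        assert path[0] == 0.0
        assert (np.diff(path) >= -1e-12).all()
        assert model.gain >= 0.0

    def test_weights_shrink_with_multiplier(self, rng):
        p = small_env(rng, 50) + 0.5
        b = small_env(rng, 120)
        norms = []
        for mult in (0.5, 1.0, 2.0, 5.0, 50.0):
            model = fit(
                p, b, MaxentSettings(regularization_multiplier=mult, hinge_knots=5)
            )
            norms.append(np.abs(model.weights).max())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_too_few_presences(self, rng):
        b = small_env(rng, 10)
        with pytest.raises(ValueError, match="at least 2"):
            fit(b.iloc[:1], b, MaxentSettings())

    def test_entropy_bounds(self, rng):
        p = small_env(rng, 40) + 0.5
        b = small_env(rng, 80)
        model = fit(p, b, MaxentSettings(hinge_knots=5))
        assert 0.0 <= model.entropy <= np.log(80) + 1e-12

    def test_json_roundtrip(self, rng, tmp_path):
        p = small_env(rng, 30) + 0.3
        b = small_env(rng, 60)
        model = fit(p, b, MaxentSettings(hinge_knots=4))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MaxentModel.from_json(path)
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.log_z == pytest.approx(model.log_z)
        np.testing.assert_allclose(
            predict(back, b, "cloglog"), predict(model, b, "cloglog")
        )


# ---------------------------------------------------------------------------
# Prediction outputs
# ---------------------------------------------------------------------------

def _two_cell_model():
    """Hand-built model whose raw distribution over a 2-cell background is
    (0.9, 0.1)."""
    lam = np.log(9.0)
    fset = FeatureSet(
        features=[Feature(var="A", cls="linear", lo=0.0, hi=1.0)],
        variables=["A"], categorical=[], var_range={"A": (0.0, 1.0)},
    )
    log_z = float(np.log(np.exp(lam) + 1.0))
    entropy = float(-(0.9 * np.log(0.9) + 0.1 * np.log(0.1)))
    return MaxentModel(
        feature_set=fset, weights=np.array([lam]), log_z=log_z, entropy=entropy,
        settings=MaxentSettings(), gain=0.0, n_presence=2, n_background=2,
        iterations=1, background_env=pd.DataFrame({"A": [1.0, 0.0]}),
    )


class TestPredict:
    def test_uniform_limit_closed_form(self, rng):
        p = small_env(rng, 20)
        b = small_env(rng, 40)
        model = fit(p, b, MaxentSettings(regularization_multiplier=1e6))
        cll = predict(model, b, "cloglog")
        np.testing.assert_allclose(cll, 1.0 - np.exp(-1.0), rtol=1e-12)

    def test_two_cell_hand_oracle(self):
        model = _two_cell_model()
        env = pd.DataFrame({"A": [1.0, 0.0]})
        raw = predict(model, env, "raw")
        np.testing.assert_allclose(raw, [0.9, 0.1], rtol=1e-12)
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        expected = 1.0 - np.exp(-np.exp(h) * np.array([0.9, 0.1]))
        np.testing.assert_allclose(predict(model, env, "cloglog"), expected)

    def test_logistic_formula(self):
        model = _two_cell_model()
        env = pd.DataFrame({"A": [1.0, 0.0]})
        tau = model.settings.prevalence_tau
        eh_r = np.exp(model.entropy) * np.array([0.9, 0.1])
        expected = tau * eh_r / (1 - tau + tau * eh_r)
        np.testing.assert_allclose(predict(model, env, "logistic"), expected)

    def test_cloglog_monotone_in_score(self, rng):
        p = small_env(rng, 50, ["A"]) + 1.0
        b = small_env(rng, 100, ["A"])
        model = fit(p, b, MaxentSettings(feature_classes=["linear"]))
        sweep = pd.DataFrame({"A": np.linspace(-3, 3, 50)})
        cll = predict(model, sweep, "cloglog")
        assert model.weights[0] > 0
        assert (np.diff(cll) >= 0).all()
        assert ((cll > 0) & (cll < 1)).all()


class TestAUC:
    def test_perfect_separation(self):
        assert auc_scores([5.0, 6.0], [1.0, 2.0, 3.0]) == 1.0

    def test_all_identical(self):
        assert auc_scores([1.0, 1.0], [1.0, 1.0, 1.0]) == 0.5

    def test_exhaustive_pair_oracle(self, rng):
        p = rng.normal(size=4)
        b = rng.normal(size=6)
        wins = sum(
            1.0 if ps > bs else (0.5 if ps == bs else 0.0)
            for ps in p for bs in b
        )
        assert auc_scores(p, b) == pytest.approx(wins / 24.0)

    def test_ties_half_credit(self):
        assert auc_scores([2.0], [1.0, 2.0, 3.0]) == pytest.approx(
            (1.0 + 0.5 + 0.0) / 3
        )


# ---------------------------------------------------------------------------
# Importance
# ---------------------------------------------------------------------------

class TestImportance:
    def test_single_variable_all_credit(self, rng):
        p = small_env(rng, 40, ["A"]) + 1.0
        b = small_env(rng, 80, ["A"])
        model = fit(p, b, MaxentSettings(feature_classes=["linear"]))
        rep = importance(model, p, b, seed=0)
        assert rep.percent_contribution["A"] == pytest.approx(100.0)
        assert rep.permutation_importance["A"] == pytest.approx(100.0)

    def test_columns_sum_to_100(self, rng):
        p = small_env(rng, 60, ["A", "B", "C"])
        p["A"] += 1.5
        b = small_env(rng, 150, ["A", "B", "C"])
        model = fit(p, b, MaxentSettings(hinge_knots=4))
        rep = importance(model, p, b, seed=0)
        assert sum(rep.percent_contribution.values()) == pytest.approx(100.0, abs=0.1)
        assert sum(rep.permutation_importance.values()) == pytest.approx(100.0, abs=0.1)

    def test_signal_variable_dominates_permutation(self, rng):
        n_p, n_b = 200, 1000
        b = small_env(rng, n_b, ["A", "B"])
        p = small_env(rng, n_p, ["A", "B"])
        p["A"] = p["A"] * 0.3 + 2.0  # presence depends on A only
        model = fit(p, b, MaxentSettings(hinge_knots=5))
        rep = importance(model, p, b, seed=0, jackknife=False)
        assert rep.permutation_importance["A"] > 90.0

    def test_jackknife_gains_nested_below_full(self, rng):
        p = small_env(rng, 60, ["A", "B"])
        p["A"] += 1.0
        b = small_env(rng, 150, ["A", "B"])
        model = fit(p, b, MaxentSettings(hinge_knots=4))
        rep = importance(model, p, b, seed=0)
        tol = 1e-3
        for v in ("A", "B"):
            assert rep.gain_with_only[v] <= model.gain + tol
            assert rep.gain_without[v] <= model.gain + tol


# ---------------------------------------------------------------------------
# Response curves and projection
# ---------------------------------------------------------------------------

class TestResponseCurve:
    def test_positive_linear_increasing(self, rng):
        p = small_env(rng, 50, ["A"]) + 1.0
        b = small_env(rng, 100, ["A"])
        model = fit(p, b, MaxentSettings(feature_classes=["linear"]))
        _, curve = response_curve(model, "A", n_points=30)
        assert (np.diff(curve) >= 0).all()

    def test_categorical_one_per_level(self, rng):
        p = pd.DataFrame({"A": rng.normal(size=30) + 1,
                          "soil": rng.choice([1.0, 2.0, 3.0], 30)})
        b = pd.DataFrame({"A": rng.normal(size=60),
                          "soil": rng.choice([1.0, 2.0, 3.0], 60)})
        model = fit(p, b, MaxentSettings(hinge_knots=4), categorical=["soil"])
        levels, curve = response_curve(model, "soil")
        assert len(levels) == len(curve) == 3

    def test_zero_weight_variable_constant_curve(self, rng):
        p = small_env(rng, 40, ["A", "B"])
        p["A"] += 2.0
        b = small_env(rng, 100, ["A", "B"])
        model = fit(p, b, MaxentSettings(feature_classes=["linear"]))
        # force B's weight to zero and check its curve is flat
        for j, f in enumerate(model.feature_set.features):
            if f.var == "B":
                model.weights[j] = 0.0
        _, curve = response_curve(model, "B", n_points=10)
        np.testing.assert_allclose(curve, curve[0])

    def test_unknown_variable(self, rng):
        p = small_env(rng, 30, ["A"])
        b = small_env(rng, 60, ["A"])
        model = fit(p, b, MaxentSettings(feature_classes=["linear"]))
        with pytest.raises(KeyError):
            response_curve(model, "nope")


class TestProject:
    @pytest.fixture
    def trained(self, spec10, rng):
        stack = make_stack(
            spec10, {"A": rng.normal(size=(10, 10)), "B": rng.normal(size=(10, 10))}
        )
        bg = sample_background(stack, 60, seed=0)
        occ_xy = np.column_stack(
            [rng.uniform(0, 1000, 25), rng.uniform(0, 1000, 25)]
        )
        p_env = env_at_points(stack, occ_xy)
        model = fit(p_env, bg, MaxentSettings(hinge_knots=4))
        return stack, bg, model

    def test_uniform_model_constant_map(self, spec10, rng):
        stack = make_stack(spec10, {"A": rng.normal(size=(10, 10))})
        bg = sample_background(stack, 50, seed=0)
        p_env = bg.env.iloc[:10].reset_index(drop=True)
        model = fit(p_env, bg, MaxentSettings(regularization_multiplier=1e6))
        out = project(model, stack)
        np.testing.assert_allclose(
            out.values[out.valid_mask], 1.0 - np.exp(-1.0), rtol=1e-12
        )

    def test_pointwise_consistency_with_predict(self, trained):
        stack, bg, model = trained
        out = project(model, stack, "cloglog")
        preds = predict(model, bg.env, "cloglog")
        np.testing.assert_allclose(out.values[bg.rows, bg.cols], preds, rtol=1e-12)

    def test_nodata_propagates(self, spec10, rng):
        a = rng.normal(size=(10, 10))
        a[4, 4] = -9999.0
        stack = make_stack(spec10, {"A": a, "B": rng.normal(size=(10, 10))})
        bg = sample_background(stack, 50, seed=0)
        model = fit(bg.env.iloc[:10] + 0.5, bg, MaxentSettings(hinge_knots=4))
        out = project(model, stack)
        assert out.values[4, 4] == out.nodata

    def test_missing_layer_named(self, trained):
        stack, _, model = trained
        partial = RasterStack([stack["A"]])
        with pytest.raises(ValueError, match="B"):
            project(model, partial)
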