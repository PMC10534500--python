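"""Bayesian-regularized dissolution ANN and the restart-selection protocol."""

import numpy as np
import pytest

from dissomap.ann import (
    NotFittedError,
    ann_parameter_count,
    build_ann,
    predict_profile,
    train_bayesreg,
    train_ensemble,
)
from dissomap.design import calibration_designs, validation_designs, sieve_label_um
from dissomap.metrics import (
    DissolutionProfile,
    ProfilePair,
    dissolution_time_grid,
    f2_truncated,
)
from dissomap.synth.dissolution import simulate_dissolution


def truth_features(designs):
    x = np.array(
        [[100 * d.hpmc_frac, sieve_label_um(d.hpmc_size_fraction)] for d in designs]
    )
    y = np.stack([simulate_dissolution(d, noise_sd=0.0).released for d in designs])
    return x, y


class TestModel:
    @pytest.mark.parametrize("h", range(1, 11))
    def test_parameter_count_formula(self, h):
        assert ann_parameter_count(h) == (2 * h + h) + (37 * h + 37)
        assert build_ann(h).n_parameters == ann_parameter_count(h)

    def test_three_hidden_neurons_have_157_parameters(self):
        assert ann_parameter_count(3) == 157

    def test_hidden_range_enforced(self):
        with pytest.raises(ValueError, match="n_hidden"):
            build_ann(11)
        with pytest.raises(ValueError, match="n_hidden"):
            build_ann(0)

    def test_hidden_activations_bounded(self, rng):
        model = build_ann(4, seed=1)
        z = model.hidden(rng.normal(scale=3, size=(100, 2)))
        assert np.all(np.abs(z) <= 1.0)  # tanh range (saturates in float64)
        assert np.abs(z).min() < 1.0

    def test_param_vector_roundtrip(self):
        model = build_ann(5, seed=2)
        theta = model.get_params()
        other = build_ann(5, seed=99)
        other.set_params(theta)
        assert np.array_equal(other.get_params(), theta)
        x = np.random.default_rng(0).normal(size=(5, 2))
        assert np.allclose(other.forward_scaled(x), model.forward_scaled(x))

    def test_unfitted_predict_raises(self):
        with pytest.raises(NotFittedError):
            build_ann(2).predict(np.zeros((1, 2)))


class TestNormalEquations:
    def test_match_finite_difference_jacobian(self, rng):
        from dissomap.ann import _normal_equations

        model = build_ann(3, seed=7)
        x = rng.normal(size=(6, 2))
        y = rng.normal(size=(6, 37))
        r = model.forward_scaled(x) - y
        jtj, jtr = _normal_equations(model, x, r)

        theta0 = model.get_params()
        eps = 1e-6
        jac = np.zeros((r.size, theta0.size))
        for k in range(theta0.size):
            t = theta0.copy()
            t[k] += eps
            model.set_params(t)
            rp = model.forward_scaled(x) - y
            jac[:, k] = (rp - r).ravel() / eps
        model.set_params(theta0)
        assert np.allclose(jtj, jac.T @ jac, atol=1e-4)
        assert np.allclose(jtr, jac.T @ r.ravel(), atol=1e-5)


class TestTraining:
    def test_fits_noiseless_linear_map(self, rng):
        x = rng.uniform(-1, 1, size=(60, 2))
        a = rng.normal(size=(2, 37))
        y = x @ a + rng.normal(size=37)
        model = build_ann(4, seed=1)
        state = train_bayesreg(model, x, y, max_epochs=300)
        assert state.epochs_used <= 300
        assert state.mse[-1] < 1e-3

    def test_epoch_cap_respected(self, rng):
        x = rng.uniform(0, 1, size=(20, 2))
        y = rng.uniform(0, 1, size=(20, 37))
        state = train_bayesreg(build_ann(2, seed=0), x, y, max_epochs=7)
        assert state.epochs_used <= 7

    def test_gradient_stop_on_converged_problem(self):
        # constant targets: the optimum is exact, gradient collapses
        x = np.random.default_rng(1).uniform(0, 1, size=(30, 2))
        y = np.tile(np.linspace(5, 90, 37), (30, 1))
        model = build_ann(1, seed=0)
        state = train_bayesreg(model, x, y, max_epochs=1000, update_hyperparams=False)
        assert "gradient" in state.termination or "damping" in state.termination
        assert state.epochs_used < 1000

    def test_without_hyperparam_updates_objective_is_plain_mse(self, rng):
        x = rng.uniform(-1, 1, size=(40, 2))
        y = x @ rng.normal(size=(2, 37))
        model = build_ann(3, seed=2)
        state = train_bayesreg(
            model, x, y, max_epochs=50, update_hyperparams=False, alpha0=0.0
        )
        n_res = 40 * 37
        assert np.allclose(state.objective, np.array(state.mse) * n_res, rtol=1e-9)

    def test_regularization_keeps_gamma_in_range(self, rng):
        x = rng.uniform(-1, 1, size=(50, 2))
        y = x @ rng.normal(size=(2, 37)) + rng.normal(scale=0.1, size=(50, 37))
        model = build_ann(4, seed=3)
        state = train_bayesreg(model, x, y, max_epochs=60)
        assert all(0 < g <= model.n_parameters for g in state.gamma)
        assert all(a > 0 for a in state.alpha) and all(b > 0 for b in state.beta)

    def test_input_shape_guards(self):
        with pytest.raises(ValueError, match=r"\(n, 2\)"):
            train_bayesreg(build_ann(2), np.zeros((5, 3)), np.zeros((5, 37)))
        with pytest.raises(ValueError, match="37"):
            train_bayesreg(build_ann(2), np.zeros((5, 2)), np.zeros((5, 36)))


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        x, y = truth_features(calibration_designs())
        model = build_ann(5, seed=3)
        train_bayesreg(model, x, y, max_epochs=150)
        return model

    def test_profile_contract(self, trained):
        prof = predict_profile(trained, 20.0, 45.0)
        assert len(prof) == 37
        assert np.array_equal(prof.times, dissolution_time_grid())
        assert np.all(np.isfinite(prof.released))
        assert np.all((prof.released >= 0.0) & (prof.released <= 110.0))

    def test_more_hpmc_predicts_slower_release(self, trained):
        lo = predict_profile(trained, 12.0, 45.0)
        hi = predict_profile(trained, 28.0, 45.0)
        at_480 = list(lo.times).index(480)
        assert hi.released[at_480] < lo.released[at_480]

    def test_recovers_validation_profiles(self, trained):
        xv, yv = truth_features(validation_designs())
        grid = dissolution_time_grid()
        scores = [
            f2_truncated(
                ProfilePair(DissolutionProfile(grid, t), DissolutionProfile(grid, p))
            )
            for t, p in zip(yv, trained.predict(xv))
        ]
        assert np.mean(scores) >= 70.0


class TestEnsemble:
    @pytest.fixture(scope="class")
    def small_selection(self):
        x, y = truth_features(calibration_designs())
        xv, yv = truth_features(validation_designs())
        grid = dissolution_time_grid()
        profiles = [DissolutionProfile(grid, row) for row in yv]
        return train_ensemble(
            x, y, xv, profiles, runs=2, hidden_range=range(2, 5),
            master_seed=11, max_epochs=80,
        )

    def test_score_table_covers_all_configs(self, small_selection):
        table = small_selection.scores
        assert len(table) == 6  # 3 widths x 2 runs
        assert set(table["n_hidden"]) == {2, 3, 4}

    def test_best_is_argmax_of_table(self, small_selection):
        assert small_selection.best_score == small_selection.scores["mean_f2"].max()
        row = small_selection.scores.loc[small_selection.scores["mean_f2"].idxmax()]
        assert (row["n_hidden"], row["run"]) == (
            small_selection.best_n_hidden,
            small_selection.best_run,
        )

    def test_deterministic_selection(self):
        x, y = truth_features(calibration_designs())
        xv, yv = truth_features(validation_designs())
        grid = dissolution_time_grid()
        profiles = [DissolutionProfile(grid, row) for row in yv]
        kwargs = dict(runs=1, hidden_range=range(2, 4), master_seed=5, max_epochs=40)
        a = train_ensemble(x, y, xv, profiles, **kwargs)
        b = train_ensemble(x, y, xv, profiles, **kwargs)
        assert a.scores.equals(b.scores)
        assert np.array_equal(a.best_model.get_params(), b.best_model.get_params())

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_ensemble(np.zeros((4, 2)), np.zeros((4, 37)), np.zeros((0, 2)), [])
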