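"""Design assembly, penalized solver, GCV selection and prediction."""

import numpy as np
import pandas as pd
import pytest

import ergsurf as es
from ergsurf.errors import PredictionRangeError, SaturatedFitError
from ergsurf.gam import _GCVObjective, assemble_design, gcv_score, solve_penalized

from conftest import make_bilinear_dataset


def random_penalized_problem(rng, n=25, p=6):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    # two random PSD penalties
    pens = []
    for _ in range(2):
        R = rng.normal(size=(p, p))
        pens.append(R.T @ R)
    lams = 10.0 ** rng.uniform(-3, 3, size=2)
    return X, y, pens, lams


def augmented_ols(X, y, penalties, lambdas):
    """Stacked-OLS oracle: append sqrt(lam)*S^{1/2} rows with zero response."""
    rows = [X]
    rhs = [y]
    for lam, S in zip(lambdas, penalties):
        w, V = np.linalg.eigh(S)
        w = np.clip(w, 0, None)
        root = (V * np.sqrt(w)) @ V.T
        rows.append(np.sqrt(lam) * root)
        rhs.append(np.zeros(S.shape[0]))
    Xa = np.vstack(rows)
    ya = np.concatenate(rhs)
    return np.linalg.lstsq(Xa, ya, rcond=None)[0]


class TestSolvePenalized:
    def test_matches_augmented_regression_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            X, y, pens, lams = random_penalized_problem(rng)
            beta, _, _ = solve_penalized(X, y, pens, lams)
            expect = augmented_ols(X, y, pens, lams)
            assert np.max(np.abs(beta - expect)) < 1e-8

    def test_zero_lambda_limit_is_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        beta, tr, rss = solve_penalized(X, y, [np.eye(5)], [1e-14])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-8)
        assert abs(tr - 5) < 1e-6  # projection trace = p

    def test_ridge_limit_shrinks_block_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        S = np.zeros((5, 5))
        S[3:, 3:] = np.eye(2)  # penalize only last two coefficients
        beta, _, _ = solve_penalized(X, y, [S], [1e12])
        assert np.max(np.abs(beta[3:])) < 1e-8

    def test_singularity_reported(self):
        X = np.ones((10, 2))  # duplicated column, no penalty to rescue it
        y = np.arange(10.0)
        with pytest.raises(es.gam.SingularModelError):
            solve_penalized(X, y, [np.zeros((2, 2))], [1.0])


class TestGCVScore:
    def test_perfect_fit_scores_zero(self):
        assert gcv_score(0.0, 10, 3.0) == 0.0

    def test_formula_arithmetic(self):
        assert gcv_score(2.5, 10, 4.0) == pytest.approx(10 * 2.5 / 36, abs=1e-12)

    def test_saturated_fit_rejected(self):
        with pytest.raises(SaturatedFitError):
            gcv_score(1.0, 5, 5.0)


class TestAssembleDesign:
    def test_indicator_block_structure(self):
        frame = pd.DataFrame({
            "subject_id": ["a"] * 3 + ["b"] * 3,
            "eye": "right",
            "group": "g",
            "flash_td_s": [100.0, 100, 178, 100, 100, 178],
            "time_ms": [0.0, 1, 2, 0, 1, 2],
            "amplitude_uv": 1.0,
        })
        b = assemble_design(es.WaveformDataset(frame), es.ModelSpec(k_t=4, k_fs=4))
        R = b.blocks["random"]
        assert R.shape == (6, 2)
        assert np.array_equal(R.sum(axis=1), np.ones(6))
        assert b.X.shape[1] == 1 + 2 + (4 * 4 - 1)

    def test_single_unit_rejected(self, small_spec):
        frame = pd.DataFrame({
            "subject_id": "only",
            "eye": "right",
            "group": "g",
            "flash_td_s": 100.0,
            "time_ms": np.arange(10.0),
            "amplitude_uv": 0.0,
        })
        with pytest.raises(ValueError):
            assemble_design(es.WaveformDataset(frame), small_spec)

    def test_per_eye_unit_doubles_units(self, bilinear_data):
        spec = es.ModelSpec(k_t=6, k_fs=4, random_effect_unit="per_eye")
        b = assemble_design(bilinear_data, spec)
        assert b.n_units == 4  # 4 subjects x 1 eye in the fixture

    def test_infinite_ridge_equals_dropping_random_block(self, bilinear_data):
        """lambda_b -> inf forces b = 0, matching a fit without the block."""
        data = make_bilinear_dataset(noise=1.0, seed=4)
        spec = es.ModelSpec(k_t=6, k_fs=4)
        b = assemble_design(data, spec)
        lam = [1.0, 1.0, 1e12]
        beta, _, _ = solve_penalized(b.X, b.y, b.penalties, lam)
        X0 = np.hstack([b.blocks["intercept"], b.blocks["smooth"]])
        pens0 = [P[np.ix_([0] + list(range(1 + b.n_units, b.X.shape[1])),
                          [0] + list(range(1 + b.n_units, b.X.shape[1])))]
                 for P in b.penalties[:2]]
        beta0, _, _ = solve_penalized(X0, b.y, pens0, lam[:2])
        fitted_full = b.X @ beta
        fitted_drop = X0 @ beta0
        assert np.max(np.abs(fitted_full - fitted_drop)) < 1e-6
        assert np.max(np.abs(beta[1:1 + b.n_units])) < 1e-8


class TestOptimizeLambdas:
    def test_selected_point_beats_grid(self, bilinear_data):
        data = make_bilinear_dataset(noise=2.0, seed=9)
        spec = es.ModelSpec(k_t=6, k_fs=4, n_grid=3)
        b = assemble_design(data, spec)
        lam, gcv = es.optimize_lambdas(b.X, b.y, b.penalties, spec)
        obj = _GCVObjective(b.X.T @ b.X, b.X.T @ b.y, float(b.y @ b.y), len(b.y), b.penalties)
        axis = np.linspace(*spec.lambda_bounds, spec.n_grid)
        grid_vals = [obj((a, c, d)) for a in axis for c in axis for d in axis]
        assert gcv <= min(grid_vals) + 1e-12

    def test_heavy_smoothing_collapses_edf_to_null_space(self):
        """As all lambdas grow, edf tends to the joint penalty null-space dim.

        Null space: intercept (unpenalized) + 3 free bilinear smooth
        directions (one absorbed by the constraint); random effects shrink
        to zero under their ridge.  A bilinear truth is still fitted
        without bias there.
        """
        data = make_bilinear_dataset(n_units=6, n_t=15, n_fs=6, noise=8.0, seed=7)
        spec = es.ModelSpec(k_t=6, k_fs=4)
        b = assemble_design(data, spec)
        _, tr, _ = solve_penalized(b.X, b.y, b.penalties, [1e8, 1e8, 1e8])
        assert tr < 4 + 1e-3
        assert tr > 4 - 0.5
        # and the GCV-selected fit remains unbiased for the bilinear truth
        clean = make_bilinear_dataset(n_units=6, n_t=15, n_fs=6, noise=0.0, seed=7)
        mu = clean.frame["amplitude_uv"].to_numpy()
        model = es.fit_gam(data, spec)
        beta = np.concatenate([[model.beta0], model.random_effects.to_numpy(),
                               model.smooth_coefs])
        fitted_pop = b.blocks["intercept"] @ beta[:1] + b.blocks["smooth"] @ beta[1 + b.n_units:]
        assert np.sqrt(np.mean((fitted_pop - mu) ** 2)) < 0.25 * np.ptp(mu)

    def test_stacked_copies_select_equivalent_smoothing(self):
        """Doubling the data must not change the fitted function."""
        data = make_bilinear_dataset(n_units=3, n_t=10, n_fs=5, noise=2.0, seed=6)
        spec = es.ModelSpec(k_t=5, k_fs=4, n_grid=3)
        b = assemble_design(data, spec)
        lam1, _ = es.optimize_lambdas(b.X, b.y, b.penalties, spec)
        beta1, _, _ = solve_penalized(b.X, b.y, b.penalties, lam1)
        X2 = np.vstack([b.X, b.X])
        y2 = np.concatenate([b.y, b.y])
        lam2, _ = es.optimize_lambdas(X2, y2, b.penalties, spec)
        beta2, _, _ = solve_penalized(X2, y2, b.penalties, lam2)
        fit1 = b.X @ beta1
        fit2 = b.X @ beta2
        scale = np.ptp(fit1)
        assert np.sqrt(np.mean((fit1 - fit2) ** 2)) < 0.02 * scale
        assert np.max(np.abs(fit1 - fit2)) < 0.06 * scale  # boundary wiggle

    def test_edf_monotone_in_each_lambda(self):
        data = make_bilinear_dataset(noise=1.0, seed=10)
        spec = es.ModelSpec(k_t=6, k_fs=4)
        b = assemble_design(data, spec)
        for axis in range(3):
            traces = []
            for lg in [-4, -2, 0, 2, 4]:
                lam = [1.0, 1.0, 1.0]
                lam[axis] = 10.0 ** lg
                _, tr, _ = solve_penalized(b.X, b.y, b.penalties, lam)
                traces.append(tr)
            assert all(b <= a + 1e-8 for a, b in zip(traces, traces[1:]))


class TestFitGam:
    def test_noise_free_bilinear_reproduced_exactly(self, bilinear_fit, bilinear_data):
        model = bilinear_fit
        y = bilinear_data.frame["amplitude_uv"].to_numpy()
        b = assemble_design(bilinear_data, model.spec)
        beta = np.concatenate([[model.beta0], model.random_effects.to_numpy(), model.smooth_coefs])
        rss = float(np.sum((y - b.X @ beta) ** 2))
        assert rss / float(y @ y) < 1e-8

    def test_prediction_exact_at_data_points_noise_free(self, bilinear_fit, bilinear_data):
        row = bilinear_data.frame.iloc[37]
        est, se = es.predict_with_se(bilinear_fit, row.time_ms, row.flash_td_s)
        assert est == pytest.approx(row.amplitude_uv, abs=1e-6)
        assert se > 0

    def test_se_positive_inside_range(self, bilinear_fit):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.5, 29.5, 50)
        fs = rng.uniform(15, 440, 50)
        _, se = es.predict_with_se(bilinear_fit, t, fs)
        assert np.all(se > 0)

    def test_out_of_range_prediction_rejected(self, bilinear_fit):
        with pytest.raises(PredictionRangeError):
            es.predict_with_se(bilinear_fit, 35.0, 100.0)
        with pytest.raises(PredictionRangeError):
            es.predict_with_se(bilinear_fit, 10.0, 500.0)

    def test_random_effects_centered(self, synthetic_fit):
        model, _, _ = synthetic_fit
        b = model.random_effects.to_numpy()
        assert abs(b.mean()) < 0.5 * b.std()

    def test_se_matches_monte_carlo_propagation(self):
        """Posterior-draw oracle: SE == sd of predictions over coefficient draws."""
        data = make_bilinear_dataset(n_units=2, n_t=5, n_fs=2, noise=1.5, seed=3)
        spec = es.ModelSpec(k_t=4, k_fs=4)
        model = es.fit_gam(data, spec)
        t0, fs0 = 12.0, 180.0
        est, se = es.predict_with_se(model, t0, fs0)
        idx = np.concatenate([[0], np.arange(1 + model.n_units, model.coef_covariance.shape[0])])
        V = model.coef_covariance[np.ix_(idx, idx)]
        x = np.concatenate([[1.0], model.smooth.design_rows(np.array([t0]), np.array([fs0]))[0]])
        rng = np.random.default_rng(99)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
        draws = rng.standard_normal((50_000, len(V))) @ L.T
        mc_sd = (draws @ x).std()
        assert se == pytest.approx(mc_sd, rel=0.01)

    def test_recovery_improves_with_cohort_size(self):
        """Surface RMSE decreases as subjects per group grow 10 -> 40 -> 160."""
        params = es.SyntheticParams(n_samples=50)
        spec = es.ModelSpec(k_t=12, k_fs=6)
        ta = np.linspace(-20, 31, 60)
        fa = np.linspace(12, 446, 30)
        rmses = []
        for n_sub in (10, 40, 160):
            design = es.DesignTable.balanced(n_sub, groups=("control",))
            data, truth = es.generate_dataset(design, params, seed=21)
            model = es.fit_gam(data, spec, group="control")
            rmses.append(es.recovery_error(model, truth, ta, fa, "control"))
        assert rmses[1] < rmses[0] * 1.05
        assert rmses[2] < rmses[1] * 1.05

    def test_sigma_estimates_positive(self, synthetic_fit):
        model, _, params = synthetic_fit
        assert model.sigma2 > 0
        assert model.sigma2_b >= 0
        assert model.sigma2**0.5 == pytest.approx(params.sigma_eps, rel=0.2)
        assert 1 <= model.edf <= model.coef_covariance.shape[0]
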