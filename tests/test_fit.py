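"""Constrained weight fitting, the mixed threshold model, and descriptives."""

import itertools

import numpy as np
import pandas as pd
import pytest

from binauralgap import (
    BandWeightModel,
    PopulationSpec,
    ThresholdMatrix,
    correlate_bands,
    fit_cf_curve,
    fit_threshold_model,
    fit_weights,
    generate_matrix,
    generate_threshold_observations,
    predict_Tprime,
)


def simplex_grid_search(A, b, resolution=0.01):
    """Exhaustive oracle: best objective on the simplex grid (m <= 3)."""
    m = A.shape[1]
    steps = int(round(1.0 / resolution))
    best, best_w = np.inf, None
    if m == 2:
        combos = ((i, steps - i) for i in range(steps + 1))
    else:
        combos = (
            (i, j, steps - i - j)
            for i in range(steps + 1)
            for j in range(steps + 1 - i)
        )
    for c in combos:
        w = np.asarray(c, dtype=float) / steps
        obj = float(np.sum((A @ w - b) ** 2))
        if obj < best:
            best, best_w = obj, w
    return best, best_w


class TestBandWeights:
    def test_exact_two_band_recovery(self, rng):
        t = rng.uniform(2.0, 10.0, size=(10, 2))
        T = 0.6 * t[:, 0] + 0.4 * t[:, 1]
        res = BandWeightModel((t, T)).fit()
        np.testing.assert_allclose(res.omega, [0.6, 0.4], atol=1e-6)
        assert np.max(np.abs(res.residuals)) < 1e-8
        assert res.r_squared == pytest.approx(1.0)

    def test_simplex_feasibility(self, rng):
        for s in range(10):
            m = generate_matrix(PopulationSpec(), seed=s)
            res = fit_weights(m)
            assert res.omega.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(res.omega >= -1e-12)

    def test_matches_grid_search_oracle_m3(self, rng):
        t = rng.uniform(2.0, 10.0, size=(12, 3))
        T = 0.5 * t[:, 0] + 0.3 * t[:, 1] + 0.2 * t[:, 2] + rng.normal(0, 0.3, 12)
        res = BandWeightModel((t, T)).fit()
        obj_grid, _ = simplex_grid_search(t, T, 0.01)
        assert 2 * res.objective <= obj_grid + 1e-9

    def test_active_constraints_when_target_outside_hull(self, rng):
        """Targets below every column force weights onto the boundary."""
        t = rng.uniform(5.0, 10.0, size=(12, 3))
        t[:, 2] = rng.uniform(1.0, 2.0, 12)  # only column 2 is small
        T = np.full(12, 1.5)
        res = BandWeightModel((t, T)).fit()
        assert 0 in res.active_constraints or 1 in res.active_constraints
        assert res.omega[2] > 0.9
        obj_grid, w_grid = simplex_grid_search(t, T, 0.01)
        assert 2 * res.objective <= obj_grid + 1e-9

    def test_convexity_certificate(self, rng):
        """The returned optimum beats 50 random feasible points."""
        m = generate_matrix(PopulationSpec(), seed=11)
        res = fit_weights(m)
        A, b = m.t_ij, m.T_i
        for _ in range(50):
            w = rng.dirichlet(np.ones(5))
            assert np.sum((A @ res.omega - b) ** 2) <= np.sum((A @ w - b) ** 2) + 1e-9

    def test_recovery_from_generated_data(self):
        """Known simplex weights are recovered under small measurement noise."""
        truth = np.asarray(PopulationSpec().true_weights)
        errs = [
            np.abs(fit_weights(generate_matrix(PopulationSpec(sigma_ms=0.1), seed=s)).omega
                   - truth).sum()
            for s in range(30)
        ]
        assert np.mean(errs) < 0.1

    def test_positivity_floor(self, rng):
        t = rng.uniform(2.0, 10.0, size=(12, 3))
        T = t[:, 0]  # wants omega = (1, 0, 0)
        res = BandWeightModel((t, T)).fit(positivity_floor=0.05)
        assert np.all(res.omega >= 0.05 - 1e-12)
        assert res.omega.sum() == pytest.approx(1.0)

    def test_underdetermined_warns(self, rng):
        t = rng.uniform(2.0, 10.0, size=(3, 5))
        T = t @ np.full(5, 0.2)
        with pytest.warns(UserWarning, match="fewer participants"):
            BandWeightModel((t, T))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            BandWeightModel((np.array([[1.0, np.nan]]), np.array([1.0])))


class TestPredictTprime:
    def test_noiseless_equals_mean_wideband(self):
        pop = PopulationSpec(sigma_ms=0.0)
        m = generate_matrix(pop, seed=2)
        res = fit_weights(m)
        assert predict_Tprime(res, m) == pytest.approx(np.mean(m.T_i), rel=1e-6)

    def test_single_participant_weighted_sum(self):
        t = np.array([[4.0, 2.0]])
        res_omega = np.array([0.5, 0.5])

        class Dummy:
            omega = res_omega

        assert predict_Tprime(Dummy(), t) == pytest.approx(3.0)

    def test_dimension_mismatch(self):
        m = generate_matrix(PopulationSpec(), seed=0)
        res = fit_weights(m)
        with pytest.raises(ValueError):
            predict_Tprime(res, np.ones((4, 3)))

    def test_unbiased_for_population_mean(self):
        """T' over many draws tracks the population wideband mean."""
        pop = PopulationSpec(sigma_ms=0.1)
        target = float(pop.profile_vector @ np.asarray(pop.true_weights))
        vals = [fit_weights(generate_matrix(pop, seed=s)).T_prime for s in range(50)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 4 * se + 0.05


class TestThresholdModel:
    def test_parameter_recovery(self):
        df = generate_threshold_observations(
            T_lambda_ms=8.0, T_beta_ms=-4.0, sigma_ms=0.2, seed=42
        )
        res = fit_threshold_model(df)
        assert abs(res.T_lambda_ms - 8.0) < 2 * res.se_T_lambda
        assert abs(res.T_beta_ms + 4.0) < 2 * res.se_T_beta
        assert res.sigma_ms == pytest.approx(0.2, abs=0.05)
        assert res.gamma_sd_ms == pytest.approx(1.0, abs=0.5)

    def test_zero_participant_variance_degenerate(self):
        df = generate_threshold_observations(gamma_sd_ms=0.0, sigma_ms=0.2, seed=3)
        res = fit_threshold_model(df)
        assert res.gamma_sd_ms < 0.2

    def test_fitted_values_reproduce_observations(self):
        df = generate_threshold_observations(seed=8)
        res = fit_threshold_model(df)
        pred = np.array(
            [res.predict(r.rho, participant=r.participant) for r in df.itertuples()]
        )
        resid = df.threshold_ms.to_numpy() - pred
        assert np.std(resid) == pytest.approx(res.sigma_ms, rel=0.3)

    def test_single_rho_rejected(self):
        df = pd.DataFrame(
            {"participant": [0, 0, 1, 1], "rho": [0.5] * 4, "threshold_ms": [1, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="slope unidentifiable"):
            fit_threshold_model(df)

    def test_single_participant_rejected(self):
        df = pd.DataFrame(
            {"participant": [0, 0], "rho": [0.2, 0.8], "threshold_ms": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="two participants"):
            fit_threshold_model(df)


class TestCorrelateBands:
    def test_identical_column_r_is_one(self):
        m = generate_matrix(PopulationSpec(), seed=5)
        m2 = ThresholdMatrix(
            t_ij=np.column_stack([m.T_i] + [m.t_ij[:, j] for j in range(1, 5)]),
            T_i=m.T_i,
            cf_labels=m.cf_labels,
        )
        rep = correlate_bands(m2)
        assert rep.r[0] == pytest.approx(1.0)

    def test_zero_variance_column_flagged(self):
        m = generate_matrix(PopulationSpec(), seed=6)
        t = m.t_ij.copy()
        t[:, 3] = 5.0
        rep = correlate_bands(ThresholdMatrix(t, m.T_i, m.cf_labels))
        assert np.isnan(rep.r[3])
        assert any("zero-variance" in f for f in rep.flags)

    def test_independent_columns_near_zero(self, rng):
        t = rng.normal(5.0, 1.0, size=(500, 5))
        T = rng.normal(5.0, 1.0, size=500)
        rep = correlate_bands(ThresholdMatrix(t, T, (200., 400., 800., 1600., 3200.)))
        assert np.all(np.abs(rep.r) < 0.15)

    def test_too_few_participants(self):
        m = ThresholdMatrix(np.ones((2, 2)), np.ones(2), (200.0, 400.0))
        with pytest.raises(ValueError):
            correlate_bands(m)

    def test_ordering_follows_weights_on_average(self):
        """Mean per-CF correlation decreases with CF when weights do."""
        acc = np.zeros(5)
        n_rep = 60
        for s in range(n_rep):
            rep = correlate_bands(generate_matrix(PopulationSpec(), seed=s))
            acc += rep.r / n_rep
        assert np.all(np.diff(acc) <= 0.02)
        assert acc[0] > acc[-1]


class TestCFCurve:
    def test_exact_loglinear_means(self):
        cfs = (200.0, 400.0, 800.0, 1600.0, 3200.0)
        means = 12.0 - 2.0 * np.log2(cfs)
        t = np.tile(means, (5, 1))
        m = ThresholdMatrix(t, np.ones(5), cfs)
        res = fit_cf_curve(m)
        assert res.r_squared == pytest.approx(1.0)
        assert res.params["slope"] == pytest.approx(-2.0)
        np.testing.assert_allclose(res.predict(cfs), means)

    def test_constant_means_zero_slope(self):
        cfs = (200.0, 400.0, 800.0)
        m = ThresholdMatrix(np.full((4, 3), 5.0), np.ones(4), cfs)
        res = fit_cf_curve(m)
        assert res.params["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_generated_data_good_fit(self):
        r2 = [fit_cf_curve(generate_matrix(PopulationSpec(), seed=s)).r_squared
              for s in range(20)]
        assert np.median(r2) > 0.9

    def test_logistic_family(self):
        m = generate_matrix(PopulationSpec(sigma_ms=0.1), seed=7)
        res = fit_cf_curve(m, family="logistic")
        assert res.r_squared > 0.8
        assert set(res.params) == {"lo", "hi", "c", "s"}

    def test_too_few_points(self):
        from binauralgap.fit import CFCurveModel

        with pytest.raises(ValueError):
            CFCurveModel(cf=[200.0, 400.0], means=[5.0, 4.0])
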