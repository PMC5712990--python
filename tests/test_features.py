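"""Tests for the causality-scenario feature space."""

import numpy as np
import pytest

from gclearn.features import (
    CausalityScenario,
    TrialScorer,
    build_lagged_problem,
    compute_features,
    engineer_features,
    enumerate_scenarios,
    featurize_dataset,
    fit_and_score,
    lagged_design,
    n_features,
    reduce_scenarios,
    ScenarioFeaturizer,
)
from gclearn.simulate import (
    generate_dataset,
    index_to_graph,
    sample_signal_coeffs,
    simulate_component,
)


def _brute_force_ols(design, targets):
    """Normal-equations oracle with explicit pseudo-inverse."""
    D = np.hstack([design, np.ones((design.shape[0], 1))])
    coef = np.linalg.pinv(D.T @ D) @ (D.T @ targets)
    resid = targets - D @ coef
    return coef, float(resid @ resid)


class TestScenarios:
    @pytest.mark.parametrize("M", [1, 2, 3, 4, 5])
    def test_count_law(self, M):
        assert len(enumerate_scenarios(M)) == (2**M - 1) * M

    def test_canonical_order_m3(self):
        scen = enumerate_scenarios(3)
        per_effect = [s for s in scen if s.effect == 0]
        assert [s.causes for s in per_effect] == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)
        ]
        assert [s.effect for s in scen] == [0] * 7 + [1] * 7 + [2] * 7

    def test_invalid_M(self):
        with pytest.raises(ValueError):
            enumerate_scenarios(0)

    @pytest.mark.parametrize("mode", ["pw", "c-pw"])
    def test_reduced_count_m3(self, mode):
        scen = reduce_scenarios(enumerate_scenarios(3), mode, 3)
        assert len(scen) == 9

    def test_reduced_families_m3(self):
        pw = reduce_scenarios(enumerate_scenarios(3), "pw", 3)
        assert CausalityScenario((1,), 1) in pw
        assert CausalityScenario((0, 1), 1) in pw
        cpw = reduce_scenarios(enumerate_scenarios(3), "c-pw", 3)
        assert CausalityScenario((0, 1, 2), 1) in cpw
        assert CausalityScenario((1, 2), 1) in cpw  # leave channel 0 out

    def test_m2_pw_cpw_coincide(self):
        pw = set(reduce_scenarios(enumerate_scenarios(2), "pw", 2))
        cpw = set(reduce_scenarios(enumerate_scenarios(2), "c-pw", 2))
        assert pw == cpw
        assert len(pw) == 4

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            reduce_scenarios(enumerate_scenarios(3), "bogus", 3)

    def test_complete_unchanged(self):
        scen = enumerate_scenarios(3)
        assert reduce_scenarios(scen, "complete", 3) == scen


class TestLaggedProblem:
    def test_window_construction(self):
        # scenario {0,1,2} -> 2 at p=10: the row for t=30 holds
        # x_c(20..29) for each channel, target x_2(30)
        N, M, p = 60, 3, 10
        X = np.arange(N * M, dtype=float).reshape(M, N).T  # x_c(t) = c*N + t
        prob = build_lagged_problem(X, CausalityScenario((0, 1, 2), 2), p)
        assert prob.design.shape == (N - p, M * p)
        row = prob.design[30 - p]
        expected = np.concatenate([c * N + np.arange(20, 30) for c in range(3)])
        np.testing.assert_array_equal(row, expected)
        assert prob.targets[30 - p] == 2 * N + 30

    def test_single_row_when_N_is_p_plus_1(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        prob = build_lagged_problem(X, CausalityScenario((0,), 1), 5)
        assert prob.design.shape == (1, 5)
        assert prob.targets.shape == (1,)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_lagged_problem(np.zeros((5, 2)), CausalityScenario((0,), 1), 5)

    def test_no_lookahead(self):
        # row for time t never contains any value at time >= t
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        p = 4
        prob = build_lagged_problem(X, CausalityScenario((0, 1), 0), p)
        for r in range(prob.design.shape[0]):
            t = r + p
            present = set(np.round(prob.design[r], 12))
            future = set(np.round(X[t:, :].ravel(), 12))
            assert not (present & future)


class TestFitAndScore:
    def test_exact_fit(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(50, 4))
        y = Z @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7
        prob = build_lagged_problem  # noqa: F841  (signature reference)
        from gclearn.features import RegressionProblem

        mse, r2, rv = fit_and_score(
            RegressionProblem(Z, y, CausalityScenario((0,), 0), 1)
        )
        assert mse == pytest.approx(0.0, abs=1e-18)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(2)
        n, k = 5000, 6
        from gclearn.features import RegressionProblem

        Z = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        _, r2, _ = fit_and_score(
            RegressionProblem(Z, y, CausalityScenario((0,), 0), 1)
        )
        assert abs(r2) < 5 * k / n + 0.01

    def test_constant_target_convention(self):
        from gclearn.features import RegressionProblem

        Z = np.random.default_rng(0).normal(size=(10, 2))
        y = np.full(10, 3.14)
        mse, r2, rv = fit_and_score(
            RegressionProblem(Z, y, CausalityScenario((0,), 0), 1)
        )
        assert r2 == 0.0
        assert mse == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_oracle(self):
        from gclearn.features import RegressionProblem

        rng = np.random.default_rng(3)
        Z = rng.normal(size=(4, 2))
        y = rng.normal(size=4)
        _, ssres = _brute_force_ols(Z, y)
        mse, _, _ = fit_and_score(
            RegressionProblem(Z, y, CausalityScenario((0,), 0), 1)
        )
        assert mse * 4 == pytest.approx(ssres, abs=1e-8)


class TestTrialScorer:
    """The gram-based fast path must agree with direct least squares."""

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_direct_lstsq(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 3))
        p = 4
        scorer = TrialScorer(X, p)
        for sc in enumerate_scenarios(3):
            mse_f, r2_f, rv_f = scorer.score(sc)
            mse_d, r2_d, rv_d = fit_and_score(build_lagged_problem(X, sc, p))
            assert mse_f == pytest.approx(mse_d, abs=1e-8)
            assert r2_f == pytest.approx(r2_d, abs=1e-8)
            assert rv_f == pytest.approx(rv_d, abs=1e-8)

    def test_nesting_inequality(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        scorer = TrialScorer(X, 3)
        scen = enumerate_scenarios(3)
        for a in scen:
            for b in scen:
                if a.effect == b.effect and set(a.causes) < set(b.causes):
                    mse_small = scorer.score(a)[0]
                    mse_big = scorer.score(b)[0]
                    assert mse_big <= mse_small + 1e-10


class TestFeatureVectors:
    def test_block_lengths_complete(self):
        rng = np.random.default_rng(0)
        fv = compute_features(rng.normal(size=(80, 3)), 4, "complete")
        assert fv.base.shape == (42,)
        assert fv.geweke.shape == (6,)
        assert len(fv.names) == 48

    def test_block_lengths_pw(self):
        rng = np.random.default_rng(0)
        fv = compute_features(rng.normal(size=(80, 3)), 4, "pw")
        assert fv.base.shape == (18,)
        assert fv.geweke.shape == (6,)

    def test_r2_le_1_and_mse_ge_0(self):
        rng = np.random.default_rng(1)
        fv = compute_features(rng.normal(size=(100, 3)), 5)
        mse = fv.base[0::2]
        r2 = fv.base[1::2]
        assert (mse >= 0).all()
        assert (r2 <= 1).all()

    def test_geweke_entries_near_zero_without_effect(self):
        # independent channels: the conditional ratios sit at the O(p/N) floor
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4000, 3))
        fv = compute_features(X, 5)
        assert np.abs(fv.geweke).max() < 10 * 5 / 4000

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(90, 3))
        v1 = compute_features(X, 4).values
        v2 = compute_features(X, 4).values
        np.testing.assert_array_equal(v1, v2)

    def test_no_lookahead_in_features(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 3))
        extended = np.vstack([X, rng.normal(size=(30, 3))])
        v1 = compute_features(X, 4).values
        v2 = compute_features(extended[:100], 4).values
        np.testing.assert_array_equal(v1, v2)

    def test_parameter_recovery_on_noiseless_trial(self):
        # OLS on the full-set scenario recovers the generating lag
        # coefficients of the effect channel within O(1/sqrt(N))
        rng = np.random.default_rng(8)
        p, M, N = 2, 3, 20000
        coeffs = sample_signal_coeffs(index_to_graph(63, M), p, rng)
        X = simulate_component(coeffs, N, 500, rng)
        prob = build_lagged_problem(X, CausalityScenario((0, 1, 2), 1), p)
        D = np.hstack([prob.design, np.ones((prob.design.shape[0], 1))])
        coef = np.linalg.lstsq(D, prob.targets, rcond=None)[0]
        # column c*p + k corresponds to lag tau = p - k of channel c;
        # generating weight for channel c at lag tau on effect j is coeffs[tau-1, c, j]
        j = 1
        for c in range(M):
            for k in range(p):
                tau = p - k
                assert coef[c * p + k] == pytest.approx(
                    coeffs[tau - 1, c, j], abs=5.0 / np.sqrt(N)
                )


class TestEngineering:
    def test_counts(self):
        assert n_features(3, "complete", True) == 1320
        assert n_features(3, "complete", False) == 48
        assert n_features(3, "pw", False) == 24

    def test_arithmetic_example(self):
        fv = compute_features(np.random.default_rng(0).normal(size=(60, 3)), 3)
        fv.base[:] = 0.0
        fv.base[0] = 4.0
        fv.geweke[:] = 0.0
        eng = engineer_features(fv)
        vals = dict(zip(eng.names, eng.values))
        name = fv.names[0]
        assert vals[f"({name})^2"] == 16.0
        assert vals[f"({name})^3"] == 64.0
        assert vals[f"ssqrt({name})"] == 2.0

    def test_zero_maps_to_zero(self):
        fv = compute_features(np.random.default_rng(0).normal(size=(60, 3)), 3)
        fv.base[:] = 0.0
        fv.geweke[:] = 0.0
        eng = engineer_features(fv)
        assert (eng.values == 0.0).all()

    def test_signed_sqrt_of_negative(self):
        fv = compute_features(np.random.default_rng(0).normal(size=(60, 3)), 3)
        fv.base[:] = 0.0
        fv.base[0] = -9.0
        fv.geweke[:] = 0.0
        eng = engineer_features(fv)
        vals = dict(zip(eng.names, eng.values))
        assert vals[f"ssqrt({fv.names[0]})"] == -3.0

    def test_pairwise_product_block(self):
        fv = compute_features(np.random.default_rng(1).normal(size=(60, 3)), 3)
        eng = engineer_features(fv)
        raw = np.concatenate([fv.base, fv.geweke])
        prod_block = eng.engineered[3 * raw.size:]
        iu, ju = np.triu_indices(raw.size, k=1)
        np.testing.assert_allclose(prod_block, raw[iu] * raw[ju])


class TestDatasetFeaturization:
    def test_matrix_shape_and_determinism(self):
        ds = generate_dataset(M=2, p=3, N=80, trials_per_graph=2, seed=1)
        F1, y1, names = featurize_dataset(ds, engineered=True)
        F2, y2, _ = featurize_dataset(ds, engineered=True)
        assert F1.shape == (8, n_features(2, "complete", True))
        np.testing.assert_array_equal(F1, F2)
        np.testing.assert_array_equal(y1, ds.graph_indices())
        assert len(names) == F1.shape[1]
        assert len(set(names)) == len(names)

    def test_transformer_matches_function(self):
        ds = generate_dataset(M=2, p=3, N=80, trials_per_graph=1, seed=2)
        F, _, names = featurize_dataset(ds, engineered=False)
        tf = ScenarioFeaturizer(p=3, mode="complete", engineered=False)
        F2 = tf.transform(ds.series())
        np.testing.assert_array_equal(F, F2)
        assert tf.feature_names_ == names

    def test_pw_names_are_subfamily(self):
        ds = generate_dataset(M=3, p=2, N=60, trials_per_graph=1, seed=3)
        _, _, full_names = featurize_dataset(ds, mode="complete",
                                             engineered=False)
        _, _, pw_names = featurize_dataset(ds, mode="pw", engineered=False)
        base_full = {n for n in full_names if n.startswith(("mse", "r2"))}
        base_pw = {n for n in pw_names if n.startswith(("mse", "r2"))}
        assert base_pw < base_full
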