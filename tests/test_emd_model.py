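from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdweight.emd_model import (
    EvalConfig,
    ModelState,
    ema,
    ema_weights,
    emd_series,
    fit,
    k_sweep,
    predict_emd,
    predict_post,
    rolling_evaluate,
)
from hdweight.errors import DataError
from hdweight.preprocess import NormStats, build_features
from hdweight.synthetic import SimulationConfig, simulate_cohort, simulate_patient
from tests.conftest import make_series


class TestEmaWeights:
    def test_normalized_n2(self):
        w = ema_weights(2, "normalized")
        assert w.rho == pytest.approx(1 / 3)
        assert w.alphas == pytest.approx([0.75, 0.25])

    def test_literal_n5_exact_rational_oracle(self):
        # independent oracle in exact rational arithmetic
        n = 5
        rho = Fraction(n - 1, n + 1)
        s = sum(rho**j for j in range(1, n + 1))
        expected = [rho] + [rho**i / (1 + s) for i in range(2, n + 1)]
        w = ema_weights(5, "literal")
        assert w.alphas == pytest.approx([float(e) for e in expected], abs=1e-15)
        assert w.alphas[0] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n", range(2, 13))
    @pytest.mark.parametrize("mode", ["normalized", "literal"])
    def test_positive_and_strictly_decreasing(self, n, mode):
        w = ema_weights(n, mode)
        assert np.all(w.alphas > 0)
        assert np.all(np.diff(w.alphas) < 0)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_normalized_sums_to_one(self, n):
        assert ema_weights(n, "normalized").alphas.sum() == pytest.approx(1.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(DataError):
            ema_weights(1)

    def test_unknown_mode_rejected(self):
        with pytest.raises(DataError):
            ema_weights(5, "geometric")


class TestEma:
    def test_constant_series_is_fixed_point(self):
        w = ema_weights(4, "normalized")
        assert ema([7.25] * 4, w) == pytest.approx(7.25)

    def test_two_point_arithmetic(self):
        w = ema_weights(2, "normalized")
        assert ema([60.0, 62.0], w) == pytest.approx(60.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            ema([1.0, 2.0, 3.0], ema_weights(2))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(2, 10), st.integers(0, 2**32 - 1), st.sampled_from(["normalized", "literal"]))
    def test_dot_product_oracle(self, n, seed, mode):
        rng = np.random.default_rng(seed)
        values = rng.uniform(40, 90, size=n)
        w = ema_weights(n, mode)
        oracle = sum(a * v for a, v in zip(w.alphas, values))
        assert ema(values, w) == pytest.approx(oracle, abs=1e-10)


class TestEmdSeries:
    def test_constant_posts_give_zero_emd(self):
        series = make_series([(62.0, 60.0, 2000.0)] * 10)
        for _, _, emd in emd_series(series, n=5):
            assert emd == pytest.approx(0.0)

    def test_step_change_gives_unit_emd(self):
        rows = [(62.0, 60.0, 2000.0)] * 8 + [(63.0, 61.0, 2000.0)]
        out = emd_series(make_series(rows), n=5)
        assert out[-1][2] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        rows = [(p + 2.0, p, 2000.0) for p in rng.uniform(55, 65, size=20)]
        series = make_series(rows)
        for t, ema_val, emd in emd_series(series, n=5):
            assert ema_val + emd == pytest.approx(series.sessions[t].post_weight, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            emd_series(make_series([(62.0, 60.0, 2000.0)] * 5), n=5)

    def test_uses_strictly_prior_sessions(self):
        # altering the target's own post-weight shifts emd one-for-one
        rows = [(62.0, 60.0 + 0.1 * i, 2000.0) for i in range(10)]
        base = emd_series(make_series(rows), n=5)
        rows[-1] = (62.0, rows[-1][1] + 1.0, 2000.0)
        bumped = emd_series(make_series(rows), n=5)
        assert bumped[-1][2] - base[-1][2] == pytest.approx(1.0)
        assert bumped[-1][1] == pytest.approx(base[-1][1])  # EMA unchanged


def _noisy_patient(seed=0, n_sessions=60):
    return simulate_cohort("stabilized", 1, n_sessions, seed=seed)[0]


class TestFit:
    def test_exact_linear_targets_interpolated(self):
        # target EMD is constant -> intercept alone fits with ~0 residual
        cfg = SimulationConfig(
            dw_drift=0.02, dw_rw_sd=0, gain_sd=0, saline_mean=0, saline_sd=0,
            post_noise_sd=0, n_sessions=40,
        )
        state = fit(simulate_patient(cfg))
        design = np.column_stack(
            [state.training_features, np.ones(len(state.training_emd))]
        )
        residuals = state.training_emd - design @ state.base_coefs
        assert np.all(np.abs(residuals) < 1e-8)

    def test_zero_targets_give_null_fit(self):
        series = make_series([(62.0, 60.0, 2000.0)] * 40)
        state = fit(series)
        assert np.allclose(state.base_coefs, 0.0, atol=1e-10)

    def test_normal_equations_oracle(self):
        state = fit(_noisy_patient())
        A = np.column_stack([state.training_features, np.ones(len(state.training_emd))])
        oracle = np.linalg.solve(A.T @ A, A.T @ state.training_emd)
        assert state.base_coefs == pytest.approx(oracle, abs=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(DataError, match="training pairs"):
            fit(make_series([(62.0, 60.0, 2000.0)] * 15), k=5)

    def test_incomplete_series_rejected(self):
        with pytest.raises(DataError):
            fit(make_series([(62.0, None, 2000.0)] * 40))


class TestPredictEmd:
    def test_tau_limit_matches_global_least_squares(self):
        series = _noisy_patient(seed=3)
        state = fit(series, tau=1e9)
        A = np.column_stack([state.training_features, np.ones(len(state.training_emd))])
        one_stage = np.linalg.lstsq(A, state.training_emd, rcond=None)[0]
        for t in (20, 30, 45):
            x = build_features(series, state.k, t)
            from hdweight.preprocess import apply_norm

            xn = apply_norm(x.to_array(), state.norm_stats)
            expected = float(np.append(xn, 1.0) @ one_stage)
            _, _, pred = predict_emd(state, x)
            assert pred == pytest.approx(expected, abs=1e-6)

    def test_weighted_normal_equations_oracle(self):
        # low-dimensional state so the kernel is non-degenerate at tau=2
        rng = np.random.default_rng(5)
        m, p = 60, 4
        X = rng.normal(size=(m, p))
        y = rng.normal(size=m)
        state = ModelState(
            k=1, n=2, tau=2.0, ema_mode="normalized", kernel_mode="sample_weight",
            norm_stats=NormStats(mean=np.zeros(p), std=np.ones(p)),
            base_coefs=np.zeros(p + 1),
            training_features=X, training_emd=y,
        )
        for _ in range(20):
            q = rng.normal(scale=0.5, size=p)
            w = np.exp(-np.sum((X - q) ** 2, axis=1) / (2 * state.tau**2))
            assert w.sum() >= p + 1
            A = np.column_stack([X, np.ones(m)])
            g = np.linalg.solve(A.T @ (A * w[:, None]), A.T @ (w * y))
            oracle = float(np.append(q, 1.0) @ g)
            base, delta, pred = predict_emd(state, q)
            assert delta == pytest.approx(oracle, abs=1e-8)
            assert pred == base + delta

    def test_degenerate_kernel_falls_back_to_base(self):
        rng = np.random.default_rng(1)
        m, p = 40, 4
        X = rng.normal(size=(m, p))
        state = ModelState(
            k=1, n=2, tau=0.01, ema_mode="normalized", kernel_mode="sample_weight",
            norm_stats=NormStats(mean=np.zeros(p), std=np.ones(p)),
            base_coefs=rng.normal(size=p + 1),
            training_features=X, training_emd=rng.normal(size=m),
        )
        q = rng.normal(size=p) + 10.0  # far from all training rows
        base, delta, pred = predict_emd(state, q)
        assert delta == 0.0
        assert pred == base

    def test_zero_residuals_give_zero_delta(self):
        rng = np.random.default_rng(2)
        m, p = 50, 4
        X = rng.normal(size=(m, p))
        coefs = rng.normal(size=p + 1)
        y = X @ coefs[:-1] + coefs[-1]
        state = ModelState(
            k=1, n=2, tau=2.0, ema_mode="normalized", kernel_mode="sample_weight",
            norm_stats=NormStats(mean=np.zeros(p), std=np.ones(p)),
            base_coefs=coefs, training_features=X, training_emd=y,
        )
        base, delta, pred = predict_emd(state, rng.normal(size=p))
        assert delta == pytest.approx(0.0, abs=1e-8)

    def test_elementwise_mode_runs_and_matches_global_at_large_tau(self):
        series = _noisy_patient(seed=9)
        state = fit(series, tau=1e9, kernel_mode="elementwise")
        x = build_features(series, state.k, 30)
        base, delta, pred = predict_emd(state, x)
        assert np.isfinite(pred)
        assert delta == pytest.approx(0.0, abs=1e-6)  # base is already global LS

    def test_non_finite_feature_rejected(self):
        state = fit(_noisy_patient())
        bad = np.full(state.n_features, np.nan)
        with pytest.raises(DataError):
            predict_emd(state, bad)


class TestPredictPost:
    def test_identity_post_pred_is_ema_plus_emd(self):
        series = _noisy_patient(seed=4)
        state = fit(series)
        r = predict_post(state, series, 40)
        assert r.post_pred == r.ema_value + r.emd_pred  # bitwise

    def test_stationary_patient_exact(self):
        series = make_series([(62.5, 60.0, 2000.0)] * 40)
        state = fit(series)
        r = predict_post(state, series, 35)
        assert r.post_pred == pytest.approx(60.0, abs=1e-9)
        assert r.abs_error == pytest.approx(0.0, abs=1e-9)

    def test_error_fields(self):
        series = _noisy_patient(seed=6)
        state = fit(series)
        r = predict_post(state, series, 30)
        assert r.abs_error == pytest.approx(abs(r.post_pred - r.post_actual))
        assert r.rel_error == pytest.approx(r.abs_error / r.post_actual)

    def test_insufficient_history_rejected(self):
        series = _noisy_patient()
        state = fit(series)
        with pytest.raises(DataError):
            predict_post(state, series, 3)


class TestRollingEvaluate:
    def test_counting(self):
        series = simulate_cohort("stabilized", 1, 150, seed=0)[0]
        results = rolling_evaluate(series, EvalConfig(warmup=30))
        assert len(results) == 120
        assert [r.target_index for r in results] == list(range(30, 150))

    def test_no_leakage(self):
        series = simulate_cohort("stabilized", 1, 60, seed=8)[0]
        base = rolling_evaluate(series, EvalConfig(warmup=40))
        # perturb the final session heavily
        import dataclasses

        tampered = series.replace_sessions(
            list(series.sessions[:-1])
            + [dataclasses.replace(series.sessions[-1], post_weight=150.0,
                                   pre_weight=155.0)]
        )
        perturbed = rolling_evaluate(tampered, EvalConfig(warmup=40))
        for a, b in zip(base[:-1], perturbed[:-1]):
            assert a.post_pred == b.post_pred  # bit-identical

    def test_noise_free_exact_recovery(self):
        cfg = SimulationConfig(
            dw_drift=0.02, dw_rw_sd=0, gain_sd=0, saline_mean=0, saline_sd=0,
            post_noise_sd=0, n_sessions=60,
        )
        results = rolling_evaluate(simulate_patient(cfg), EvalConfig())
        assert all(r.abs_error < 1e-6 for r in results)

    def test_warmup_too_small_rejected(self):
        series = simulate_cohort("stabilized", 1, 60, seed=0)[0]
        with pytest.raises(DataError, match="warmup"):
            rolling_evaluate(series, EvalConfig(warmup=10))

    def test_handles_missing_weights(self):
        from hdweight.synthetic import inject_missing

        series = inject_missing(simulate_cohort("stabilized", 1, 80, seed=2)[0], 0.1, seed=3)
        results = rolling_evaluate(series, EvalConfig())
        assert len(results) >= 40
        scored = [r for r in results if r.post_actual is not None]
        assert all(np.isfinite(r.post_pred) for r in scored)


class TestKSweep:
    def test_single_k_matches_direct_run(self):
        from hdweight.evaluate import metric_quad

        series = simulate_cohort("stabilized", 2, 60, seed=5)
        table = k_sweep(series, [5], EvalConfig(warmup=40))
        quads = []
        for s in series:
            res = rolling_evaluate(s, EvalConfig(warmup=40))
            quads.append(metric_quad([r.post_actual for r in res], [r.post_pred for r in res]))
        assert table.loc[0, "mae"] == pytest.approx(np.mean([q.mae for q in quads]))
        assert table.loc[0, "r2"] == pytest.approx(np.mean([q.r2 for q in quads]))

    def test_emits_row_per_k(self):
        series = simulate_cohort("stabilized", 1, 60, seed=5)
        table = k_sweep(series, [2, 4, 6], EvalConfig(warmup=40))
        assert list(table["k"]) == [2, 4, 6]
        assert set(table.columns) == {"k", "mae", "mape", "mse", "r2"}


class TestModelStateSerialization:
    def test_round_trip_preserves_predictions(self):
        series = _noisy_patient(seed=11)
        state = fit(series)
        clone = ModelState.from_dict(state.to_dict())
        x = build_features(series, state.k, 30)
        assert predict_emd(clone, x) == predict_emd(state, x)

    def test_bad_coef_length_rejected(self):
        with pytest.raises(DataError):
            ModelState(
                k=1, n=2, tau=1.0, ema_mode="normalized", kernel_mode="sample_weight",
                norm_stats=NormStats(np.zeros(4), np.ones(4)),
                base_coefs=np.zeros(3),
                training_features=np.zeros((10, 4)), training_emd=np.zeros(10),
            )
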