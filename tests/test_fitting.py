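"""Profile fitting: packing, robust loss, objective, recovery, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as t_dist

import sweatpk as sp
from sweatpk.fitting import N_KINETIC_PARAMS, default_bounds


def small_table(seed=0, cv=0.0):
    rng = np.random.default_rng(seed)
    design = sp.DESIGNS["A"]
    truth = sp.sample_ground_truth(rng, design)
    table, _ = sp.generate_profile(truth, design,
                                   sp.NoiseModel(technical_cv=cv), seed=seed)
    return table, truth, design


class TestPacking:
    def test_roundtrip_is_identity(self):
        rng = np.random.default_rng(0)
        for T in (2, 7, 15, 20):
            lb, ub = default_bounds(T)
            x = rng.uniform(lb, ub)
            rates, initial, volumes = sp.unpack_parameters(x, T)
            assert np.allclose(
                sp.pack_parameters(rates, initial, volumes), x)

    def test_vector_length_is_eleven_plus_timepoints(self):
        lb, ub = default_bounds(15)
        assert lb.size == ub.size == 26

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(sp.InputError):
            sp.unpack_parameters(np.zeros(11), 0)
        with pytest.raises(sp.InputError):
            sp.unpack_parameters(np.zeros(20), 15)


class TestRobustLoss:
    def test_quadratic_limit(self):
        # alpha = 2: rho(x) = (x/c)^2 / 2
        assert sp.robust_loss(1.0, 2.0, 1.0) == pytest.approx(0.5)
        assert sp.robust_loss(3.0, 2.0, 1.5) == pytest.approx(2.0)

    def test_soft_l1_closed_form(self):
        # alpha = 1: rho(x) = sqrt((x/c)^2 + 1) - 1
        assert sp.robust_loss(1.0, 1.0, 1.0) == pytest.approx(
            np.sqrt(2) - 1, abs=1e-12)
        assert sp.robust_loss(0.0, 1.0, 1.0) == 0.0

    def test_invalid_scale_rejected(self):
        with pytest.raises(sp.DomainError):
            sp.robust_loss(1.0, 2.0, 0.0)

    @given(x=st.floats(-100, 100), alpha=st.sampled_from([2.0, 1.0, 0.5, 0.0]))
    @settings(deadline=None, derandomize=True)
    def test_even_zero_at_zero_and_monotone(self, x, alpha):
        c = 1.3
        rho = sp.robust_loss(x, alpha, c)
        assert rho >= 0
        assert sp.robust_loss(-x, alpha, c) == rho
        assert sp.robust_loss(0.0, alpha, c) == 0.0
        assert sp.robust_loss(1.1 * abs(x), alpha, c) >= rho

    def test_limits_continuous_in_alpha(self):
        for x in (0.3, 1.7, 4.0):
            for a0 in (2.0, 0.0):
                near = sp.robust_loss(x, a0 + 1e-7, 1.0) \
                    if a0 == 0 else sp.robust_loss(x, a0 - 1e-7, 1.0)
                assert near == pytest.approx(
                    sp.robust_loss(x, a0, 1.0), rel=1e-4)


class TestObjective:
    def test_zero_at_generating_parameters(self):
        table, truth, _ = small_table()
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        loss, _ = sp.objective(x, table, sp.PKConstants())
        assert loss <= 1e-12

    def test_perturbing_volume_increases_loss(self):
        table, truth, _ = small_table()
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        for j in range(truth.volumes.volumes.size):
            x2 = x.copy()
            x2[N_KINETIC_PARAMS + j] *= 1.05
            loss, _ = sp.objective(x2, table, sp.PKConstants())
            assert loss > 1e-12  # strictly above the zero at truth

    def test_duplicated_rows_double_quadratic_loss(self):
        table, truth, _ = small_table(cv=0.1)
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        loss1, _ = sp.objective(x, table, sp.PKConstants(), alpha=2.0,
                                scale=1.0)
        doubled = sp.MeasurementTable(
            pd.concat([table.data, table.data], ignore_index=True))
        loss2, _ = sp.objective(x, doubled, sp.PKConstants(), alpha=2.0,
                                scale=1.0)
        assert loss2 == pytest.approx(2 * loss1, rel=1e-12)

    def test_fully_censored_table_rejected(self):
        table, truth, _ = small_table()
        df = table.data.copy()
        df["censored"] = True
        bad = sp.MeasurementTable(df)
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        with pytest.raises(sp.InputError, match="no usable"):
            sp.objective(x, bad, sp.PKConstants())

    def test_censored_rows_do_not_affect_retained_residuals(self):
        table, truth, _ = small_table(cv=0.1)
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        _, r_all = sp.objective(x, table, sp.PKConstants())
        df = table.data.copy()
        drop = df.index[5]
        df.loc[drop, "censored"] = True
        _, r_cens = sp.objective(x, sp.MeasurementTable(df),
                                 sp.PKConstants())
        keep = np.delete(r_all, 5)
        assert np.array_equal(r_cens, keep)


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        y = np.arange(10.0)
        assert sp.adjusted_r2(y, y, 3) == 1.0

    def test_mean_prediction_formula(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=120)
        fitted = np.full(120, y.mean())
        expected = 1.0 - 119 / 93  # R^2 = 0, n=120, p=26
        assert sp.adjusted_r2(y, fitted, 26) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_known_r2_penalty(self):
        # engineered sample with R^2 exactly 0.95
        n = 120
        y = np.zeros(n)
        y[0], y[1] = 1.0, -1.0  # ss_tot = 2
        fitted = y.copy()
        fitted[2] += np.sqrt(0.1)  # ss_res = 0.1 -> R^2 = 0.95
        got = sp.adjusted_r2(y, fitted, 26)
        assert got == pytest.approx(1 - 0.05 * 119 / 93, abs=1e-10)

    def test_insufficient_df_rejected(self):
        with pytest.raises(sp.InputError):
            sp.adjusted_r2(np.ones(5), np.ones(5), 4)


class TestFitProfile:
    def test_noise_free_fit_reaches_zero_loss(self, noise_free_fit):
        result, truth, table = noise_free_fit
        assert result.loss < 1e-12
        assert result.adjusted_r2 > 1 - 1e-10

    def test_identifiable_constants_recovered(self, noise_free_fit):
        # k2-k4 and rate differences are invariant under the model's
        # volume-exponential gauge and must come back to the truth
        result, truth, table = noise_free_fit
        inv_t = sp.gauge_invariants(truth.rates)
        inv_f = sp.gauge_invariants(result.rates)
        for name in ("k2", "k3", "k4"):
            assert inv_f[name] == pytest.approx(inv_t[name], rel=0.01)
        for name in ("k6_minus_k5", "k7_minus_k5", "k8_minus_k5",
                     "k1_minus_kappa"):
            scale = max(abs(inv_t[name]), 0.01)
            assert abs(inv_f[name] - inv_t[name]) / scale < 0.02

    def test_predicted_signals_recovered(self, noise_free_fit):
        result, truth, table = noise_free_fit
        t = table.times
        traj = sp.simulate(result.rates, sp.PKConstants(), result.initial, t)
        sig_fit = sp.predicted_signal(traj, result.volumes)
        traj_t = sp.simulate(truth.rates, sp.PKConstants(), truth.initial, t)
        sig_true = sp.predicted_signal(traj_t, truth.volumes)
        denom = np.maximum(sig_true, sig_true.max() * 1e-9)
        assert np.max(np.abs(sig_fit - sig_true) / denom) < 1e-4

    def test_estimates_respect_bounds(self, noise_free_fit):
        result, _, table = noise_free_fit
        lb, ub = default_bounds(table.n_timepoints)
        assert np.all(result.x >= lb) and np.all(result.x <= ub)

    def test_same_seed_is_bit_identical(self):
        table, _, _ = small_table(cv=0.1)
        config = sp.FitConfig(n_starts=4, rng_seed=5, alphas=(2.0,))
        r1 = sp.fit_profile(table, sp.PKConstants(), config)
        r2 = sp.fit_profile(table, sp.PKConstants(), config)
        assert np.array_equal(r1.x, r2.x)
        assert r1.loss == r2.loss

    def test_loss_non_increasing_in_n_starts(self):
        # seed substreams are a prefix sequence: more starts never worse
        table, _, _ = small_table(cv=0.1)
        losses = []
        for n in (2, 4, 8):
            config = sp.FitConfig(n_starts=n, rng_seed=9, alphas=(2.0,))
            losses.append(sp.fit_profile(table, sp.PKConstants(),
                                         config).loss)
        assert losses[0] >= losses[1] >= losses[2]


class TestGauge:
    def test_gauge_family_leaves_objective_flat(self):
        table, truth, design = small_table()
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        base, _ = sp.objective(x, table, sp.PKConstants())
        scale = np.median(table.data["signal"])
        for delta in (-0.004, 0.004, 0.01):
            x2 = sp.gauge_transform(x, table.times, delta)
            loss, r = sp.objective(x2, table, sp.PKConstants())
            assert np.max(np.abs(r)) < 1e-8 * scale

    def test_constant_volume_rescaling_changes_objective(self):
        # the spec'd identifiability probe: a *constant* rescaling of
        # (C, V) cannot be absorbed, unlike the exponential gauge
        table, truth, _ = small_table()
        x = sp.pack_parameters(truth.rates, truth.initial, truth.volumes)
        x2 = x.copy()
        x2[N_KINETIC_PARAMS:] *= 1.5
        loss, _ = sp.objective(x2, table, sp.PKConstants())
        assert loss > 1e-3


class TestConfidenceIntervals:
    def _result(self):
        table, _, _ = small_table(cv=0.1)
        config = sp.FitConfig(n_starts=2, rng_seed=1, alphas=(2.0,))
        return sp.fit_profile(table, sp.PKConstants(), config)

    def test_zero_cv_gives_point_interval(self):
        result = self._result()
        cvs = {n: 0.0 for n in result.parameter_names()}
        ci = sp.confidence_intervals(result, cvs)
        for name, est in zip(result.parameter_names(), result.x):
            assert ci[name] == (est, est)

    def test_half_width_matches_t_quantile(self):
        result = self._result()
        cvs = {n: 0.1 for n in result.parameter_names()}
        ci = sp.confidence_intervals(result, cvs, df=93)
        q = t_dist.ppf(0.975, 93)
        assert q * 0.1 == pytest.approx(0.1986, abs=5e-4)
        for name, est in zip(result.parameter_names(), result.x):
            lo, hi = ci[name]
            assert (hi - lo) / 2 == pytest.approx(q * 0.1 * abs(est),
                                                  rel=1e-12)

    def test_width_scales_linearly_with_estimate(self):
        result = self._result()
        cvs = {n: 0.2 for n in result.parameter_names()}
        ci = sp.confidence_intervals(result, cvs)
        names = result.parameter_names()
        widths = {n: ci[n][1] - ci[n][0] for n in names}
        for name, est in zip(names, result.x):
            if est > 0:
                assert widths[name] / est == pytest.approx(
                    widths[names[0]] / result.x[0]
                    if result.x[0] > 0 else widths[name] / est, rel=1e-9)

    def test_missing_cv_rejected(self):
        result = self._result()
        with pytest.raises(sp.InputError, match="missing CV"):
            sp.confidence_intervals(result, {"k1": 0.1})
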