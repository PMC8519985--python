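"""F2TC impulse response, forward model, derived quantities and estimator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import linregress

from oracles import ode_f2tc_forward, ode_f2tc_irf

from dilkit.core import ConvolutionGrid, FrameSchedule, TimeActivityCurve
from dilkit.pet import (F2TCParams, FitOptions, dv_of, f2tc_forward, f2tc_irf,
                        fit_f2tc, ki_of, suv, suv_early)
from conftest import random_f2tc_params


class TestIRF:
    def test_zero_before_delay(self, dil_f2tc):
        import dataclasses
        p = dataclasses.replace(dil_f2tc, t0=5.0)
        assert np.all(f2tc_irf(p, np.array([0.0, 2.0, 4.99])) == 0.0)

    def test_flow_plateau_then_k1_at_window_end(self, dil_f2tc):
        p = dil_f2tc
        assert f2tc_irf(p, p.t0 + p.W / 2) == pytest.approx(p.F)
        assert f2tc_irf(p, p.t0 + p.W) == pytest.approx(p.K1)

    def test_k3_zero_reduces_to_single_exponential(self):
        p = F2TCParams(F=1.0, W=6.0, K1=0.3, k2=0.4, k3=0.0, k4=0.2)
        tp = np.array([30.0, 120.0, 600.0])  # seconds past the window
        expect = p.K1 * np.exp(-p.k2 * tp / 60.0)
        np.testing.assert_allclose(f2tc_irf(p, p.W + tp), expect, rtol=1e-12)

    def test_repeated_root_handled_by_analytic_limit(self):
        # k2 = k4, k3 = 0 makes the eigenvalues coincide
        p = F2TCParams(F=1.0, W=0.0, K1=0.3, k2=0.2, k3=0.0, k4=0.2)
        vals = f2tc_irf(p, np.array([0.0, 60.0, 300.0]))
        expect = p.K1 * np.exp(-p.k2 * np.array([0.0, 1.0, 5.0]))
        np.testing.assert_allclose(vals, expect, rtol=1e-6)

    def test_bounded_by_flow_and_nonnegative(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 1400.0, 500)
        for _ in range(50):
            p = random_f2tc_params(rng)
            h = f2tc_irf(p, t)
            assert np.all(h >= 0.0)
            assert np.all(h <= p.F * (1 + 1e-12))

    def test_matches_compartment_ode_at_dil_reference(self, dil_f2tc):
        """Analytic eigen-expansion vs stiff ODE integration, 1 min past window."""
        ours = f2tc_irf(dil_f2tc, dil_f2tc.t0 + dil_f2tc.W + 60.0)
        ref = ode_f2tc_irf(dil_f2tc, 60.0)[0]
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_matches_compartment_ode_for_random_draws(self):
        rng = np.random.default_rng(7)
        tq = np.array([10.0, 60.0, 300.0, 1200.0])
        for _ in range(25):
            p = random_f2tc_params(rng)
            ref = ode_f2tc_irf(p, tq)
            ours = f2tc_irf(p, p.t0 + p.W + tq)
            assert np.max(np.abs(ours - ref)) < 1e-6 * max(p.K1, 1e-12)


class TestForward:
    def test_zero_aif_gives_zero_tac(self, dil_f2tc, pet_schedule):
        tac = f2tc_forward(dil_f2tc, lambda t: np.zeros_like(t), pet_schedule)
        assert np.all(tac.values == 0.0)

    def test_unit_impulse_aif_returns_frame_averaged_irf(self, dil_f2tc,
                                                         pet_schedule):
        # triangular spike whose piecewise-linear interpolant carries unit
        # area in *minutes* at t = 0
        dt = 0.5

        def impulse(t):
            v = np.zeros_like(t)
            v[np.asarray(t) < dt / 2] = 2.0 * 60.0 / dt
            return v

        tac = f2tc_forward(dil_f2tc, impulse, pet_schedule, dt=dt)
        grid = ConvolutionGrid(pet_schedule, impulse, dt=dt)
        expect = grid.frame_average(f2tc_irf(dil_f2tc, grid.t))
        # first frame straddles the impulse support; compare the rest
        np.testing.assert_allclose(tac.values[1:], expect[1:], rtol=5e-3)

    def test_linear_in_the_aif(self, dil_f2tc, pet_schedule, pet_aif):
        a = f2tc_forward(dil_f2tc, pet_aif, pet_schedule).values
        b = f2tc_forward(dil_f2tc, lambda t: 3.0 * pet_aif(t), pet_schedule).values
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)

    def test_matches_refined_grid_trapezoid_convolution(self, dil_f2tc,
                                                        pet_schedule, pet_aif,
                                                        pet_grid):
        """Brute-force trapezoid convolution at 25x resolution (jump node
        of the residue function averaged between its one-sided limits)."""
        p = dil_f2tc
        ours = pet_grid.frame_average(
            __import__("dilkit.pet", fromlist=["x"])._f2tc_forward_grid(p, pet_grid))
        dtf = 0.02
        tf = np.arange(0, pet_schedule.span_end + dtf / 2, dtf)
        a = pet_aif(tf)
        h = f2tc_irf(p, tf) / 60.0
        i = int(round((p.t0 + p.W) / dtf))
        h[i] = 0.5 * (p.F + p.K1) / 60.0
        conv = np.convolve(a, h)[: tf.size] * dtf
        conv -= 0.5 * dtf * (a[0] * h + h[0] * a)
        ref = []
        for s, e in zip(pet_schedule.start, pet_schedule.end):
            m = (tf >= s - 1e-9) & (tf <= e + 1e-9)
            ref.append(np.trapezoid(conv[m], tf[m]) / (e - s))
        ref = np.array(ref)
        assert np.max(np.abs(ours - ref)) < 1e-4 * np.max(np.abs(ref))

    def test_matches_driven_ode_oracle(self, dil_f2tc, pet_schedule, pet_aif):
        ours = f2tc_forward(dil_f2tc, pet_aif, pet_schedule).values
        ref = ode_f2tc_forward(dil_f2tc, pet_aif, pet_schedule)
        assert np.max(np.abs(ours - ref)) < 1e-4 * np.max(np.abs(ref))

    def test_schedule_beyond_aif_support_rejected(self, dil_f2tc, pet_schedule):
        short_aif = TimeActivityCurve(times=np.arange(0.0, 600.0),
                                      values=np.ones(600))
        with pytest.raises(ValueError):
            f2tc_forward(dil_f2tc, short_aif, pet_schedule)


class TestDerivedQuantities:
    def test_ki_identity_and_reported_medians(self, dil_f2tc, nondil_f2tc):
        assert ki_of(dil_f2tc) == pytest.approx(0.055, rel=1e-9)
        assert ki_of(nondil_f2tc) == pytest.approx(0.036, rel=1e-9)

    def test_ki_zero_iff_k3_zero(self):
        p = F2TCParams(F=1.0, W=5.0, K1=0.3, k2=0.4, k3=0.0, k4=0.1)
        assert ki_of(p) == 0.0
        with pytest.raises(ValueError):
            ki_of(F2TCParams(F=1.0, W=5.0, K1=0.3, k2=0.0, k3=0.0, k4=0.1))

    def test_ki_equals_patlak_slope_of_irreversible_system(self, pet_aif):
        """Patlak regression on a k4 = 0 forward simulation recovers Ki."""
        import dataclasses
        rng = np.random.default_rng(3)
        p = dataclasses.replace(random_f2tc_params(rng), k4=0.0, t0=0.0, W=0.0)
        sched = FrameSchedule.from_durations([60.0] * 60)  # 1 h, 1-min frames
        tac = f2tc_forward(p, pet_aif, sched).values
        t = sched.mid
        ca = pet_aif(t)
        ca_int = np.array([quad(lambda u: float(pet_aif(u)), 0, tt,
                                limit=200)[0] for tt in t])
        x = ca_int / ca / 60.0  # normalised time, minutes
        y = tac / ca
        late = t > 2400.0
        slope = linregress(x[late], y[late]).slope
        assert slope == pytest.approx(ki_of(p), rel=0.01)

    def test_dv_identity_and_reported_medians(self, dil_f2tc, nondil_f2tc):
        assert dv_of(dil_f2tc) == pytest.approx(2.29, rel=1e-9)
        assert dv_of(nondil_f2tc) == pytest.approx(1.17, rel=1e-9)

    def test_dv_reduces_to_k1_over_k2_without_binding(self):
        p = F2TCParams(F=1.0, W=5.0, K1=0.3, k2=0.4, k3=0.0, k4=0.1)
        assert dv_of(p) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            dv_of(F2TCParams(F=1.0, W=5.0, K1=0.3, k2=0.4, k3=0.1, k4=0.0))

    def test_dv_equals_integral_of_tissue_response(self):
        """DV equals the total area under the post-window impulse response."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = random_f2tc_params(rng)
            if p.k2 < 0.05 or p.k4 < 0.05:
                continue
            area, _ = quad(lambda tp: float(f2tc_irf(p, p.t0 + p.W + tp)) / 60.0,
                           0.0, np.inf, limit=400)
            assert area == pytest.approx(dv_of(p), rel=5e-3)

    def test_invariant_ki_never_exceeds_k1(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = random_f2tc_params(rng)
            if p.k2 + p.k3 > 0:
                assert ki_of(p) <= p.K1 + 1e-15


class TestSUV:
    def test_unit_ratio(self):
        assert suv(325.0 / 88800.0, 325.0, 88.8) == pytest.approx(1.0)
        assert suv(0.0, 325.0, 88.8) == 0.0

    def test_cohort_dosimetry_arithmetic(self):
        # 0.00915 MBq/mL at 325 MBq into 88.8 kg:
        # 0.00915 * 88800 / 325 = 2.50006... g/mL
        assert suv(0.00915, 325.0, 88.8) == pytest.approx(2.50006, abs=1e-4)

    def test_zero_dose_or_weight_rejected(self):
        with pytest.raises(ValueError):
            suv(1.0, 0.0, 88.8)
        with pytest.raises(ValueError):
            suv(1.0, 325.0, 0.0)

    def test_early_suv_means_last_four_frames(self, pet_schedule):
        vals = np.zeros(28)
        vals[-4:] = [2.0, 4.0, 6.0, 8.0]
        tac = TimeActivityCurve(pet_schedule.mid, vals)
        assert suv_early(tac, pet_schedule, 325.0, 88.8) == pytest.approx(
            suv(5.0, 325.0, 88.8))

    def test_early_frames_start_at_ten_minutes(self, pet_schedule):
        assert np.all(pet_schedule.start[-4:] >= 600.0)
        assert pet_schedule.start[-5] < 600.0

    def test_constant_tac(self, pet_schedule):
        tac = TimeActivityCurve(pet_schedule.mid, np.full(28, 0.003))
        assert suv_early(tac, pet_schedule, 325.0, 88.8) == pytest.approx(
            suv(0.003, 325.0, 88.8))

    def test_too_few_frames_rejected(self):
        sched = FrameSchedule.from_durations([10.0] * 3)
        tac = TimeActivityCurve(sched.mid, np.ones(3))
        with pytest.raises(ValueError):
            suv_early(tac, sched, 325.0, 88.8)


class TestFit:
    def test_all_zero_tac_flagged_degenerate(self, pet_schedule, pet_aif):
        tac = TimeActivityCurve(pet_schedule.mid, np.zeros(28))
        res = fit_f2tc(tac, pet_aif, pet_schedule)
        assert res.degenerate and not res.converged
        assert res.params.K1 == 0.0

    def test_too_few_frames_rejected(self, pet_aif):
        sched = FrameSchedule.from_durations([10.0] * 5)
        tac = TimeActivityCurve(sched.mid, np.ones(5))
        with pytest.raises(ValueError):
            fit_f2tc(tac, pet_aif, sched)

    def test_fit_respects_extraction_bound_and_derived_consistency(
            self, pet_schedule, pet_aif, pet_grid, nondil_f2tc):
        """Ki <= K1 <= F on noisy fits; reported ki/dv equal the identities
        applied to the fitted vector."""
        from dilkit.pet import _f2tc_forward_grid
        from dilkit.synthetic import _frame_noise
        y0 = pet_grid.frame_average(_f2tc_forward_grid(nondil_f2tc, pet_grid))
        rng = np.random.default_rng(17)
        for r in range(5):
            y = _frame_noise(y0, pet_schedule.duration, 0.1, rng)
            res = fit_f2tc(TimeActivityCurve(pet_schedule.mid, y), pet_aif,
                           pet_schedule, FitOptions(n_starts=1, seed=r),
                           grid=pet_grid)
            p = res.params
            assert p.K1 <= p.F * (1 + 1e-9)
            if res.ki is not None:
                assert res.ki <= p.K1 + 1e-12
                assert res.ki == pytest.approx(ki_of(p), abs=1e-15)
            if res.dv is not None:
                assert res.dv == pytest.approx(dv_of(p), abs=1e-12)

    def test_noiseless_nondil_recovery_within_two_percent(
            self, pet_schedule, pet_aif, pet_grid, nondil_f2tc):
        tac = f2tc_forward(nondil_f2tc, pet_aif, pet_schedule, grid=pet_grid)
        res = fit_f2tc(tac, pet_aif, pet_schedule, FitOptions(n_starts=5, seed=0),
                       grid=pet_grid)
        assert res.converged
        assert res.params.K1 == pytest.approx(0.187, rel=0.02)
        assert res.params.k4 == pytest.approx(0.130, rel=0.02)

    def test_low_noise_median_bias_small_for_k1_and_ki(
            self, pet_schedule, pet_aif, pet_grid, dil_f2tc):
        """Median K1/Ki bias stays below 10% in the calibrated noise regime."""
        from dilkit.pet import _f2tc_forward_grid
        from dilkit.synthetic import _frame_noise
        y0 = pet_grid.frame_average(_f2tc_forward_grid(dil_f2tc, pet_grid))
        rng = np.random.default_rng(21)
        k1s, kis = [], []
        for r in range(30):
            y = _frame_noise(y0, pet_schedule.duration, 0.02, rng)
            res = fit_f2tc(TimeActivityCurve(pet_schedule.mid, y), pet_aif,
                           pet_schedule, FitOptions(n_starts=1, seed=r),
                           grid=pet_grid)
            k1s.append(res.params.K1)
            kis.append(res.ki)
        assert abs(np.median(k1s) / dil_f2tc.K1 - 1.0) < 0.10
        assert abs(np.median(kis) / 0.055 - 1.0) < 0.10
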