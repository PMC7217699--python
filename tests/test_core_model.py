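"""Feedback-loop model: logistic limbs, sampler, kernel, stepping, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micturition import ModelParams, MicturitionModel, Perturbation, simulate, summarize_cycles
from micturition.core import (
    ModelState,
    Phase,
    afferent_drive_max,
    contraction_amplitude,
    nvc_kernel,
    sample_firing,
    step,
)

from oracles import deterministic_recurrence


@pytest.fixture
def params():
    return ModelParams()


class TestAfferentDrive:
    @pytest.mark.parametrize(
        "p, expected, tol",
        [
            (4.5, 14.65, 1e-12),  # logistic midpoint = (fmin + fmax) / 2
            (0.0, 4.3, 1e-6),  # far-left asymptote
            (10.0, 25.0, 1e-6),  # far-right asymptote
        ],
    )
    def test_reference_points(self, params, p, expected, tol):
        assert afferent_drive_max(p, params) == pytest.approx(expected, abs=tol)

    def test_monotone_and_bounded(self, params):
        grid = np.linspace(0, 10, 400)  # beyond ~12 mmHg the curve saturates in float64
        v = afferent_drive_max(grid, params)
        assert np.all(np.diff(v) > 0)
        wide = afferent_drive_max(np.linspace(0, 30, 400), params)
        assert np.all((wide > params.fmin) & (wide <= params.fmax))

    def test_negative_pressure_rejected(self, params):
        with pytest.raises(ValueError):
            afferent_drive_max(-0.1, params)


class TestSampleFiring:
    def test_uniform_moments(self):
        rng = np.random.default_rng(0)
        draws = np.array([sample_firing(10.0, 1.0, rng) for _ in range(100_000)])
        assert draws.min() >= 0 and draws.max() <= 10
        assert np.mean(draws) == pytest.approx(5.0, abs=0.1)

    def test_variance_scaling_preserves_mean_and_shrinks_range(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_firing(10.0, 0.2, rng) for _ in range(20_000)])
        lo, hi = 5 - 5 * math.sqrt(0.2), 5 + 5 * math.sqrt(0.2)
        assert draws.min() >= lo - 1e-12 and draws.max() <= hi + 1e-12
        assert np.mean(draws) == pytest.approx(5.0, abs=0.1)

    def test_zero_ceiling(self):
        assert sample_firing(0.0, 1.0, np.random.default_rng(0)) == 0.0

    def test_invalid_variance_scale(self):
        with pytest.raises(ValueError):
            sample_firing(1.0, 1.5, np.random.default_rng(0))

    @settings(max_examples=50, derandomize=True)
    @given(smax=st.floats(0, 50), vs=st.floats(0, 1), seed=st.integers(0, 2**16))
    def test_bounds_property(self, smax, vs, seed):
        s = sample_firing(smax, vs, np.random.default_rng(seed))
        assert 0 <= s <= max(smax, 1e-12)


class TestContractionAmplitude:
    def test_midpoint_at_decade_pressure(self, params):
        # at s = mp the logistic is 1/2; ceiling at p = 10 is exactly 6 mmHg
        assert contraction_amplitude(params.mp, 10.0, params) == pytest.approx(3.0, abs=1e-12)

    def test_saturated_gate(self, params):
        # s = 20 Hz: gate = 1/(1+e^-7); ceiling 6 mmHg at p = 10
        expected = 6.0 / (1.0 + math.exp(-7.0))
        assert contraction_amplitude(20.0, 10.0, params) == pytest.approx(expected, abs=1e-9)

    def test_floor_below_unit_pressure(self, params):
        for s in (0.0, 6.0, 25.0):
            assert contraction_amplitude(s, 0.5, params) == 0.0

    def test_monotone_gate(self, params):
        s_grid = np.linspace(0, 25, 60)
        p_grid = np.linspace(1.0, 15.0, 60)
        for p in (1.0, 5.0, 15.0):
            vals = [contraction_amplitude(s, p, params) for s in s_grid]
            assert np.all(np.diff(vals) >= 0)
        for s in (2.0, 6.0, 20.0):
            vals = [contraction_amplitude(s, p, params) for p in p_grid]
            assert np.all(np.diff(vals) >= 0)


class TestNvcKernel:
    def test_zero_amplitude(self, params):
        assert np.all(nvc_kernel(0.0, params) == 0)
        assert len(nvc_kernel(0.0, params)) == params.bump_duration

    def test_peak_at_offset_for_integral_offset(self, params):
        p3 = params.replace(bump_peak_offset=3.0)
        k = nvc_kernel(2.0, p3)
        assert k.max() == pytest.approx(2.0)
        assert int(np.argmax(k)) == 2  # third sample = 3 s after the trigger

    def test_symmetry_about_centre(self, params):
        # default peak offset sits at the centre of the 6-sample support
        k = nvc_kernel(1.0, params)
        assert np.allclose(k, k[::-1])
        assert np.all(k >= 0)

    def test_half_rise_precedes_peak_within_burst_window(self, params):
        # the detectable (half-rise) onset follows the triggering firing
        # sample by 1.5-3 s, matching the in-vivo burst-to-NVC precedence
        half_rise = params.bump_peak_offset - math.sqrt(2 * params.bump_variance * math.log(2))
        assert 1.5 <= half_rise <= 3.0


class TestStep:
    def test_void_triggers_at_threshold(self, params):
        state = ModelState(p=14.99, base=14.99, phase=Phase.FILLING)
        step(state, params, rng=np.random.default_rng(0))
        assert state.phase is Phase.EMPTYING
        assert state.void_triggered
        assert state.p >= params.void_threshold

    def test_emptying_rate_and_reset(self, params):
        state = ModelState(p=15.0, base=15.0, phase=Phase.EMPTYING)
        step(state, params, rng=np.random.default_rng(0))
        assert state.p == pytest.approx(13.0)
        for _ in range(7):
            step(state, params, rng=np.random.default_rng(0))
        assert state.p < params.basal_reset
        assert state.phase is Phase.FILLING

    def test_zero_variance_is_deterministic(self, params):
        det = params.replace(variance_scale=0.0)
        a = simulate(det, n_steps=400, seed=1)
        b = simulate(det, n_steps=400, seed=999)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.s, b.s)


class TestSimulate:
    def test_three_voids_at_threshold(self, params):
        tr = simulate(params, n_voids=3, seed=11)
        assert tr.n_voids == 3
        assert np.all(tr.p[tr.void_times] >= params.void_threshold)

    def test_bit_identical_reruns(self, params):
        a = simulate(params, n_voids=2, seed=5)
        b = simulate(params, n_voids=2, seed=5)
        for x, y in [(a.p, b.p), (a.s, b.s), (a.smax, b.smax), (a.dP, b.dP)]:
            assert np.array_equal(x, y)

    def test_zero_length_request_rejected(self, params):
        with pytest.raises(ValueError):
            simulate(params, n_voids=0)
        with pytest.raises(ValueError):
            simulate(params)

    def test_firing_bounds_long_run(self, params):
        tr = simulate(params, n_steps=5000, seed=3)
        assert tr.s.max() <= params.fmax
        assert tr.s.min() >= 0

    def test_matches_independent_recurrence(self, params):
        det = params.replace(variance_scale=0.0)
        tr = simulate(det, n_steps=1500, seed=0)
        ps, ss, voids = deterministic_recurrence(det, 1500)
        assert np.max(np.abs(tr.p - ps)) < 1e-9
        assert np.max(np.abs(tr.s - ss)) < 1e-9
        assert list(tr.void_times) == voids


class TestPerturbations:
    def test_variance_attenuation_delays_first_void(self, params):
        model = MicturitionModel(params)
        ctrl, att = [], []
        for seed in range(20):
            ctrl.append(model.simulate(n_voids=1, seed=seed).void_times[0])
            att.append(
                model.simulate(
                    n_voids=1, seed=seed,
                    perturbations=[Perturbation("variance_attenuation", reduction=0.8)],
                ).void_times[0]
            )
        assert np.median(att) > np.median(ctrl)

    def test_opto_window_clamps_rate(self, params):
        tr = simulate(
            params, n_steps=50, seed=0,
            perturbations=[Perturbation("opto_pulse", start=10, stop=15, rate=20.0)],
        )
        assert np.allclose(tr.s[9:14], 20.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Perturbation("tickle")


class TestSummarizeCycles:
    def test_intervals_and_counts(self, params):
        tr = simulate(params, n_voids=3, seed=4)
        s = summarize_cycles(tr)
        assert len(s) == 3
        void_times_s = (tr.void_times + 1) * params.dt
        expect = np.diff(np.r_[0.0, void_times_s])
        assert np.allclose(s["interval_s"], expect)
        assert np.all(s["peak_pressure_mmHg"] >= params.void_threshold)

    def test_no_voids_warns_and_returns_empty(self, params):
        tr = simulate(params, n_steps=30, seed=0)
        with pytest.warns(UserWarning):
            s = summarize_cycles(tr)
        assert len(s) == 0

    def test_nvc_amplitude_grows_across_cycle(self, params):
        tr = simulate(params, n_voids=20, seed=5)
        s = summarize_cycles(tr)
        q5 = np.nanmean(s["nvc_amp_q5"])
        q2 = np.nanmean(s["nvc_amp_q2"]) if np.isfinite(s["nvc_amp_q2"]).any() else 0.0
        assert q5 > q2

    def test_zero_variance_trace_has_no_detectable_nvcs(self, params):
        tr = simulate(params.replace(variance_scale=0.0), n_voids=5, seed=1)
        s = summarize_cycles(tr)
        assert s["n_nvcs"].sum() == 0
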