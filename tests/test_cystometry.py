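"""Pressure/EMG analysis: detection, cycle metrics, evoked events, bursts."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from micturition.cystometry import (
    EMGTrace,
    PressureTrace,
    VoidEvent,
    characterize_evoked_event,
    cycle_metrics,
    detect_nvcs,
    detect_voids,
    eus_burst_metrics,
    nvc_triggered_spikes,
    process_emg,
)

from oracles import brute_force_nvcs


def gaussian_bump(t, centre, amplitude, sd=1.0):
    return amplitude * np.exp(-((t - centre) ** 2) / (2 * sd**2))


class TestDetectVoids:
    def test_subthreshold_ramp_yields_nothing(self):
        pt = PressureTrace(rate=10.0, samples=np.linspace(0, 10, 1000))
        assert detect_voids(pt, min_peak=12.0) == []

    def test_close_peaks_resolve_to_the_larger(self):
        t = np.arange(0, 60, 0.1)
        x = gaussian_bump(t, 20, 16.0, 2) + gaussian_bump(t, 30, 15.5, 2)
        pt = PressureTrace(rate=10.0, samples=x)
        ev = detect_voids(pt, min_peak=10.0, min_separation=30.0)
        assert len(ev) == 1
        assert ev[0].peak_time == pytest.approx(20.0, abs=0.2)

    def test_recovers_truth_voids(self, noiseless_recording):
        rec = noiseless_recording
        ev = detect_voids(rec.pressure)
        truth = rec.truth["void_times"]
        assert len(ev) == len(truth)
        for e, t in zip(ev, truth):
            assert abs(e.peak_time - t) <= 1.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_voids(PressureTrace(rate=10.0, samples=np.empty(0)))


class TestCycleMetrics:
    def _toy(self):
        # one full cycle: void at t=10, basal dip to 1, ramp to the next
        # void at t=110 with an EMG burst onset at t=100 where p = 5
        rate = 10.0
        t = np.arange(0, 120, 1 / rate)
        x = np.full_like(t, 1.0)
        x += gaussian_bump(t, 10, 15.0, 1.0)
        ramp = (t > 20) & (t <= 100)
        x[ramp] += (t[ramp] - 20) * (4.0 / 80.0)
        x[t > 100] += 4.0 + gaussian_bump(t[t > 100], 110, 11.0, 1.0)
        return PressureTrace(rate=rate, samples=x)

    def test_printed_compliance_formula(self):
        pt = self._toy()
        voids = [VoidEvent(10.0, 16.0), VoidEvent(110.0, 16.0)]
        out = cycle_metrics(pt, voids, emg_burst_onsets=[100.0], infusion_rate_ul_per_s=80 / 90)
        ev = out[0]
        assert ev.basal_pressure == pytest.approx(1.0, abs=0.05)
        assert ev.threshold_pressure == pytest.approx(5.0, abs=0.1)
        assert ev.capacity_ul == pytest.approx(80.0, abs=1.0)
        # compliance = capacity / (threshold - basal) = 80 / 4
        assert ev.compliance_ul_per_mmHg == pytest.approx(20.0, rel=0.05)

    def test_degenerate_threshold_flagged(self):
        pt = self._toy()
        voids = [VoidEvent(10.0, 16.0), VoidEvent(110.0, 16.0)]
        # burst onset at t=20 where pressure equals the basal minimum exactly
        out = cycle_metrics(pt, voids, emg_burst_onsets=[20.0], infusion_rate_ul_per_s=1.0)
        assert np.isnan(out[0].compliance_ul_per_mmHg)

    def test_missing_emg_leaves_threshold_unset(self):
        pt = self._toy()
        voids = [VoidEvent(10.0, 16.0), VoidEvent(110.0, 16.0)]
        out = cycle_metrics(pt, voids)
        assert out[0].threshold_pressure is None
        assert out[0].compliance_ul_per_mmHg is None

    def test_requires_a_complete_cycle(self):
        with pytest.raises(ValueError):
            cycle_metrics(self._toy(), [VoidEvent(10.0, 16.0)])


class TestDetectNvcs:
    def test_flat_trace_empty(self):
        pt = PressureTrace(rate=10.0, samples=np.full(2000, 3.0))
        assert detect_nvcs(pt) == []

    def test_amplitude_filters(self):
        t = np.arange(0, 120, 0.1)
        x = gaussian_bump(t, 20, 0.05) + gaussian_bump(t, 50, 0.5) + gaussian_bump(t, 90, 5.0)
        ev = detect_nvcs(PressureTrace(rate=10.0, samples=x))
        assert len(ev) == 1
        assert ev[0].peak_time == pytest.approx(50.0, abs=0.2)
        assert ev[0].amplitude == pytest.approx(0.5, abs=0.05)

    def test_separation_keeps_larger_then_earlier(self):
        t = np.arange(0, 60, 0.1)
        x = gaussian_bump(t, 30, 0.5) + gaussian_bump(t, 33, 0.5)
        ev = detect_nvcs(PressureTrace(rate=10.0, samples=x))
        assert len(ev) == 1
        assert ev[0].peak_time <= 31.0  # equal heights resolve to the earlier

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = gaussian_filter1d(rng.normal(0, 1, 3000), 12)
        a = detect_nvcs(PressureTrace(rate=10.0, samples=x))
        b = detect_nvcs(PressureTrace(rate=10.0, samples=x + 7.0))
        assert [(e.peak_time, round(e.amplitude, 9)) for e in a] == [
            (e.peak_time, round(e.amplitude, 9)) for e in b
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = gaussian_filter1d(rng.normal(0, 1.0, 6000), 12) * 1.2 + 0.002 * np.arange(6000)
        ev = detect_nvcs(PressureTrace(rate=10.0, samples=x))
        oracle = brute_force_nvcs(x, 10.0)
        assert [round(e.peak_time * 10) for e in ev] == [i for i, _, _ in oracle]
        for e, (_, prom, w) in zip(ev, oracle):
            assert e.amplitude == pytest.approx(prom, abs=1e-9)
            assert e.width == pytest.approx(w, abs=1e-6)


class TestCharacterizeEvokedEvent:
    def _segment(self, amplitude=2.0, baseline=1.0):
        t = np.arange(0, 40, 0.1)
        x = np.full_like(t, baseline)
        stim = 10.0
        sd_r = (6.0 - 1.3) / np.sqrt(2 * np.log(5))
        sd_d = (1.3 + 8.2 - 6.0) / np.sqrt(2 * np.log(5))
        rel = t - stim
        bump = np.where(rel <= 6.0, np.exp(-((rel - 6) ** 2) / (2 * sd_r**2)),
                        np.exp(-((rel - 6) ** 2) / (2 * sd_d**2)))
        bump[rel < 0] = 0.0
        return PressureTrace(rate=10.0, samples=x + amplitude * bump), stim

    def test_twenty_percent_threshold_rule(self):
        pt, stim = self._segment(amplitude=2.0)
        m = characterize_evoked_event(pt, stim, smooth=0.0)
        assert m.outcome == "eNVC"
        assert m.threshold_level == pytest.approx(0.4, abs=0.02)
        assert m.latency == pytest.approx(1.3, abs=0.15)
        assert m.time_to_peak == pytest.approx(6.0, abs=0.15)
        assert m.duration == pytest.approx(8.2, abs=0.3)

    def test_flat_segment_is_failure(self):
        pt = PressureTrace(rate=10.0, samples=np.full(400, 1.0))
        m = characterize_evoked_event(pt, 10.0)
        assert m.outcome == "failure"
        assert m.latency is None

    def test_void_level_peak(self):
        pt, stim = self._segment(amplitude=15.0, baseline=1.0)
        assert characterize_evoked_event(pt, stim, smooth=0.0).outcome == "void"

    def test_stimulus_outside_segment_rejected(self):
        pt = PressureTrace(rate=10.0, samples=np.full(400, 1.0))
        with pytest.raises(ValueError):
            characterize_evoked_event(pt, 99.0)


class TestProcessEmg:
    def test_constant_signal_envelope(self):
        emg = EMGTrace(rate=1000.0, samples=np.full(20000, 2.0))
        env = process_emg(emg)
        mid = env.samples[6000:14000]
        assert np.allclose(mid, 2.0, atol=1e-9)

    def test_artefact_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50000)
        emg = EMGTrace(rate=1000.0, samples=x)
        clean = process_emg(emg).samples
        x2 = x.copy()
        x2[25000] = 100 * np.std(x)
        with_artefact = process_emg(EMGTrace(rate=1000.0, samples=x2)).samples
        assert np.max(np.abs(with_artefact - clean)) < 0.01 * np.max(np.abs(clean))

    def test_zero_signal(self):
        env = process_emg(EMGTrace(rate=1000.0, samples=np.zeros(10000)))
        assert np.allclose(env.samples, 0.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            process_emg(EMGTrace(rate=1000.0, samples=np.zeros(100)))


class TestEusBurstMetrics:
    def _burst_trace(self, freq=22.7, dur=4.4, amp=10.0, seed=0):
        rate = 3125.0
        rng = np.random.default_rng(seed)
        t = np.arange(0, 60, 1 / rate)
        x = rng.normal(0, 1.0, len(t))
        sel = (t >= 27.8) & (t < 27.8 + dur)
        x[sel] += amp * np.sin(2 * np.pi * freq * (t[sel] - 27.8))
        return EMGTrace(rate=rate, samples=x)

    def test_frequency_and_duration_recovery(self):
        emg = self._burst_trace()
        (m,) = eus_burst_metrics(emg, [(20.0, 40.0)])
        assert m["frequency"] == pytest.approx(22.7, abs=0.5)
        assert m["duration"] == pytest.approx(4.4, abs=0.3)

    def test_noise_only_window_is_null(self):
        emg = self._burst_trace()
        out = eus_burst_metrics(emg, [(5.0, 15.0), (20.0, 40.0)])
        assert out[0]["frequency"] is None
        assert out[1]["frequency"] is not None

    def test_amplitude_invariance_of_frequency(self):
        f1 = eus_burst_metrics(self._burst_trace(amp=10), [(20.0, 40.0)])[0]["frequency"]
        f2 = eus_burst_metrics(self._burst_trace(amp=20), [(20.0, 40.0)])[0]["frequency"]
        assert f1 == pytest.approx(f2, abs=0.25)

    def test_requires_windows(self):
        with pytest.raises(ValueError):
            eus_burst_metrics(self._burst_trace(), [])


class TestNvcTriggeredSpikes:
    def test_window_arithmetic_single_spike(self):
        # one spike exactly 2 s before each event falls in the [-3, -1.5) window
        events = [50.0, 100.0, 150.0, 200.0, 250.0]
        train = np.array([e - 2.0 for e in events])
        res = nvc_triggered_spikes(
            [train], events, [(0.0, 300.0)], rng=np.random.default_rng(0)
        )
        assert res["contrasts"][0] == pytest.approx(1.0)
        k = np.searchsorted(res["bin_centers"], -1.75)
        assert res["rates"][0][k] == pytest.approx(1 / 0.5)

    def test_homogeneous_train_contrast_is_null(self):
        means = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            train = np.sort(rng.uniform(0, 600, 3000))
            events = np.sort(rng.uniform(50, 550, 12))
            res = nvc_triggered_spikes([train], events, [(0.0, 600.0)], rng=rng)
            means.append(res["contrasts"][0])
        z = np.mean(means) / (np.std(means) / np.sqrt(len(means)))
        assert abs(z) < 3

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        train = np.sort(rng.uniform(0, 600, 2000))
        events = np.sort(rng.uniform(50, 550, 8))
        res = nvc_triggered_spikes([train], events, [(0.0, 600.0)], rng=rng, bin_width=0.5)
        total = sum(
            np.sum((train >= e - 10.0) & (train < e + 10.0)) for e in events
        )
        assert res["rates"][0].sum() * 0.5 * len(events) == pytest.approx(total)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            nvc_triggered_spikes([np.arange(10.0)], [5.0], [(0.0, 20.0)], np.random.default_rng(0))
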