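"""Cystometry and EUS-EMG analysis.

Void and non-voiding-contraction (NVC) detection on bladder-pressure
traces, cystometric cycle variables (basal pressure, voiding threshold,
micturition pressure, capacity, compliance), characterisation of
optogenetically evoked pressure events, EMG envelope processing, burst
metrics, and NVC-triggered spike-count analysis with shuffled controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "PressureTrace",
    "EMGTrace",
    "VoidEvent",
    "NVCEvent",
    "EvokedEventMetrics",
    "detect_voids",
    "cycle_metrics",
    "detect_nvcs",
    "characterize_evoked_event",
    "process_emg",
    "eus_burst_metrics",
    "nvc_triggered_spikes",
]


@dataclass
class PressureTrace:
    """Uniformly sampled intravesical pressure (mmHg)."""

    rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pressure samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class EMGTrace:
    """Uniformly sampled external-urethral-sphincter EMG (arbitrary units)."""

    rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate


@dataclass
class VoidEvent:
    """One voiding contraction and its cystometric variables.

    basal: lowest pressure after the previous void; threshold: pressure at
    EUS-EMG burst onset (void initiation); peak: micturition pressure.
    Capacity (infusion rate x fill time) and compliance
    (capacity / (threshold - basal)) are filled in when computable.
    """

    peak_time: float
    peak_pressure: float
    basal_pressure: Optional[float] = None
    threshold_pressure: Optional[float] = None
    capacity_ul: Optional[float] = None
    compliance_ul_per_mmHg: Optional[float] = None


@dataclass
class NVCEvent:
    """A non-voiding contraction: transient pressure rise during filling."""

    peak_time: float
    amplitude: float
    width: float


@dataclass
class EvokedEventMetrics:
    """Characterisation of an optogenetically evoked pressure event.

    Threshold is 20% of the amplitude above the pre-stimulus baseline;
    latency runs from stimulus onset to the threshold crossing; duration
    is the time spent above threshold.
    """

    outcome: str  # "failure" | "eNVC" | "void"
    amplitude: Optional[float] = None
    threshold_level: Optional[float] = None
    latency: Optional[float] = None
    duration: Optional[float] = None
    time_to_peak: Optional[float] = None


# ---------------------------------------------------------------------------
# void detection and cycle metrics


def detect_voids(pressure: PressureTrace, min_peak: float = 10.0, min_separation: float = 30.0) -> list[VoidEvent]:
    """Detect voiding contractions as large, well-separated pressure peaks.

    Local maxima above ``min_peak`` mmHg separated by at least
    ``min_separation`` s; of two conflicting peaks the larger is kept
    (ties resolve to the earlier).  Deterministic.
    """
    x = pressure.samples
    if len(x) == 0:
        raise ValueError("empty pressure trace")
    if pressure.duration <= min_separation:
        raise ValueError("trace shorter than min_separation")
    distance = max(1, int(round(min_separation * pressure.rate)))
    # a final/initial plateau should still count: pad with -inf so edge peaks survive
    idx, _ = signal.find_peaks(np.r_[-np.inf, x, -np.inf], height=min_peak, distance=distance)
    idx -= 1
    return [VoidEvent(peak_time=pressure.t0 + i / pressure.rate, peak_pressure=float(x[i])) for i in idx]


def cycle_metrics(
    pressure: PressureTrace,
    voids: Sequence[VoidEvent],
    emg_burst_onsets: Optional[Sequence[float]] = None,
    infusion_rate_ul_per_s: Optional[float] = None,
    basal_window: float = 60.0,
) -> list[VoidEvent]:
    """Complete cystometric variables for each void-to-void cycle.

    For each void after the first: basal pressure = minimum in the window
    following the previous void; threshold pressure = pressure at the first
    EUS burst onset preceding the void; capacity = infusion rate x (burst
    onset - cycle start); compliance = capacity / (threshold - basal).
    Without EMG burst onsets, threshold/capacity/compliance are left unset.
    """
    if len(voids) < 2:
        raise ValueError("need at least one complete (void-to-void) cycle")
    out = []
    t = pressure.times
    onsets = np.sort(np.asarray(emg_burst_onsets, dtype=float)) if emg_burst_onsets is not None else None
    for prev, cur in zip(voids[:-1], voids[1:]):
        ev = VoidEvent(peak_time=cur.peak_time, peak_pressure=cur.peak_pressure)
        sel = (t > prev.peak_time) & (t <= min(prev.peak_time + basal_window, cur.peak_time))
        if sel.any():
            ev.basal_pressure = float(np.min(pressure.samples[sel]))
        if onsets is not None:
            cand = onsets[(onsets > prev.peak_time) & (onsets <= cur.peak_time)]
            if len(cand):
                onset = float(cand[-1])  # burst immediately preceding this void
                ev.threshold_pressure = float(np.interp(onset, t, pressure.samples))
                if infusion_rate_ul_per_s is not None:
                    ev.capacity_ul = infusion_rate_ul_per_s * (onset - prev.peak_time)
                    if ev.basal_pressure is not None:
                        dp = ev.threshold_pressure - ev.basal_pressure
                        ev.compliance_ul_per_mmHg = ev.capacity_ul / dp if dp > 0 else math.nan
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# NVC detection


def _intervoid_segments(n: int, rate: float, t0: float, void_times: Optional[Sequence[float]], void_halfwidth: float) -> list[tuple[int, int]]:
    """Index ranges [a, b) of intervoid periods (void peak +/- halfwidth excluded)."""
    if void_times is None or len(void_times) == 0:
        return [(0, n)]
    mask = np.ones(n, dtype=bool)
    for vt in void_times:
        a = int(np.floor((vt - void_halfwidth - t0) * rate))
        b = int(np.ceil((vt + void_halfwidth - t0) * rate)) + 1
        mask[max(a, 0) : min(b, n)] = False
    segs = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def detect_nvcs(
    pressure: PressureTrace,
    void_times: Optional[Sequence[float]] = None,
    amp_min: float = 0.1,
    amp_max: float = 4.0,
    width_bounds: tuple[float, float] = (1.5, 8.0),
    separation: float = 5.0,
    void_halfwidth: float = 15.0,
) -> list[NVCEvent]:
    """Detect non-voiding contractions in the intervoid periods.

    Each intervoid segment is linearly detrended, then peaks are kept that
    (1) rise ``amp_min``..``amp_max`` mmHg above the local baseline
    (prominence), (2) have a half-prominence width within ``width_bounds``
    seconds, and (3) lie at least ``separation`` s from any other retained
    peak (conflicts resolved by larger amplitude, then earlier time).
    Deterministic, and invariant to constant pressure offsets.
    """
    x = pressure.samples
    if len(x) == 0:
        return []
    lo_w, hi_w = width_bounds
    events: list[NVCEvent] = []
    for a, b in _intervoid_segments(len(x), pressure.rate, pressure.t0, void_times, void_halfwidth):
        seg = x[a:b]
        if len(seg) < 3:
            continue
        seg = signal.detrend(seg, type="linear")
        idx, props = signal.find_peaks(seg, prominence=(amp_min, amp_max))
        if len(idx) == 0:
            continue
        widths = signal.peak_widths(seg, idx, rel_height=0.5)[0] / pressure.rate
        keep = (widths >= lo_w) & (widths <= hi_w)
        idx, widths = idx[keep], widths[keep]
        proms = props["prominences"][keep]
        # separation filter: greedy by amplitude (desc), then time (asc)
        order = np.lexsort((idx, -proms))
        chosen: list[int] = []
        for k in order:
            if all(abs(idx[k] - idx[c]) / pressure.rate >= separation for c in chosen):
                chosen.append(k)
        for k in sorted(chosen, key=lambda k: idx[k]):
            events.append(
                NVCEvent(
                    peak_time=pressure.t0 + (a + idx[k]) / pressure.rate,
                    amplitude=float(proms[k]),
                    width=float(widths[k]),
                )
            )
    events.sort(key=lambda e: e.peak_time)
    return events


# ---------------------------------------------------------------------------
# evoked events


def characterize_evoked_event(
    pressure: PressureTrace,
    stimulus_time: float,
    response_window: float = 20.0,
    baseline_window: float = 5.0,
    failure_amplitude: float = 0.1,
    void_pressure: float = 15.0,
    smooth: float = 0.3,
    peak_window: float = 12.0,
) -> EvokedEventMetrics:
    """Characterise the pressure response to one stimulus.

    The trace is lightly smoothed (moving average over ``smooth`` s;
    threshold-crossing times are badly biased by sample noise otherwise)
    and the pre-stimulus baseline (a linear fit over ``baseline_window``
    s before the stimulus) is extrapolated and subtracted, so the slow
    infusion ramp is not mistaken for a response.  Amplitude is the
    residual post-stimulus peak; events below ``failure_amplitude`` are
    failures; raw peaks reaching ``void_pressure`` are voids; the rest
    are evoked NVCs.  Latency runs from stimulus onset to the crossing of
    20% of amplitude, duration is the time above that level, both by
    linear interpolation between samples.

    The peak is searched within ``peak_window`` s of the stimulus (evoked
    responses peak ~6 s after onset; searching the full response window
    would let slow baseline drift masquerade as a response), while the
    decay back through threshold is tracked over the whole
    ``response_window``.
    """
    t = pressure.times
    if not (t[0] <= stimulus_time <= t[-1]):
        raise ValueError("stimulus time outside the pressure segment")
    x = pressure.samples
    if smooth > 0:
        w = max(1, int(round(smooth * pressure.rate)))
        x = uniform_filter1d(x, size=w, mode="nearest")
    pre = (t >= stimulus_time - baseline_window) & (t < stimulus_time)
    post = (t >= stimulus_time) & (t <= stimulus_time + response_window)
    if not post.any():
        raise ValueError("response window extends beyond the segment")
    if pre.sum() >= 2:
        coef = np.polyfit(t[pre] - stimulus_time, x[pre], 1)
    else:
        coef = np.array([0.0, x[np.searchsorted(t, stimulus_time)]])
    baseline = 0.0  # residuals are measured about the extrapolated trend
    ts = t[post]
    xs = x[post] - np.polyval(coef, ts - stimulus_time)
    in_peak = ts <= stimulus_time + peak_window
    raw_peak = float(x[post].max())  # a precipitated void may crest late
    ipk = int(np.argmax(np.where(in_peak, xs, -np.inf)))
    amplitude = float(xs[ipk] - baseline)
    if amplitude < failure_amplitude:
        return EvokedEventMetrics(outcome="failure")
    level = baseline + 0.2 * amplitude
    above = xs >= level
    # first crossing at/after the stimulus
    rising = np.flatnonzero(above)
    i0 = rising[0]
    if i0 == 0:
        latency = float(ts[0] - stimulus_time)
    else:
        frac = (level - xs[i0 - 1]) / (xs[i0] - xs[i0 - 1])
        latency = float(ts[i0 - 1] + frac * (ts[i0] - ts[i0 - 1]) - stimulus_time)
    # end of the supra-threshold excursion containing the peak
    j = ipk
    while j + 1 < len(xs) and above[j + 1]:
        j += 1
    if j + 1 < len(xs):
        frac = (xs[j] - level) / (xs[j] - xs[j + 1])
        t_end = float(ts[j] + frac * (ts[j + 1] - ts[j]))
    else:
        t_end = float(ts[-1])
    i = i0  # start of the excursion containing the peak
    k = ipk
    while k - 1 >= 0 and above[k - 1]:
        k -= 1
    if k > 0:
        frac = (level - xs[k - 1]) / (xs[k] - xs[k - 1])
        t_start = float(ts[k - 1] + frac * (ts[k] - ts[k - 1]))
    else:
        t_start = float(ts[0])
    outcome = "void" if raw_peak >= void_pressure else "eNVC"
    return EvokedEventMetrics(
        outcome=outcome,
        amplitude=amplitude,
        threshold_level=level - baseline,
        latency=latency,
        duration=t_end - t_start,
        time_to_peak=float(ts[ipk] - stimulus_time),
    )


# ---------------------------------------------------------------------------
# EMG processing


def process_emg(
    emg: EMGTrace,
    artefact_sd: float = 50.0,
    rms_window: float = 5.0,
    smooth_window: float = 0.32,
) -> EMGTrace:
    """Artefact-cleaned RMS envelope of the EMG.

    Samples exceeding ``artefact_sd`` standard deviations are replaced by
    linear interpolation; the signal is then RMS-filtered over a moving
    ``rms_window`` (s) and smoothed with a moving mean over
    ``smooth_window`` (s; 0.32 s is 1000 samples at the default 3125 Hz).
    """
    x = emg.samples.copy()
    n = len(x)
    w_rms = int(round(rms_window * emg.rate))
    w_sm = max(1, int(round(smooth_window * emg.rate)))
    if w_rms > n or w_rms < 1:
        raise ValueError("RMS window longer than the trace (or empty)")
    sd = np.std(x)
    if sd > 0:
        bad = np.abs(x) > artefact_sd * sd
        if bad.any():
            good = ~bad
            x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])
    env = np.sqrt(np.maximum(uniform_filter1d(x * x, size=w_rms, mode="nearest"), 0.0))
    env = uniform_filter1d(env, size=w_sm, mode="nearest")
    return EMGTrace(rate=emg.rate, samples=env, t0=emg.t0)


def eus_burst_metrics(
    emg: EMGTrace,
    void_windows: Sequence[tuple[float, float]],
    threshold_k: float = 3.0,
    envelope_window: float = 0.1,
) -> list[dict]:
    """Per-void EUS burst duration and intra-burst frequency.

    A short-window RMS envelope (``envelope_window`` s, fine enough to
    resolve burst edges) is thresholded at ``threshold_k`` times the
    baseline (outside-window) standard deviation of the raw EMG.  Duration
    is the span of the supra-threshold segment within the void window;
    frequency is the dominant spectral peak of the raw EMG over that
    segment.  Returns one dict per window; ``None`` metrics where no
    supra-threshold activity exists.
    """
    if len(void_windows) == 0:
        raise ValueError("need at least one void window")
    x = emg.samples
    t = emg.times
    base_mask = np.ones(len(x), dtype=bool)
    for a, b in void_windows:
        base_mask &= ~((t >= a) & (t <= b))
    baseline_sd = float(np.std(x[base_mask])) if base_mask.any() else float(np.std(x))
    w = max(1, int(round(envelope_window * emg.rate)))
    env = np.sqrt(np.maximum(uniform_filter1d(x * x, size=w, mode="nearest"), 0.0))
    thr = threshold_k * baseline_sd
    out = []
    for a, b in void_windows:
        sel = np.flatnonzero((t >= a) & (t <= b) & (env > thr))
        if len(sel) < 2:
            out.append({"duration": None, "frequency": None})
            continue
        i0, i1 = sel[0], sel[-1]
        duration = (i1 - i0) / emg.rate
        seg = x[i0 : i1 + 1] - np.mean(x[i0 : i1 + 1])
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / emg.rate)
        spec = np.abs(np.fft.rfft(seg * np.hanning(len(seg))))
        spec[freqs < 1.0] = 0.0  # ignore DC/drift
        out.append({"duration": float(duration), "frequency": float(freqs[np.argmax(spec)])})
    return out


# ---------------------------------------------------------------------------
# NVC-triggered spike analysis


def nvc_triggered_spikes(
    spike_trains: Sequence[np.ndarray],
    nvc_times: Sequence[float],
    intervoid_segments: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    bin_width: float = 0.5,
    window: float = 10.0,
    pressure: Optional[PressureTrace] = None,
) -> dict:
    """NVC-triggered spike rates with an equal-size shuffled control.

    ``nvc_times`` should be NVC *onset* times (the pontine burst precedes
    the contraction onset by 1.5-3 s, so onset-referenced windows capture
    it; for a detected event use ``peak_time - width / 2``).  For each
    unit, spikes are binned in half-open bins of ``bin_width`` s over
    [-window, +window) around each event; the early/late contrast is the
    spike count in [-3, -1.5) minus the count in [-6, -4.5) s, averaged
    over events.  The shuffled control repeats the computation at
    an equal number of random times drawn uniformly from the intervoid
    segments.  If a pressure trace is supplied, the mean pressure excursion
    (referenced to the value at window start) is returned for both event
    sets.
    """
    nvc_times = np.asarray(nvc_times, dtype=float)
    if len(nvc_times) < 5:
        raise ValueError("need at least 5 NVC events")
    segs = np.asarray(intervoid_segments, dtype=float)
    lengths = segs[:, 1] - segs[:, 0]
    if np.any(lengths <= 0):
        raise ValueError("intervoid segments must have positive length")
    # equal number of shuffled times, uniform over the intervoid periods
    picks = rng.choice(len(segs), size=len(nvc_times), p=lengths / lengths.sum())
    shuffled = segs[picks, 0] + rng.uniform(0.0, 1.0, size=len(nvc_times)) * lengths[picks]

    edges = np.arange(-window, window + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def _triggered(events: np.ndarray):
        rates, contrasts = [], []
        for train in spike_trains:
            train = np.asarray(train, dtype=float)
            counts = np.zeros(len(centers))
            cs = []
            for ev in events:
                rel = train - ev
                rel = rel[(rel >= -window) & (rel < window)]
                counts += np.histogram(rel, bins=edges)[0]
                early = np.sum((rel >= -6.0) & (rel < -4.5))
                late = np.sum((rel >= -3.0) & (rel < -1.5))
                cs.append(late - early)
            rates.append(counts / (len(events) * bin_width))
            contrasts.append(float(np.mean(cs)))
        return np.array(rates), np.array(contrasts)

    rates, contrasts = _triggered(nvc_times)
    sh_rates, sh_contrasts = _triggered(shuffled)
    result = {
        "bin_centers": centers,
        "rates": rates,
        "contrasts": contrasts,
        "shuffled_rates": sh_rates,
        "shuffled_contrasts": sh_contrasts,
        "shuffled_times": shuffled,
    }
    if pressure is not None:
        def _excursion(events):
            curves = []
            for ev in events:
                sel = (pressure.times >= ev - window) & (pressure.times < ev + window)
                if sel.any():
                    seg = pressure.samples[sel]
                    curves.append(seg - seg[0])
            m = min(len(c) for c in curves)
            return np.mean([c[:m] for c in curves], axis=0)

        result["pressure_excursion"] = _excursion(nvc_times)
        result["shuffled_pressure_excursion"] = _excursion(shuffled)
    return result
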