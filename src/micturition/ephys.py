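"""Spike-train analysis for pontine unit recordings.

Firing-rate estimation by Gaussian convolution, auto/cross-correlograms,
optogenetic tagging of light-responsive units, micturition-phase firing
profiles, spike-count/pressure cross-correlation at 1 Hz, and sigmoid
fits of firing rate against normalised bladder pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .cystometry import PressureTrace

__all__ = [
    "SpikeTrain",
    "RateTrace",
    "PhaseProfile",
    "CorrelogramResult",
    "OptoTagResult",
    "SigmoidFit",
    "SigmoidRateModel",
    "firing_rate",
    "correlogram",
    "opto_tag",
    "phase_profile",
    "pressure_rate_xcorr",
    "fit_pressure_sigmoid",
]


@dataclass
class SpikeTrain:
    """Spike times (s) of one unit over a known recording duration."""

    times: np.ndarray
    duration: float
    unit_id: str = ""

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return len(self.times)


@dataclass
class RateTrace:
    rate: float  # sampling rate of the rate estimate, Hz
    samples: np.ndarray  # instantaneous firing rate, Hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass
class PhaseProfile:
    n_phases: int
    rates: np.ndarray  # mean rate per phase, Hz
    occupancy: np.ndarray  # time spent per phase, s
    zscored: Optional[np.ndarray] = None


@dataclass
class CorrelogramResult:
    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    normalisation: str = "counts"

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.values))])


@dataclass
class OptoTagResult:
    unit_id: str
    median_latency: Optional[float]
    reliability: float
    sustained_rate: float
    baseline_rate: float
    tagged: bool


def firing_rate(train: SpikeTrain, sd: float = 0.010, rate: float = 1000.0) -> RateTrace:
    """Smooth firing rate by convolution with a normalised Gaussian (SD ``sd`` s).

    The output integrates back to the spike count (the kernel is normalised
    to unit area), so rate is conserved as well as non-negative.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    n = max(1, int(math.ceil(train.duration * rate)))
    counts = np.zeros(n)
    if train.n_spikes:
        idx = np.minimum((train.times * rate).astype(int), n - 1)
        np.add.at(counts, idx, 1.0)
    half = int(math.ceil(4 * sd * rate))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / (sd * rate)) ** 2)
    k /= k.sum()
    return RateTrace(rate=rate, samples=np.convolve(counts, k, mode="same") * rate)


def correlogram(
    a: SpikeTrain,
    b: Optional[SpikeTrain] = None,
    bin_width: float = 0.001,
    max_lag: float = 0.05,
) -> CorrelogramResult:
    """Auto- or cross-correlogram of spike-time differences (1 ms bins).

    Counts pairs ``t_b - t_a`` per lag bin over a symmetric lag axis.  In
    auto mode the zero-lag self pairs are excluded, so a refractory train
    shows a central trough.
    """
    if bin_width <= 0 or max_lag <= 0:
        raise ValueError("bin_width and max_lag must be positive")
    auto = b is None
    tb = a.times if auto else b.times
    nbins = int(round(max_lag / bin_width))
    edges = (np.arange(-nbins, nbins + 1) - 0.5) * bin_width
    counts = np.zeros(2 * nbins, dtype=float)
    for t in a.times:
        lo = np.searchsorted(tb, t - max_lag)
        hi = np.searchsorted(tb, t + max_lag)
        d = tb[lo:hi] - t
        counts += np.histogram(d, bins=edges)[0]
    if auto:
        # remove the n self pairs (d == 0) from the bin containing zero
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        counts[zero_bin] -= a.n_spikes
    centres = (edges[:-1] + edges[1:]) / 2.0
    return CorrelogramResult(lags=centres, values=counts, bin_width=bin_width)


def opto_tag(
    train: SpikeTrain,
    pulse_times: Sequence[float],
    long_pulse_times: Sequence[float] = (),
    latency_max: float = 0.010,
    reliability_min: float = 0.5,
    response_window: float = 0.020,
    long_pulse_duration: float = 1.0,
    sustained_factor: float = 2.0,
) -> OptoTagResult:
    """Classify a unit as opto-identified from its light responses.

    Tagged iff (1) the median first-spike latency after brief pulses is
    <= ``latency_max``, (2) the fraction of pulses with a spike inside
    ``response_window`` is >= ``reliability_min``, and (3) the firing rate
    during long (1 s) pulses exceeds ``sustained_factor`` times the
    pre-pulse baseline.  Thresholds are reported alongside the result
    because no single printed criterion exists for them.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if len(pulse_times) == 0:
        raise ValueError("no pulses given")
    t = train.times
    lats = []
    responded = 0
    for p in pulse_times:
        i = np.searchsorted(t, p)
        if i < len(t) and t[i] - p <= response_window:
            lats.append(t[i] - p)
            responded += 1
    reliability = responded / len(pulse_times)
    median_latency = float(np.median(lats)) if lats else None

    long_pulse_times = np.asarray(long_pulse_times, dtype=float)
    if len(long_pulse_times):
        during = sum(
            np.sum((t >= p) & (t < p + long_pulse_duration)) for p in long_pulse_times
        ) / (len(long_pulse_times) * long_pulse_duration)
        before = sum(
            np.sum((t >= p - long_pulse_duration) & (t < p)) for p in long_pulse_times
        ) / (len(long_pulse_times) * long_pulse_duration)
    else:
        during = before = 0.0
    sustained_ok = (not len(long_pulse_times)) or during > sustained_factor * max(before, 1e-9)
    tagged = (
        median_latency is not None
        and median_latency <= latency_max
        and reliability >= reliability_min
        and sustained_ok
    )
    return OptoTagResult(
        unit_id=train.unit_id,
        median_latency=median_latency,
        reliability=reliability,
        sustained_rate=float(during),
        baseline_rate=float(before),
        tagged=bool(tagged),
    )


def phase_profile(
    train: SpikeTrain,
    void_times: Sequence[float],
    n_phases: int = 10,
    zscore: bool = False,
) -> PhaseProfile:
    """Mean firing rate in equal time divisions of each intervoid interval.

    The span between successive voids is split into ``n_phases`` equal
    windows; spike counts are divided by occupancy to give a rate per
    phase, pooled over cycles.  The void itself falls in the final phase
    bin.  Conservation: sum(rate * occupancy) equals the spike count in
    the analysed span.
    """
    void_times = np.sort(np.asarray(void_times, dtype=float))
    if len(void_times) < 2:
        raise ValueError("need at least 2 voids to define cycle phases")
    counts = np.zeros(n_phases)
    occ = np.zeros(n_phases)
    t = train.times
    for a, b in zip(void_times[:-1], void_times[1:]):
        edges = np.linspace(a, b, n_phases + 1)
        counts += np.histogram(t, bins=edges)[0]
        # the final edge is inclusive: a spike exactly at the void belongs
        # to the last phase
        counts[-1] += np.sum(t == b)
        occ += np.diff(edges)
    rates = np.divide(counts, occ, out=np.zeros_like(counts), where=occ > 0)
    z = None
    if zscore:
        sd = rates.std()
        z = (rates - rates.mean()) / sd if sd > 0 else np.zeros_like(rates)
    return PhaseProfile(n_phases=n_phases, rates=rates, occupancy=occ, zscored=z)


def _bin_counts_1hz(train: SpikeTrain) -> np.ndarray:
    edges = np.arange(0.0, math.floor(train.duration) + 1.0)
    return np.histogram(train.times, bins=edges)[0].astype(float)


def pressure_rate_xcorr(
    spikes,
    pressure: PressureTrace,
    max_lag: float = 20.0,
) -> CorrelogramResult:
    """Cross-correlation of firing and pressure at 1 Hz, z-scored.

    Both series are reduced to 1 Hz (1 s spike-count bins; pressure
    averaged per second), z-scored, and correlated with the biased
    normalisation over lags up to ``max_lag``.  Positive lag means the
    pressure change follows the firing change.
    """
    if isinstance(spikes, SpikeTrain):
        s = _bin_counts_1hz(spikes)
    elif isinstance(spikes, RateTrace):
        n = int(len(spikes.samples) / spikes.rate)
        s = spikes.samples[: int(n * spikes.rate)].reshape(n, -1).mean(axis=1)
    else:
        s = np.asarray(spikes, dtype=float)
    n_sec = int(len(pressure.samples) / pressure.rate)
    per = int(round(pressure.rate))
    p = pressure.samples[: n_sec * per].reshape(n_sec, per).mean(axis=1)
    m = min(len(s), len(p))
    s, p = s[:m], p[:m]
    maxlag = int(round(max_lag))
    if m < 10 * maxlag:
        raise ValueError("series too short for the requested maximum lag")
    if s.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    s = (s - s.mean()) / s.std()
    p = (p - p.mean()) / p.std()
    lags = np.arange(-maxlag, maxlag + 1)
    vals = np.empty(len(lags))
    for i, L in enumerate(lags):
        if L >= 0:
            vals[i] = np.sum(s[: m - L] * p[L:]) / m
        else:
            vals[i] = np.sum(s[-L:] * p[: m + L]) / m
    return CorrelogramResult(lags=lags.astype(float), values=vals, bin_width=1.0, normalisation="zscored-biased")


# ---------------------------------------------------------------------------
# sigmoid firing/pressure fit


@dataclass
class SigmoidFit:
    """Result of fitting ``f(x) = a + b / (1 + exp(c (d - x)))``.

    ``conf_int`` rows are 95% intervals for (a, b, c, d) from the
    linearised parameter covariance; ``d_in_range`` flags whether the
    midpoint lies inside the data range (a fit with ``d`` outside it is
    effectively degenerate/linear over the data).
    """

    params: np.ndarray  # a, b, c, d
    conf_int: np.ndarray  # (4, 2)
    cov: np.ndarray
    rss: float
    r_squared: float
    converged: bool
    d_in_range: bool
    n: int

    @property
    def a(self):
        return self.params[0]

    @property
    def b(self):
        return self.params[1]

    @property
    def c(self):
        return self.params[2]

    @property
    def d(self):
        return self.params[3]

    def predict(self, x):
        a, b, c, d = self.params
        return a + b / (1.0 + np.exp(c * (d - np.asarray(x, dtype=float))))

    def summary(self) -> str:
        names = ["a (baseline)", "b (range)", "c (slope)", "d (midpoint)"]
        lines = [
            "Sigmoid fit: f(x) = a + b / (1 + exp(c (d - x)))",
            f"n = {self.n}, R^2 = {self.r_squared:.4f}, converged = {self.converged}",
            f"{'param':<14}{'estimate':>12}{'95% CI low':>14}{'95% CI high':>14}",
        ]
        for name, est, (lo, hi) in zip(names, self.params, self.conf_int):
            lines.append(f"{name:<14}{est:>12.4g}{lo:>14.4g}{hi:>14.4g}")
        if not self.d_in_range:
            lines.append("warning: midpoint d lies outside the data range")
        return "\n".join(lines)


def _sigmoid(x, a, b, c, d):
    return a + b / (1.0 + np.exp(np.clip(c * (d - x), -500, 500)))


class SigmoidRateModel:
    """Firing rate as a sigmoid of normalised bladder pressure.

    ``fit`` performs bounded least squares with a small multi-start over
    the slope (the only parameter whose initialisation is delicate) and
    returns a :class:`SigmoidFit` with 95% confidence intervals.
    """

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 20:
            raise ValueError("need at least 20 (pressure, rate) pairs")
        if self.x.min() >= 0 and self.x.max() <= 1 and np.ptp(self.x) < 0.5:
            raise ValueError("pressure values span less than half the normalised range")
        if np.ptp(self.y) == 0:
            raise ValueError("degenerate data: constant firing rate")

    def fit(self, increasing: bool = True) -> SigmoidFit:
        x, y = self.x, self.y
        rng_y = np.ptp(y)
        x_half = x[np.argmin(np.abs(y - (y.min() + rng_y / 2)))]
        b_lo = 0.0 if increasing else -np.inf
        bounds = ([-np.inf, b_lo, 0.0, -np.inf], [np.inf, np.inf, np.inf, np.inf])
        best = None
        for c0 in (2.0, 10.0, 50.0):
            p0 = [float(y.min()), float(rng_y), c0, float(x_half)]
            try:
                res = optimize.least_squares(
                    lambda q: _sigmoid(x, *q) - y, p0, bounds=bounds, method="trf"
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("sigmoid fit failed from every start")
        p = best.x
        resid = _sigmoid(x, *p) - y
        rss = float(np.sum(resid**2))
        dof = max(len(x) - 4, 1)
        s2 = rss / dof
        J = best.jac
        JTJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JTJ)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(JTJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tcrit = stats.t.ppf(0.975, dof)
        ci = np.column_stack([p - tcrit * se, p + tcrit * se])
        tss = float(np.sum((y - y.mean()) ** 2))
        return SigmoidFit(
            params=p,
            conf_int=ci,
            cov=cov,
            rss=rss,
            r_squared=1.0 - rss / tss if tss > 0 else np.nan,
            converged=bool(best.success),
            d_in_range=bool(x.min() <= p[3] <= x.max()),
            n=len(x),
        )


def fit_pressure_sigmoid(x, y, increasing: bool = True) -> SigmoidFit:
    """Functional wrapper around :class:`SigmoidRateModel`."""
    return SigmoidRateModel(x, y).fit(increasing=increasing)
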