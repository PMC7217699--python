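"""Iterative simulator of the autonomous micturition feedback loop.

Bladder pressure and pontine (Barrington's CRH-neuron) firing are updated
once per timestep.  Pressure rises by a constant infusion increment; the
current pressure sets the ceiling ``smax`` of pontine firing through an
afferent logistic; the actual rate ``s`` is drawn uniformly below that
ceiling; ``s`` in turn triggers a transient Gaussian-profiled bladder
contraction whose amplitude is gated by a second, spinal logistic that is
itself scaled by pressure.  The two logistics close a positive feedback
loop that terminates each cycle in a regenerative voiding contraction.

Voids trigger at a fixed pressure threshold; the bladder then empties at a
constant rate until pressure falls below a basal value and filling restarts.
"""

from __future__ import annotations

import enum
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "Phase",
    "Perturbation",
    "ModelState",
    "SimulationTrace",
    "MicturitionModel",
    "afferent_drive_max",
    "sample_firing",
    "contraction_amplitude",
    "nvc_kernel",
    "step",
    "simulate",
    "summarize_cycles",
]


class Phase(enum.Enum):
    FILLING = "filling"
    EMPTYING = "emptying"


@dataclass
class Perturbation:
    """A manipulation applied to the loop during a window of timesteps.

    kind:
      - ``"opto_pulse"``: clamp the sampled firing rate to ``rate`` Hz,
        mimicking optogenetic activation of the pontine population.
      - ``"astressin"``: replace the spinal-logistic midpoint ``mp`` with
        ``mp_value`` Hz, mimicking intrathecal CRH-receptor blockade which
        sensitises the spinal response to descending drive.
      - ``"variance_attenuation"``: shrink the variance of sampled firing
        by ``reduction`` (fraction in [0, 1]) without changing its mean.
    """

    kind: str
    start: int = 0
    stop: int = np.iinfo(np.int64).max
    rate: float = 20.0
    mp_value: float = 5.0
    reduction: float = 0.8

    _KINDS = ("opto_pulse", "astressin", "variance_attenuation")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.stop < self.start:
            raise ValueError("perturbation window must have stop >= start")
        if not 0.0 <= self.reduction <= 1.0:
            raise ValueError("reduction must lie in [0, 1]")

    def active(self, t: int) -> bool:
        return self.start <= t < self.stop


@dataclass
class ModelState:
    """Instantaneous state of the loop.

    ``p`` is the total intravesical pressure: the slowly accumulating base
    pressure plus the transient contributions of contractions triggered in
    recent timesteps, which are queued in ``pending_bump`` (one entry per
    future timestep, nearest first).
    """

    t: int = 0
    p: float = 0.0
    s: float = 0.0
    smax: float = 0.0
    phase: Phase = Phase.FILLING
    base: float = 0.0
    pending_bump: deque = field(default_factory=deque)
    last_amplitude: float = 0.0
    void_triggered: bool = False


def afferent_drive_max(p, params: ModelParams):
    """Ceiling of pontine firing as a logistic function of bladder pressure.

    ``smax = fmin + (fmax - fmin) / (1 + exp(-ks (p - ms)))`` — the model's
    afferent limb: bladder distension translates into synaptic drive that
    raises the attainable firing rate of Barrington's CRH neurons.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    out = params.fmin + (params.fmax - params.fmin) / (
        1.0 + np.exp(-params.ks * (p - params.ms))
    )
    return float(out) if out.ndim == 0 else out


def sample_firing(smax: float, variance_scale: float, rng: np.random.Generator) -> float:
    """Draw a firing rate uniformly on [0, smax], with optional variance scaling.

    A draw ``u ~ U(0, smax)`` is shrunk towards the mean ``smax/2`` by
    ``sqrt(variance_scale)`` so that the mean is preserved exactly while the
    variance scales linearly — the operation used to simulate attenuation of
    pontine firing variability.
    """
    if smax < 0:
        raise ValueError("smax must be non-negative")
    if not 0.0 <= variance_scale <= 1.0:
        raise ValueError("variance_scale must lie in [0, 1]")
    if smax == 0:
        # still consume one draw so trajectories stay aligned across conditions
        rng.uniform(0.0, 1.0)
        return 0.0
    u = rng.uniform(0.0, smax)
    return smax / 2.0 + (u - smax / 2.0) * math.sqrt(variance_scale)


def contraction_amplitude(s: float, p: float, params: ModelParams, mp: Optional[float] = None) -> float:
    """Amplitude of the bladder contraction evoked by firing rate ``s``.

    The spinal limb of the loop: a logistic in ``s`` whose ceiling grows
    with pressure as ``dPmax_coeff * log10(p)`` (floored at zero below
    1 mmHg, where the logarithm would go negative).  ``mp`` may be
    overridden to model pharmacological sensitisation of the spinal gate.
    """
    if s < 0 or p < 0:
        raise ValueError("firing rate and pressure must be non-negative")
    if mp is None:
        mp = params.mp
    dpmax = max(0.0, params.dPmax_coeff * math.log10(p)) if p > 0 else 0.0
    return params.dP_min + (dpmax - params.dP_min) / (
        1.0 + math.exp(-params.kp * (s - mp))
    )


def nvc_kernel(amplitude: float, params: ModelParams) -> np.ndarray:
    """Gaussian temporal profile of one contraction (non-voiding contraction).

    Returns ``bump_duration`` pressure contributions for the timesteps
    following the trigger, peaking at ``amplitude`` a fixed
    ``bump_peak_offset`` after the triggering firing sample.  Successive
    contractions summate because their profiles are simply added.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    offsets = np.arange(1, params.bump_duration + 1) * params.dt
    profile = np.exp(-((offsets - params.bump_peak_offset) ** 2) / (2.0 * params.bump_variance))
    return amplitude * profile


def _effective(params: ModelParams, t: int, perturbations: Sequence[Perturbation]):
    """Resolve (opto_rate or None, mp, variance_scale) at timestep t."""
    opto = None
    mp = params.mp
    vs = params.variance_scale
    for pert in perturbations:
        if not pert.active(t):
            continue
        if pert.kind == "opto_pulse":
            opto = pert.rate
        elif pert.kind == "astressin":
            mp = pert.mp_value
        elif pert.kind == "variance_attenuation":
            vs = vs * (1.0 - pert.reduction)
    return opto, mp, vs


def step(
    state: ModelState,
    params: ModelParams,
    perturbations: Sequence[Perturbation] = (),
    rng: Optional[np.random.Generator] = None,
) -> ModelState:
    """Advance the loop by one timestep, in place, and return the state.

    Filling: infuse, mature one queued contraction contribution, update
    ``smax`` from pressure, sample ``s`` (clamped during opto windows),
    schedule a new contraction, and trigger a void when pressure reaches
    threshold.  Emptying: decrement pressure with no infusion, sampling or
    new contractions until the basal level is reached.
    """
    if rng is None:
        rng = np.random.default_rng()
    state.t += 1
    state.void_triggered = False
    opto, mp, vs = _effective(params, state.t, perturbations)

    if state.phase is Phase.FILLING:
        state.base += params.infusion_step
        active = state.pending_bump.popleft() if state.pending_bump else 0.0
        state.p = state.base + active
        state.smax = afferent_drive_max(state.p, params)
        if opto is not None:
            state.s = float(opto)
            rng.uniform(0.0, 1.0)  # keep the stream aligned with unperturbed runs
        else:
            state.s = sample_firing(state.smax, vs, rng)
        state.last_amplitude = contraction_amplitude(state.s, state.p, params, mp=mp)
        kern = nvc_kernel(state.last_amplitude, params)
        while len(state.pending_bump) < len(kern):
            state.pending_bump.append(0.0)
        for i, v in enumerate(kern):
            state.pending_bump[i] += v
        if state.p >= params.void_threshold:
            state.phase = Phase.EMPTYING
            state.void_triggered = True
            state.pending_bump.clear()
    else:
        state.p = max(0.0, state.p - params.emptying_step)
        state.base = state.p
        state.smax = afferent_drive_max(state.p, params)
        state.s = params.fmin
        state.last_amplitude = 0.0
        if state.p < params.basal_reset:
            state.phase = Phase.FILLING
            state.pending_bump.clear()
    return state


@dataclass
class SimulationTrace:
    """Per-timestep output of a simulation run.

    Arrays are aligned; ``void_times`` holds the timestep indices at which
    voids triggered (pressure at those indices is >= the void threshold).
    """

    params: ModelParams
    p: np.ndarray
    s: np.ndarray
    smax: np.ndarray
    dP: np.ndarray
    phase: np.ndarray  # 0 = filling, 1 = emptying
    void_times: np.ndarray
    seed: Optional[int] = None
    base: Optional[np.ndarray] = None  # infusion baseline (pressure minus transients)

    def __post_init__(self) -> None:
        n = len(self.p)
        if not (len(self.s) == len(self.smax) == len(self.dP) == len(self.phase) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.void_times) <= 0):
            raise ValueError("void_times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds."""
        return (np.arange(len(self.p)) + 1) * self.params.dt

    @property
    def n_voids(self) -> int:
        return len(self.void_times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pressure_mmHg": self.p,
                "firing_hz": self.s,
                "smax_hz": self.smax,
                "dP_mmHg": self.dP,
                "phase": np.where(self.phase == 0, "filling", "emptying"),
            }
        )

    def void_table(self) -> pd.DataFrame:
        idx = self.void_times.astype(int)
        return pd.DataFrame(
            {
                "void_index": np.arange(len(idx)),
                "time_s": (idx + 1) * self.params.dt,
                "peak_pressure_mmHg": self.p[idx],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Per-cycle summary; see :func:`summarize_cycles`."""
        return summarize_cycles(self)


def simulate(
    params: ModelParams,
    n_steps: Optional[int] = None,
    n_voids: Optional[int] = None,
    perturbations: Sequence[Perturbation] = (),
    seed: Optional[int] = None,
    initial_pressure: float = 0.0,
    max_steps: int = 2_000_000,
) -> SimulationTrace:
    """Run the feedback loop until ``n_steps`` elapse or ``n_voids`` occur.

    Fully reproducible from (params, perturbations, seed): the same seed
    yields a bit-identical trace.
    """
    if n_steps is None and n_voids is None:
        raise ValueError("specify n_steps and/or n_voids")
    if (n_steps is not None and n_steps < 1) or (n_voids is not None and n_voids < 1):
        raise ValueError("stopping criteria must be positive")
    rng = np.random.default_rng(seed)
    state = ModelState(p=initial_pressure, base=initial_pressure)
    ps, ss, sm, dps, ph, bs = [], [], [], [], [], []
    voids = []
    while True:
        step(state, params, perturbations, rng)
        ps.append(state.p)
        ss.append(state.s)
        sm.append(state.smax)
        dps.append(state.last_amplitude)
        ph.append(0 if state.phase is Phase.FILLING else 1)
        bs.append(state.base)
        if state.void_triggered:
            voids.append(state.t - 1)  # 0-based index into the arrays
        if n_steps is not None and state.t >= n_steps:
            break
        if n_voids is not None and len(voids) >= n_voids:
            break
        if state.t >= max_steps:
            raise RuntimeError(f"simulation exceeded max_steps={max_steps}")
    return SimulationTrace(
        params=params,
        p=np.array(ps),
        s=np.array(ss),
        smax=np.array(sm),
        dP=np.array(dps),
        phase=np.array(ph, dtype=np.int8),
        void_times=np.array(voids, dtype=int),
        seed=seed,
        base=np.array(bs),
    )


def summarize_cycles(trace: SimulationTrace, nvc_amp_min: float = 0.1, nvc_amp_max: float = 4.0) -> pd.DataFrame:
    """Per-cycle metrics: interval, peak pressure, detected NVC statistics.

    NVCs are measured on the simulated pressure with the cystometry
    detector (detrended intervoid peak search), not from the generator's
    internal amplitudes, so the summary reflects what an experimenter
    would extract from the trace.  Amplitude quintile columns report the
    mean detected amplitude within each fifth of the cycle.
    """
    import warnings

    from .cystometry import PressureTrace, detect_nvcs

    if trace.n_voids == 0:
        warnings.warn("trace contains no voids; returning empty summary")
        return pd.DataFrame(
            columns=[
                "cycle", "start_s", "void_s", "interval_s", "peak_pressure_mmHg",
                "n_nvcs", "mean_nvc_amp_mmHg",
            ]
            + [f"nvc_amp_q{i}" for i in range(1, 6)]
        )
    dt = trace.params.dt
    ptrace = PressureTrace(rate=1.0 / dt, samples=trace.p)
    void_idx = trace.void_times.astype(int)
    nvcs = detect_nvcs(ptrace, void_times=(void_idx + 1) * dt, amp_min=nvc_amp_min, amp_max=nvc_amp_max)
    nvc_times = np.array([e.peak_time for e in nvcs])
    nvc_amps = np.array([e.amplitude for e in nvcs])

    rows = []
    starts = np.concatenate([[0], void_idx[:-1] + 1])
    for i, (a, b) in enumerate(zip(starts, void_idx)):
        # cycle runs from the previous void (or the trace origin) to this void
        t0, t1 = a * dt, (b + 1) * dt
        in_cycle = (nvc_times > t0) & (nvc_times <= t1) if len(nvc_times) else np.array([], bool)
        amps = nvc_amps[in_cycle] if len(nvc_times) else np.array([])
        times = nvc_times[in_cycle] if len(nvc_times) else np.array([])
        row = {
            "cycle": i,
            "start_s": t0,
            "void_s": t1,
            "interval_s": t1 - t0,
            "peak_pressure_mmHg": float(np.max(trace.p[a : b + 1])),
            "n_nvcs": int(in_cycle.sum()) if len(nvc_times) else 0,
            "mean_nvc_amp_mmHg": float(np.mean(amps)) if len(amps) else np.nan,
        }
        for q in range(5):
            lo = t0 + (t1 - t0) * q / 5.0
            hi = t0 + (t1 - t0) * (q + 1) / 5.0
            sel = (times > lo) & (times <= hi)
            row[f"nvc_amp_q{q + 1}"] = float(np.mean(amps[sel])) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class MicturitionModel:
    """Object-style front end to the feedback-loop simulator.

    Parameters are fixed at construction; :meth:`simulate` returns a
    :class:`SimulationTrace` whose :meth:`~SimulationTrace.summary` gives
    per-cycle metrics.  Fitting the loop parameters to in-vivo recordings
    is deliberately out of scope; the class exists to make simulation,
    perturbation experiments and downstream analysis ergonomic.
    """

    def __init__(self, params: Optional[ModelParams] = None):
        self.params = params if params is not None else ModelParams()

    def simulate(self, n_steps=None, n_voids=None, perturbations=(), seed=None, **kw) -> SimulationTrace:
        return simulate(self.params, n_steps=n_steps, n_voids=n_voids,
                        perturbations=perturbations, seed=seed, **kw)

    def with_params(self, **changes) -> "MicturitionModel":
        return MicturitionModel(self.params.replace(**changes))
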