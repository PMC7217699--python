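"""Parameter containers for the autonomous micturition feedback-loop model.

The model couples bladder pressure to the firing of pontine (Barrington's
nucleus) CRH neurons through two logistic functions: an ascending (afferent)
limb mapping pressure to the ceiling of pontine firing, and a descending
(spinal) limb mapping pontine firing to the amplitude of the evoked bladder
contraction, itself scaled by current pressure.  Defaults are the published
operating point of the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping


@dataclass
class ModelParams:
    """Parameters of the micturition feedback loop.

    Attributes
    ----------
    fmin, fmax : float
        Floor and ceiling of the pontine firing-rate ceiling ``smax`` (Hz).
    ks, ms : float
        Slope (1/mmHg) and midpoint (mmHg) of the afferent logistic
        mapping pressure to ``smax``.
    kp, mp : float
        Slope (1/Hz) and midpoint (Hz) of the spinal logistic mapping
        firing rate to contraction amplitude.
    dP_min : float
        Minimum contraction amplitude (mmHg); zero so that low firing
        produces no detectable response ("failures").
    dPmax_coeff : float
        Pressure-dependent ceiling of contraction amplitude is
        ``dPmax_coeff * log10(p)`` mmHg (floored at 0 for p < 1 mmHg).
    infusion_step : float
        Pressure increment per timestep from continuous infusion (mmHg).
    void_threshold : float
        Pressure at which a void is triggered (mmHg).
    emptying_step : float
        Pressure decrement per timestep while the bladder empties (mmHg).
    basal_reset : float
        Pressure below which filling restarts after a void (mmHg).
    dt : float
        Duration of one model timestep (s).
    bump_duration : int
        Number of timesteps over which one contraction (NVC) unfolds.
    bump_variance : float
        Variance of the Gaussian contraction profile (s^2).
    bump_peak_offset : float
        Delay from the triggering firing sample to the contraction peak (s).
    variance_scale : float
        Scales the variance of sampled firing about its mean ``smax/2``;
        1 is the full uniform sampler, 0 is deterministic.
    opto_rate : float
        Firing rate imposed during simulated optogenetic activation (Hz).
    """

    fmin: float = 4.3
    fmax: float = 25.0
    ks: float = 4.0
    ms: float = 4.5
    kp: float = 0.5
    mp: float = 6.0
    dP_min: float = 0.0
    dPmax_coeff: float = 6.0
    infusion_step: float = 0.015
    void_threshold: float = 15.0
    emptying_step: float = 2.0
    basal_reset: float = 0.3
    dt: float = 1.0
    bump_duration: int = 6
    bump_variance: float = 2.0
    bump_peak_offset: float = 3.5
    variance_scale: float = 1.0
    opto_rate: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.fmax > self.fmin >= 0:
            raise ValueError("require fmax > fmin >= 0")
        if not self.void_threshold > self.basal_reset > 0:
            raise ValueError("require void_threshold > basal_reset > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.bump_duration < 1:
            raise ValueError("bump_duration must be >= 1")
        if not 0.0 <= self.variance_scale <= 1.0:
            raise ValueError("variance_scale must lie in [0, 1]")
        if self.bump_variance <= 0:
            raise ValueError("bump_variance must be positive")
        if self.infusion_step < 0 or self.emptying_step <= 0:
            raise ValueError("infusion_step >= 0 and emptying_step > 0 required")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**dict(d))
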