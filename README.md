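# micturition

Simulation and analysis of autonomous micturition — the reflex bladder
filling/voiding cycle of the urethane-anaesthetised mouse — built around a
probabilistic feedback-loop model of the pontine (Barrington's nucleus CRH
neuron) drive to the bladder and its spinal gating.

The package is for physiologists and computational neuroscientists who want
to (1) simulate the micturition cycle and its optogenetic / pharmacological
perturbations, (2) generate complete synthetic cystometry sessions
(pressure, multi-unit spike trains, sphincter EMG) with ground-truth
annotations, and (3) run the standard analysis chain — void and
non-voiding-contraction (NVC) detection, cystometric variables, evoked-event
characterisation, EMG burst metrics, opto-tagging, phase profiles,
spike–pressure cross-correlation and sigmoid firing–pressure fits — on
either synthetic or recorded data.

## The model

Bladder pressure `p(t)` and pontine firing `s(t)` are updated once per
second. Two logistic functions close the loop:

- **Afferent limb** — distension sets the ceiling of pontine firing:

  `smax(t) = fmin + (fmax − fmin) / (1 + exp(−ks (p(t) − ms)))`

  with `fmin = 4.3 Hz`, `fmax = 25 Hz`, `ks = 4 /mmHg`, `ms = 4.5 mmHg`.
  The actual rate is sampled uniformly: `s(t) ~ U(0, smax(t))`.

- **Spinal limb** — firing evokes a transient contraction whose amplitude is
  gated by pressure:

  `ΔP(t) = ΔPmin + (ΔPmax − ΔPmin) / (1 + exp(−kp (s(t) − mp)))`,
  `ΔPmax = 6·log10 p(t)` (floored at 0 below 1 mmHg),

  with `kp = 0.5 /Hz`, `mp = 6 Hz`, `ΔPmin = 0`. Each contraction unfolds as
  a Gaussian bump (6 samples, variance 2 s²) added to the pressure;
  overlapping bumps summate. Infusion adds 0.015 mmHg/s; a void triggers at
  15 mmHg, after which pressure falls 2 mmHg/s until it drops below
  0.3 mmHg and filling restarts.

Low firing produces no detectable response ("failures"), mid-cycle firing
bursts produce NVCs that grow with filling, and late in the cycle the two
logistics regenerate into a voiding contraction. Perturbations reproduce the
experimental manipulations: clamping `s` to 20 Hz (optogenetic pulse),
lowering `mp` to 5 Hz (intrathecal CRH-receptor blockade), and shrinking the
firing variance by 80 % at a fixed mean (NVC attenuation).

A companion conductance-based model (`micturition.ppn`) shows how the spinal
logistic can arise: a single-compartment parasympathetic preganglionic
neuron receives a fast pontine synapse (subthreshold alone, ~20 % EPSP
summation at 20 Hz) and a ramping bladder-afferent drive; pontine trains
evoke no output early in the filling cycle and 8–10 spikes/s at its end.

## Worked example

```python
from micturition import MicturitionModel

model = MicturitionModel()                      # published default parameters
trace = model.simulate(n_voids=3, seed=42)
print(trace.void_table().to_string(index=False))
print(trace.summary()[["cycle", "interval_s", "n_nvcs",
                       "mean_nvc_amp_mmHg"]].to_string(index=False))
```

```
 void_index  time_s  peak_pressure_mmHg
          0   147.0           16.703531
          1   310.0           16.602178
          2   441.0           15.834405
 cycle  interval_s  n_nvcs  mean_nvc_amp_mmHg
     0       147.0       3           0.309945
     1       163.0       5           0.371590
     2       131.0       1           0.653881
```

Three micturition cycles, 131–163 s apart, each voiding just above the
15 mmHg threshold. The per-cycle summary runs the NVC detector (detrended
intervoid peak search, 0.1–4 mmHg, 1.5–8 s wide, ≥5 s apart) on the
simulated pressure: a handful of sub-mmHg NVCs per cycle whose amplitude
grows as the bladder fills.

The same objects feed the rest of the toolkit, e.g.
`micturition.synthetic.generate_recording` for a full annotated session and
`micturition.ephys.SigmoidRateModel(x, y).fit()` for a firing-vs-pressure
sigmoid with 95 % confidence intervals and a `summary()` table. A thin CLI
mirrors the library: `micturition simulate|generate|analyze|ppn|pipeline`.

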