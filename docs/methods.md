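# Methods

## The feedback-loop model

The simulator advances bladder pressure `p` and pontine firing `s` in 1 s
steps. During filling each step: (1) adds the infusion increment
(0.015 mmHg) to the base pressure and matures the contraction contributions
queued for this step; (2) computes the firing ceiling
`smax = fmin + (fmax − fmin)/(1 + e^(−ks(p−ms)))` from the *total* pressure;
(3) samples `s ~ U(0, smax)`; (4) schedules a new contraction of amplitude
`ΔP = ΔPmax/(1 + e^(−kp(s−mp)))`, `ΔPmax = 6·log10 p` (0 below 1 mmHg),
shaped as a Gaussian bump over the next six steps; (5) triggers a void when
`p ≥ 15 mmHg`. Emptying then removes 2 mmHg per step — no infusion, no
sampling, no new contractions, pending contributions discarded — and
filling restarts once `p < 0.3 mmHg` (in practice the emptying staircase
ends at 0). All rate/step constants are the published operating point;
a run is bit-reproducible from (parameters, perturbations, seed).

Interpretive choices where the published description is ambiguous:

- **Log base.** `ΔPmax = 6·log p` is read as log10. With the natural log
  the loop is supercritical from ~2 mmHg: cycles last ~90 s, ~70 % of each
  cycle sits below 1 mmHg, contractions merge into a continuous rise with
  essentially no detectable discrete NVCs, and attenuating the firing
  variance barely delays voiding. With log10 the loop produces ~110–170 s
  cycles carrying 3–5 isolated NVCs of 0.1–1 mmHg (the amplitude band the
  detection criteria target), variance attenuation delays voiding robustly,
  and optogenetic failures are confined to the early cycle — the qualitative
  behaviours the model exists to exhibit.
- **Contraction timing.** The six-sample Gaussian bump (variance 2 s²) peaks
  at its centre, 3.5 s after the triggering firing sample. This yields a
  firing→pressure cross-correlation peak at +3 s (1 Hz sampling) and a
  burst-to-contraction-onset precedence of ~1.8 s (half-rise), inside the
  1.5–3 s window seen in vivo. An offset of 3 s — superficially the obvious
  choice — yields a +2 s correlation peak and ~1.3 s precedence, failing
  both observations, because the instantaneous pressure→firing coupling
  drags the correlation peak earlier than the bump delay itself.
- **`ΔPmin = 0`** so that low firing produces no detectable response;
  the uniform sampler's lower bound is 0; sampled firing below `fmin` is not
  clipped (`fmin` floors only the ceiling `smax`).
- **Variance attenuation** rescales deviations about the preserved mean
  `smax/2` by √(1−0.8); an optogenetic pulse clamps `s` (consuming one
  random draw so perturbed and control runs stay stream-aligned); the CRH
  antagonist simulation replaces `mp` by 5 Hz.

Perturbation effects at the default operating point (medians over 20-seed
batteries, 5 cycles each): variance attenuation delays the first void by
~10 s; `mp` 6→5 raises the median generated contraction amplitude by ~38 %
and shortens the intervoid interval by ~24 %. The *detected* NVC amplitude
is not a reliable readout of the latter effect — sensitising the gate also
compresses the cycle, so the population of resolvable, isolated NVCs shifts
— which is why the tests assert the generated amplitudes and the detected
intervals.

## The preganglionic neuron model

A single-compartment neuron with squid-type spike conductances
(`g_Na = 120`, `g_K = 36`, `g_leak = 0.3 mS/cm²`, leak reversal −54.4 mV,
resting ≈ −65 mV) integrated at 25 µs (gates by exponential update, voltage
by forward Euler; halving the step changes per-stimulus spike counts by at
most one). Two exponential-decay excitatory synapses (reversal 0 mV): a
pontine input driven by 20 Hz × 1 s trains, and a bladder-afferent input
whose event rate ramps linearly over 300 s.

The afferent drive represents the *aggregate* pelvic-afferent ensemble, not
one fibre: default 0 → 300 Hz (e.g. ~30 fibres at ~10 Hz by cycle end), so
individual afferent EPSPs are small and the drive is effectively tonic.
This matters in a single compartment: a single-fibre rate (~15 Hz) forces a
per-event weight so large that chance coincidence with a pontine EPSP fires
the cell early in the ramp, while the dendritic placement that filters such
events in a morphological model is unavailable here.

Synaptic parameters are calibrated, not copied: (1) the pontine decay
constant is bisected so 20 Hz EPSP summation (steady-state peak / first
peak − 1) lands at ~20 % (result: ~47 ms); (2) the pontine weight is set to
0.55× the minimal train-spiking weight — single EPSPs and cycle-start
trains are subthreshold, and doubling the weight breaks that, as required;
(3) the afferent weight is bracketed by a coarse scan (the response is
monotone in weight only below depolarisation block) and bisected so the
train at ramp end evokes 8–10 spikes/s while the ramp alone stays silent.
The calibrated gate is steep: trains at ten equally spaced ramp positions
evoke [0 0 0 0 0 0 0 0 0 8] spikes — output confined to the final tenth of
the cycle, as in the recordings.

## The synthetic-recording generator

`generate_recording` resamples a model run to 10 Hz and adds Gaussian
transducer noise (SD 0.02 mmHg — the published recordings resolve 0.1 mmHg
contractions, so instrument noise must sit well below that floor); each of
the (default 8) units is an independent inhomogeneous Poisson realisation
of the model's firing series with a once-drawn log-normal gain (SD 0.2,
emulating the amplitude spread between identified and putative pontine
units — a generator convenience, not a biological claim); EUS EMG is
baseline Gaussian noise (3125 Hz, so the standard 0.32 s smoothing window
is exactly 1000 samples) plus a near-rectangular (short-taper Tukey)
22.7 Hz burst of 4.4 s at each void, onset preceding the pressure peak.
All draws derive from one seed through named substreams.

Ground-truth NVC annotations are what an ideal noise-free observer applying
the standard criteria (per-segment linear detrend; 0.1 mmHg prominence
floor; 1.5–8 s half-prominence width; 5 s isolation, larger peak first)
annotates on the model-resolution trace — late-cycle summated complexes are
not counted as distinct NVCs. Detector correctness itself is established
independently against a literal brute-force restatement of those criteria;
the truth-recovery test therefore measures robustness to noise and
resampling (noiseless recall ≈ 0.99).

The evoked-stimulation protocol places one 20 Hz stimulus per cycle of a
deterministic (variance-suppressed) model run, by default at 60–80 % of the
filling phase — the paper's mid-fill stimulation series, where events are
well isolated from both the early failure zone and the imminent void. The
response is an asymmetric-Gaussian bump constructed so the standard
characterisation reads back its latency (1.3 s to the 20 % threshold),
time-to-peak (6.0 s) and duration (8.2 s above threshold) directly, with
per-event jitter at the published spreads; its amplitude is the spinal
logistic at the local total pressure, so stimuli below 1 mmHg fail
naturally. A stimulus is labelled a void when the noiseless composite
reaches 15 mmHg within 20 s — on its own or on top of the imminent
spontaneous rise.

## Analysis conventions

- **Void detection**: peaks above 10 mmHg separated by ≥30 s (the published
  analysis verified voids by eye; these defaults are explicit and
  configurable). Cystometric variables follow the printed definitions;
  compliance = capacity / (threshold − basal), flagged NaN when the
  denominator is not positive.
- **NVC detection**: intervoid periods only (void ± 15 s excluded);
  per-segment linear detrend; prominence 0.1–4 mmHg; half-prominence width
  1.5–8 s; 5 s isolation resolved larger-first then earlier-first.
  Detections are invariant to constant pressure offsets.
- **NVC-triggered spike analysis**: event times are NVC *onsets*
  (peak − width/2): the pontine burst precedes the contraction onset by
  1.5–3 s, so onset-referenced windows — counts in [−3, −1.5) minus
  [−6, −4.5) s, half-open bins — capture it. Peak-referenced windows
  (with the burst at −4.5…−3 s) invert the contrast. The shuffled control
  redraws an equal number of times uniformly from the intervoid segments.
- **Evoked events**: the trace is smoothed (0.3 s moving average; threshold
  crossing times are badly noise-biased otherwise) and a linear fit to the
  5 s pre-stimulus baseline is subtracted, so the infusion ramp is not
  mistaken for a response. Amplitude and shape are measured within 12 s of
  the stimulus (responses peak ~6 s in; a 20 s search lets baseline drift
  masquerade as amplitude), the void decision over the full 20 s.
- **EMG**: artefacts >50 SD are interpolated out; the display envelope is a
  5 s moving RMS smoothed over 0.32 s; burst *metrics* use a 0.1 s RMS
  envelope (a 5 s window smears a 4.4 s burst into ~8 s) thresholded at 3×
  the baseline SD, with the intra-burst frequency from the dominant
  spectral peak of the raw segment.
- **Spike–pressure cross-correlation**: both series at 1 Hz (1 s spike
  bins, per-second pressure means), z-scored, biased normalisation;
  positive lag means pressure follows firing.
- **Opto-tagging** thresholds (nowhere printed): median first-spike latency
  ≤10 ms, reliability ≥0.5 within a 20 ms response window, sustained rate
  during 1 s pulses >2× the pre-pulse baseline; all configurable and
  reported with the result.
- **Sigmoid fits** of rate vs normalised pressure use bounded least squares
  with three slope starts (2, 10, 50); 95 % CIs come from the linearised
  covariance with t critical values. Per-parameter CI coverage on generated
  data is ≥90 % at nominal 95 % (100-seed check); joint all-four coverage
  is necessarily lower and is not a calibration criterion. A fitted
  midpoint outside the data range is flagged.

## Problem sizes

Default test and reproduction runs use desk-scale sizes chosen to estimate
each quantity stably: 10–50 simulated cycles (the cross-correlation lag
uses 50, ~7,000 steps), 20 synthetic voids for EMG metrics, 200 evoked
events, 20-seed perturbation batteries, 100-seed coverage and oracle
batteries, and single 300 s neuron-model protocols (the calibration search
takes ~40 s).

## Limitations

The generator emulates the statistical structure the analyses assume — it
shares the feedback-loop model's idealisations (fixed void threshold, no
urethral sphincter inside the loop, stationary parameters) and adds white
measurement noise only; real recordings carry drift, movement artefacts,
sorting errors and non-stationary excitability that passing tests say
nothing about. Model parameters are not fitted to recordings (out of
scope), and the neuron model constrains behaviour, not biophysical
parameter values: it is a single compartment with generic spike kinetics,
and its calibrated weights should not be read as measurements.
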