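# Default parameters: the published operating point of the micturition
# feedback-loop model plus the synthetic-recording generator settings.
model:
  fmin: 4.3            # Hz, floor of the pontine firing ceiling
  fmax: 25.0           # Hz, ceiling of the pontine firing ceiling
  ks: 4.0              # 1/mmHg, afferent logistic slope
  ms: 4.5              # mmHg, afferent logistic midpoint
  kp: 0.5              # 1/Hz, spinal logistic slope
  mp: 6.0              # Hz, spinal logistic midpoint
  dP_min: 0.0          # mmHg, contraction amplitude floor
  dPmax_coeff: 6.0     # mmHg per log10-unit of pressure
  infusion_step: 0.015 # mmHg per timestep
  void_threshold: 15.0 # mmHg
  emptying_step: 2.0   # mmHg per timestep
  basal_reset: 0.3     # mmHg
  dt: 1.0              # s
  bump_duration: 6     # timesteps
  bump_variance: 2.0   # s^2
  bump_peak_offset: 3.5  # s after the triggering firing sample
  variance_scale: 1.0
  opto_rate: 20.0      # Hz
generator:
  pressure_rate: 10.0
  pressure_noise_sd: 0.02
  n_units: 8
  unit_gain_sd: 0.2
  emg_rate: 3125.0
  emg_noise_sd: 1.0
  eus_burst_rate: 22.7
  eus_burst_duration: 4.4
  eus_burst_amplitude: 10.0
  evoked_latency: 1.3
  evoked_time_to_peak: 6.0
  evoked_duration: 8.2
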