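# Versioned default configuration: prior means of the biophysical model and
# prior variances of the fitted log-scale parameters.  Baseline connection
# strengths were chosen so that, at the prior means, the circuit is stable,
# the observed 5-45 Hz spectrum peaks in the beta band (15-30 Hz), and the
# superficial pyramidal population expresses faster activity (higher
# spectral peak) than the deep pyramidal population.
version: 1

frequency_grid:
  start_hz: 5.0
  stop_hz: 45.0
  step_hz: 0.5

sigmoid_slope: 0.6666666666666666

priors:
  delay_ms: 1.0
  variance:
    gamma: 0.0625        # 1/16 on intrinsic log-scalings
    beta: 0.0625         # 1/16 on condition modulators
    kappa: 0.015625      # 1/64 on log rate-constant deviations
    delay: 0.015625      # 1/64 on log delay deviations
    obs_contrib: 0.0625  # 1/16 on log observation contributions
    gain: 0.125          # 1/8 on log gain
    noise: 0.125         # 1/8 on log noise amplitudes

inversion:
  max_iter: 128
  tol_nats: 0.01
  fd_step: 1.0e-4

# Rate constants place the deep-inhibitory loop resonance (~sqrt(k_DP*k_II)
# rad/ms) in the beta band and the superficial-inhibitory loop near 40 Hz;
# loop strengths sit at roughly half their critical products, giving clear
# resonances with a stability margin against log-scale perturbations.
m1:
  time_constant_ms:
    superficial_pyramidal: 4.0
    middle_pyramidal: 7.0
    deep_pyramidal: 16.0
    inhibitory_interneuron: 4.0
  base_strength:
    SP->MP: 0.26
    MP->SP: 0.81
    SP->DP: 10.0
    SP->II: 0.68
    II->SP: 8.7
    MP->II: 5.7
    II->MP: 0.35
    DP->II: 0.16
    II->DP: 0.34
    DP->SP: 0.9
    DP->MP: 0.05
    MP->DP: 0.3
    SP->SP: 2.0
    MP->MP: 6.0
    DP->DP: 1.4
    II->II: 0.47
  observation:
    contributions:
      superficial_pyramidal: 0.2
      middle_pyramidal: 0.2
      deep_pyramidal: 0.6
      inhibitory_interneuron: 0.0
    gain: 1.0
    channel_noise_white: 5.0e-6
    channel_noise_pink: 2.0e-5
  noise:
    # small absolute scale keeps the stochastic simulation in the sigmoid's
    # near-linear regime; the observation gain absorbs absolute power.
    white_amplitude: 1.0e-6
    pink_amplitude: 1.0e-6
    pink_exponent: 1.0
    input_gains:
      Es: 1.0
      Em: 1.0
      Ed: 1.0

reduced_cmc:
  time_constant_ms:
    spiny_stellate: 4.0
    superficial_pyramidal: 4.0
    deep_pyramidal: 16.0
    inhibitory_interneuron: 4.0
  base_strength:
    SS->SP: 1.0
    SP->DP: 8.0
    SS->II: 0.7
    II->SS: 1.0
    SP->II: 0.6
    II->SP: 6.0
    DP->II: 0.16
    II->DP: 0.34
    SS->SS: 1.5
    SP->SP: 2.0
    DP->DP: 1.4
    II->II: 0.47
  observation:
    contributions:
      spiny_stellate: 0.0
      superficial_pyramidal: 0.4
      deep_pyramidal: 0.6
      inhibitory_interneuron: 0.0
    gain: 1.0
    channel_noise_white: 5.0e-8
    channel_noise_pink: 2.5e-7
  noise:
    white_amplitude: 1.0e-6
    pink_amplitude: 1.0e-6
    pink_exponent: 1.0
    input_gains:
      Eg: 1.0

synthetic:
  n_subjects: 11
  n_trials: 60
  fs_hz: 600.0
  effect_log_units: 0.3
  jitter_sd_log: 0.1
  spectral_noise_sd_log: 0.1
  grip_increase:            # rest -> grip connectivity increases
    - DP->SP
    - SP->MP
    - MP->SP
    - MP->MP
  post_grip_input_increase: # rest -> post-grip input increases
    - Es
    - Ed
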