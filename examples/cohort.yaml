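# Standard experimental setup: 25 participants x 2 days, 400 trials/session
# at a 70/30 correct/error feedback ratio, 37-channel 10-10 montage, 1200 Hz.
# Uncomment the scaled-down block for a desktop-sized run.
n_participants: 25
n_days: 2
n_per_movement: 100
ratio_correct: 0.70
fs_hz: 1200.0
# montage: null -> the full 37-channel sensorimotor montage
profile:
  participant_amp_scale: 0.5
  day_amp_scale: 0.25
  latency_jitter_ms: 10.0
  day_latency_shift_ms: 30.0
  noise_rms_uV: 6.0
  alpha_rms_uV: 1.0
  artifact_epoch_rate: 0.18
  artifact_amp_uV: 300.0
  bad_channel_rate: 0.008
templates:
  neg_peak_latency_ms: 350.0
  pos_peak_latency_ms: 450.0
  neg_amp_uV: -4.0
  pos_amp_uV: 3.0
  class_delta_uV: -2.5
preprocess:
  band_hz: [0.05, 10.0]
  filter_order: 8
  bad_channel_sd_k: 3.0
  epoch_window_ms: [100.0, 500.0]
  reject_amp_uV: 150.0
  balance: true
methods: [mlp-features, mlp-epoch, slda-features]
schemes: [within-day, between-day, across-participant]
cv_folds: 10
master_seed: 0

# --- scaled-down desktop variant ---
# n_participants: 4
# n_per_movement: 50
# fs_hz: 200.0
# montage: [Fz, F1, F2, FCz, FC1, FC2, Cz, C1, C2]
# profile: {bad_channel_rate: 0.0}
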