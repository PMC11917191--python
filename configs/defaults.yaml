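# Study-default parameters for dyadnirs run-all.
# Every value here mirrors the library defaults; edit a copy to override.
seed: 0
n_subjects: 12
simulate: true
out_dir: run
run_preproc: true
run_stats: true
dyad:
  duration_ms: 240000      # 4 coded minutes (after the 1 min warm-up)
  infant_rate: 0.1         # infant behaviors per second of mutual gaze
  maternal_base_rate: 0.1
  response_prob: 0.5
  response_latency_low_ms: 100.0
  response_latency_high_ms: 900.0
  gaze_coverage: 0.8
contingency:
  window_ms: 1000
  warmup_ms: 60000
  coded_ms: 240000
  inclusive_end: true
  reuse_maternal: true
nirs:
  n_trials_per_condition: 10
  sampling_hz: 7.8125
  baseline_s: 12.0
  trial_s: 15.0
preproc:
  dpf: 5.1
  motion_sd_thresh: 14.0
  motion_amp_thresh: 0.4
  motion_window_s: 1.0
  wavelet_iqr: 0.5
  bandpass_low_hz: 0.01
  bandpass_high_hz: 1.0
  epoch_s: 18.0
  baseline_ref_s: 3.0
  min_trials_per_condition: 3
  min_roi_channels: 2
  enable_heart_rate_check: true
stats:
  n_bins: 6
  bin_s: 3.0
  min_regression_n: 10
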