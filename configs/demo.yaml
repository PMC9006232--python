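# Demo: synthetic study over the 100-day overlap window analysed in
# ten-day periods, with the defaults documented in docs/methods.md.
mode: synthetic
seed: 1
output_dir: scratch/demo_out
synthetic:
  start_date: 2013-05-01
  end_date: 2013-08-08
  species:
    baboon:
      daily_rate: 3.0
      group_size_lambda: 8.0
      items_per_individual_mean: 1.5
      guard_detect_prob: 0.85
      camera_trigger_p: 0.9
    vervet:
      daily_rate: 2.0
      group_size_lambda: 3.0
      items_per_individual_mean: 0.5
      guard_detect_prob: 0.15
      camera_trigger_p: 0.4
clustering:
  camera_window_min: 30
  obs_gap_min: 1
analysis:
  start_date: 2013-05-01
  end_date: 2013-08-08
  period_len_days: 10
subsets:
  sizes: [1, 2, 3, 4, 5]
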