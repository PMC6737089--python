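# Synthetic demonstration session for `avakit run-all`.
# All omitted keys take the documented defaults (neuropil alpha 0.9,
# 10-s dF/F baseline window, ANOVA p < 0.01, 10 shuffle repeats,
# collapse b grid -0.5..0.5 step 0.001).
seed: 7
output_dir: scratch/pipeline_demo
synthetic:
  n_neurons: 120
  protocol:
    freq_lo: 3000.0
    freq_hi: 48000.0
    tones_per_octave: 2
    levels: [40.0, 60.0, 80.0]
    reps: 5
    stim_dur: 1.0
    isi_range: [4.0, 6.0]
    frame_rate: 30.0
  branching_param: 1.0
  drive_rate: 0.02
  evoked_drive_per_level: [0.05, 0.1, 0.2]
  tuning_width: 0.5
  fluorescence:
    kernel_tau: 0.7
    np_contamination: 0.3
    noise_sd: 0.3
figures: true
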