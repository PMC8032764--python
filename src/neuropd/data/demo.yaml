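# Demo pipeline run: all stages on synthetic data, scaled for a quick tour.
seed: 7
output_dir: neuropd_demo
stages: [synth, doseresponse, occupancy, pet, eeg]
conversion:
  molecular_weight: 445.469
  free_fraction_rat: 0.14
  free_fraction_human: 0.055
occupancy:
  region: hippocampus
  rescale_to_asymptote: true
pet:
  occupancy: 0.94
eeg:
  n_subjects: 6
  duration_s: 120
  n_perm: 1000
  effects:
    - {center_hz: 7.3, width_octaves: 0.5, change: 0.19}
    - {center_hz: 34.9, width_octaves: 0.5, change: -0.19}
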