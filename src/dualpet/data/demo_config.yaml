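# Demo run: two-patient dual-tracer phantom cohort at the study protocol.
cohort:
  n_patients: 2
  mean_lesions_per_patient: 6.25
grid:
  n: 96
  voxel_size_mm: 2.0
noise:
  kind: gaussian_sqrt
  scale: 4.0
protocol:
  dose1_MBq_per_kg: 0.5
  uptake1_min: 60.0
  scan1_duration_min: 10.0
  interval_after_scan1_min: 252.0
  dose2_MBq_per_kg: 3.0
  uptake2_min: 90.0
  scan2_duration_min: 5.0
scenarios: [R15, R20, decay]
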