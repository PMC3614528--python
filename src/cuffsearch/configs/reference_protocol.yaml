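# Search criteria of the reference in-vivo protocol: a 12-contact cuff
# (rows A-C x contacts I-IV), row-B main cathodes with same-index flanking
# grounds, one optional auxiliary row-B contact (cathodic/anodic steering or
# ground), and the published duration/amplitude/steering grids.  Enumerates
# 40 contact configurations and 768 (SPV, CEC) stimuli.
layout:
  rows: [A, B, C]
  contacts_per_row: 4
cec_constraints:
  main_cathodes: [BI, BII, BIII, BIV]
  ground_rule: flanking_same_index
  aux_roles: [none, cathodic_steer, anodic_steer, grounded]
  aux_positions: [BI, BII, BIII, BIV]
spv_grid:
  durations_us: [10, 20, 40]
  main_amplitudes_ua: [50, 100, 200, 400]
  steering_fractions: [0.5, 1.0]
  stimulus_type: monophasic_rectangular
routine:
  n_repetitions: 3
  min_inter_stimulus_delay_ms: 400
  variability_limit_pct: 10
  processing_allowance_ms: 667
search_defaults:
  tolerance_pct: 15
  min_significant_magnitude_mm: 0.5
  max_direction_deviation_deg: 60
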