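# Shipped pipeline defaults.  Every leaf carries a provenance tag:
#   reported               - value stated by the movement-capture /
#                            sonification model description
#   implementation-default - value this package chose (unstated upstream)
sampling:
  fs: {value: 100.0, provenance: reported}
fusion:
  beta: {value: 0.033, provenance: reported}
  stationary_window: {value: 10.0, provenance: reported}
  median_points: {value: 3, provenance: reported}
anthropometry:
  shank:
    L: {value: 0.246, provenance: implementation-default}
    D: {value: 0.567, provenance: implementation-default}
    w: {value: 0.093, provenance: implementation-default}
  thigh:
    L: {value: 0.245, provenance: implementation-default}
    D: {value: 0.567, provenance: implementation-default}
    w: {value: 0.200, provenance: implementation-default}
  hat:
    L: {value: 0.509, provenance: implementation-default}
    D: {value: 0.374, provenance: implementation-default}
    w: {value: 0.678, provenance: implementation-default}
posture:
  sit_shank: {value: 10.0, provenance: implementation-default}
  sit_thigh: {value: 90.0, provenance: implementation-default}
  sit_hat: {value: 5.0, provenance: implementation-default}
  stand_shank: {value: 0.0, provenance: implementation-default}
  stand_thigh: {value: 0.0, provenance: implementation-default}
  stand_hat: {value: 0.0, provenance: implementation-default}
features:
  freeze:
    lowpass_order: {value: 2, provenance: reported}
    lowpass_fc: {value: 7.0, provenance: reported}
    velocity_threshold: {value: 8.0, provenance: implementation-default}
    min_dwell: {value: 0.130, provenance: reported}
    rearm_fraction: {value: 0.5, provenance: implementation-default}
  jerk:
    jerk_threshold: {value: 20000.0, provenance: implementation-default}
    smoothing_fc: {value: 15.0, provenance: implementation-default}
  # CoM speed is smoothed prior to mapping (reported step; cutoff unstated)
  speed_smoothing_fc: {value: 2.0, provenance: implementation-default}
mapping:
  speed_hi: {value: 0.5, provenance: implementation-default}
  speed_lo: {value: 0.03, provenance: implementation-default}
  jerk_ceiling_factor: {value: 4.0, provenance: implementation-default}
  scale_tonic: {value: 440.0, provenance: reported}
  # transfer orders / polarities / ranges / smoothing cutoffs per mapping
  orders: {value: {S: 0.45, P: 0.75, F: 1.0, J: 0.45}, provenance: reported}
  smoothing_fc: {value: {S: 6.0, J: 19.0}, provenance: reported}
synthesis:
  sample_rate: {value: 48000, provenance: reported}
  bit_depth: {value: 24, provenance: reported}
  channels: {value: 2, provenance: reported}
  duration: {value: 8.0, provenance: reported}
combo:
  default: {value: SJPF, provenance: implementation-default}
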