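# Example cohort configuration: 10 subjects, V3-confined categorical
# delay-period match effect at amplitude 0.5 signal units.
seed: 42
n_subjects: 10
n_per_area: 32
noise_sd: 3.0
gain: 1.0
amp_s1: 1.0
amp_s2: 1.0
delay_match_amp: 0.0
delay_mismatch_amp: 0.0
delay_overrides:
  categorical:
    V3:
      match: 0.5
      mismatch: 0.0
subject_amp_sd: 0.05
accuracy:
  categorical: 0.97
  coordinate: 0.81
rt_mean_ms:
  categorical: 900.0
  coordinate: 1080.0
rt_sd_ms: 200.0
include_own_quadrant: false
use_ground_truth_segments: false
n_dct: 8
alpha: 0.05
write_bold: false
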