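# Default synthetic cohort calibration.
#
# target_suvr holds the group-mean windowed SUVR (40-70 min) and its
# between-animal SD that the generator is calibrated to reproduce, per
# target region and age group (months). Ground-truth DVRs are derived at
# run time by inverting the noiseless DVR -> windowed-SUVR map under the
# kinetics below; SUVR SDs map to DVR SDs through the local slope of the
# same curve. Baseline ratios slightly below 1 clamp to DVR = 1 (the
# reference region is devoid of specific binding).
group_labels: ["2", "4", "6", "8", "9", "11"]
n_per_group: 3
calibration_window_min: [40.0, 70.0]
kinetics:
  R1: 0.9
  k2: 0.10      # 1/min
  r1_sd: 0.10   # between-animal delivery spread (one draw per animal)
  k2_sd: 0.02   # between-animal efflux spread, 1/min
reference_model:
  amplitude: 100.0   # kBq/mL
  lambda_fast: 0.7   # 1/min
  lambda_slow: 0.005 # 1/min
noise_scale: 0.5
target_suvr:      # region -> group -> [mean, sd]
  CX:
    "2": [0.98, 0.01]
    "4": [1.13, 0.11]
    "6": [1.27, 0.07]
    "8": [1.37, 0.06]
    "9": [1.36, 0.05]
    "11": [1.35, 0.08]
  HIP:
    "2": [0.92, 0.01]
    "4": [1.10, 0.09]
    "6": [1.24, 0.12]
    "8": [1.32, 0.09]
    "9": [1.34, 0.16]
    "11": [1.39, 0.15]
  STR:
    "2": [0.97, 0.02]
    "4": [1.13, 0.09]
    "6": [1.34, 0.09]
    "8": [1.54, 0.07]
    "9": [1.53, 0.08]
    "11": [1.71, 0.05]
  MB:
    "2": [0.99, 0.02]
    "4": [0.99, 0.01]
    "6": [1.04, 0.03]
    "8": [1.06, 0.03]
    "9": [1.06, 0.06]
    "11": [1.21, 0.03]
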