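# Default evidence config: current-state AMI care-continuum chain.
# All values are probabilities in [0, 1].
evidence:
  nonseek_share: 0.45          # share of persons with AMI not seeking professional help
  selfmanage_share: 0.29       # share of non-seekers preferring self-management
  access_barrier_share: 0.275  # share citing affordability/access as the barrier
  access_success: 0.862        # probability a help-seeker receives care
  treatment_effectiveness: 0.80
  baseline_suicide: 0.014      # per-state per-step suicide probability
  target_ami_suicide: 0.065    # overall AMI suicide rate (calibration target)
model:
  row3_return: 0.100           # return to start after ineffective treatment
  row4_split_mode: exact-thirds
  rounding: published
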