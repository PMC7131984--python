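# Basic center-out session with the default synthetic mouse.
task:
  variant: center_out
  amp_threshold: 0.9
  reward_delay_ms: 1000
  iti_ms: 3000
  session_ms: 1800000   # 30 min
agent:
  reach_rate: 0.15      # spontaneous reaches / s
  amp_mean: 1.2         # cm
  amp_sd: 0.25
  jitter_sd: 0.02       # cm baseline noise
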