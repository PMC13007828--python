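# Full synthetic study: simulate -> detect -> rates -> statistics.
# Channels are generated as bipolar-equivalent traces (no montage step).
out_dir: runs/demo
seed: 7
simulate:
  n_subjects: {seizure: 12, healthy: 8}
  duration_s: 600.0
  n_channels: 8
  event_rate: {seizure: 0.16, healthy: 0.03}
detection: {}   # published defaults
stats:
  plan: [seizure_vs_healthy]
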