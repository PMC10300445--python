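# Working-memory length sweep on the uneven-density task.  Accuracy and
# single-sample inference latency are reported per memory length; the trend
# is informative, not asserted (latency is hardware-dependent).
task:
  kind: density
  n_samples: 512
  T: 32
  n_in: 16
  motif_len: 8
  jitter: 2
  noise_rate: 0.02

network:
  hidden: [32]
  mode: segment
  mem_len: 4
  tau: 2.0
  theta: 1.0
  fusion: true

training:
  epochs: 10
  batch_size: 32
  learning_rate: 1.0e-3
  optimizer: adam
  loss: cross_entropy

sweep: [1, 2, 4, 8]
seeds: [0, 1]
train_fraction: 0.8
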