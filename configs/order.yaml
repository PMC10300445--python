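# Motif-order discrimination: working-memory network vs. the defaults.
# Five repetitions with different random seeds; metrics are aggregated
# as mean +- sd over seeds.
task:
  kind: order
  n_samples: 2000
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
  epochs: 30
  batch_size: 32
  learning_rate: 1.0e-3
  optimizer: adam
  loss: cross_entropy

seeds: [0, 1, 2, 3, 4]
train_fraction: 0.8
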