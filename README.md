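# snnwm — spiking neural networks with working memory

`snnwm` is a NumPy library for building and training spiking neural networks
whose neurons integrate input over a *window* of time rather than a single
timestep.  It is aimed at researchers studying temporal credit assignment in
SNNs and at designers of neuromorphic accelerators who want a software model
of the working-memory dataflow and its resource costs.

## The model

The base neuron is the discrete-time leaky integrate-and-fire (LIF) unit

```
V_j(t) = e^{-1/τ} V_j(t-1) + Σ_i w_ij s_i(t),
s_j(t) = H(V_j(t) - θ),      H(0) = 1,
V_j(t) ← V_rest  wherever s_j(t) = 1   (hard reset),
```

whose temporal receptive field is limited to the recent past via the leak
`e^{-1/τ}`.  `snnwm` widens that field with **multi-delay dendrites**: each
pair of neurons is connected through `Nk` dendrite groups with integer
transmission delays `d_k`,

```
I_j(t) = Σ_k Σ_i w_ijk s_i(t − d_k).
```

The weight tensor is factorized as `w_ijk = w_k · w_ij` — a spatial matrix
(`Ni × Nj`) times a shared temporal vector (`Nk`) — cutting the parameter
count from `Ni·Nj·Nk` to `Ni·Nj + Nk`.  Three temporal regimes build on
this kernel:

- **overlap**: arithmetic delays `{0,…,L−1}`, realized as a causal 1-D
  convolution in time — every step sees the last `L` steps;
- **segment** (non-overlapping working memory): the train is cut into
  windows of length `mem_len`; all spikes of a window are aggregated once
  and fed to the neuron as a constant drive for the whole window, which
  *rectifies* spike timing inside the window;
- **temporal fusion**: the decoding layer weights spikes from *every*
  timestep (`o_j = Σ_t w_t Σ_i w_ij s_i(t)`) and emits one output vector
  per sample — a global, leak-free readout.

Training is backpropagation through the unrolled dynamics (both layer and
time paths), with the exponential surrogate `∂H/∂x = e^{−2x²}` standing in
for the threshold derivative.  All gradients are hand-derived closed forms;
the test suite verifies them against an independent reverse-mode autodiff
oracle to 1e-6.

The package also ships spike encoders (direct / Poisson-rate / latency),
synthetic motif-order and spike-density tasks whose solution *requires*
global temporal information, and closed-form cost models for parameter
counts and membrane-state memory traffic (`2T` accesses per neuron classic
vs `2⌈T/mem_len⌉` under working memory).

## Worked example

Train a one-hidden-layer working-memory network on the motif-order task —
two fixed spatiotemporal motifs presented in either order, with identical
marginal spike statistics in both classes — and compare it with a classic
SNN whose readout counts spikes:

```python
import numpy as np
from snnwm import (TaskSpec, TrainingConfig, init_network, make_order_task,
                   split_dataset, train)

spec = TaskSpec(kind="order", seed=0)      # n=2000 samples, T=32, 16 neurons
data = make_order_task(spec)
tr, te = split_dataset(data, (0.8, 0.2), seed=0)
cfg = TrainingConfig(epochs=30, seed=0)

wm = init_network(16, [32], 2, T=32, mode="segment", mem_len=4, seed=0)
_, hist = train(wm, (tr, te), cfg)
print("working memory + fusion:", hist.test_accuracy[-1])

base = init_network(16, [32], 2, T=32, mode="classic", seed=0, fusion=False)
_, hist = train(base, (tr, te), cfg)
print("classic + spike count:  ", hist.test_accuracy[-1])
```

prints

```
working memory + fusion: 1.0
classic + spike count:   0.4925
```

The working-memory network separates the two motif orders perfectly, while
the time-blind baseline stays at chance — the classes are indistinguishable
by spike counts alone, by construction.

The same experiments are available from the shell:

```sh
snnwm train configs/order.yaml --out runs/order
snnwm sweep configs/density_sweep.yaml --out runs/sweep
snnwm count --ni 4 --nj 3 --nk 5 --t 16 --mem-len 4
```

The last command prints the cost accounting for one layer: 60 dense vs 17
factorized parameters, and a 4× reduction in membrane-state memory accesses.

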