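# Methods

## Neuron model

All dynamics are discrete-time with 0-indexed steps `t = 0 … T−1`.  The LIF
membrane update is

    V(t) = λ V(t−1) + I(t),        λ = e^{−1/τ},

with a spike emitted when `V(t) ≥ θ` (Heaviside convention `H(0) = 1`) and a
hard reset to `V_rest` applied at the spiking step itself.  The spike
response kernel is the identity (`K(s) = s`): a presynaptic spike contributes
its synaptic weight to the drive with no postsynaptic-potential shape.  The
initial membrane state is `V_rest`.  `τ = ∞` (λ = 1) gives the non-leaky
integrate-and-fire unit.  There are no refractory periods, adaptive
thresholds, or trainable time constants.

Spikes at negative times are zero (causal zero padding), so a delay tap
larger than the elapsed time contributes nothing.

## Temporal regimes

A layer's drive is computed from a factorized delay kernel: a spatial matrix
`W1` (Ni × Nj) and a temporal tap vector `w2` (length Nk) with integer
delays `d_k`, equivalent to the rank-1 tensor `w_ijk = w2[k]·W1[i,j]`.  The
dense-tensor drive is retained as a brute-force oracle; the factorized path
computes the spatial projection `P = S·W1` once and then applies the taps,
which for arithmetic delays `{0,…,L−1}` is a causal 1-D convolution in time.

- **classic**: delays `{0}`, single fixed unit tap — exactly the baseline
  LIF layer.  The tap is excluded from training so the baseline stays the
  baseline.
- **overlap**: taps over the last `L` steps; outputs at time `t` depend only
  on inputs up to `t` (causality is a tested invariant).
- **segment**: non-overlapping windows of length `mem_len`.  Window `m`
  covers steps `mL … mL+L−1`; its drive is `Σ_p w2[p]·P[mL+p]`, constant
  throughout the window.  The temporal taps are indexed by within-window
  position `p` in ascending time (equivalently, delays `L−1−p` referenced to
  the window end); this convention removes the sign ambiguity between
  "delay" and "position".  With uniform taps the drive — and, given the
  window-entry membrane state, everything downstream — is invariant to
  any permutation of spike times inside a window ("rectification").
  In strict mode `T` must be divisible by `mem_len`; an explicit
  `pad_final_window` flag zero-pads the last short window instead, off by
  default because padding silently changes drive magnitude.
- **fusion head**: a static readout `o_j = Σ_t w_time[t]·Σ_i W1[i,j]·s_i(t)`
  over all `T` steps, emitted once per sample as the logits.  No leak and no
  threshold are applied at this layer.  The head has exactly `T` temporal
  taps, one per timestep.  Freezing `w_time` at the uniform value `1/T`
  degrades the head to a mean-spike-count readout, which serves as the
  time-blind baseline.

## Training

Optimization is backpropagation through the unrolled dynamics over both the
layer and the time dimension.  The forward pass uses the exact hard
threshold; the backward pass substitutes the exponential surrogate
`∂H/∂x = e^{−2x²}` (maximum 1 at threshold, strictly positive everywhere) at
every spike.  Gradients flow through the reset product
`V(t)(1−s(t)) + V_rest·s(t)` by default; a `detach_reset` flag severs the
reset path, since both conventions are common.  All backward formulas are
hand-derived; the suite checks them against an independent tape-based
reverse-mode oracle on random small networks of every regime, with both
reset conventions and both losses, to 1e-6 (observed agreement is at
machine precision).

Defaults are desk-scale: Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-3,
batch 32, cross-entropy on the fusion logits (MSE against one-hot targets
available).  Spatial weights initialize Glorot-uniform; temporal taps start
at the window-averaging value `1/Nk`, so all regimes produce comparable
drive magnitudes at initialization; the head's taps start at `1/T`.  Larger
published-scale presets (SGD momentum / Adam, lr 1e-1 / 1e-3, 200–300
epochs) are shipped as a named preset for reference but are not the
defaults.  Training is fully deterministic given the config seed.

## Synthetic tasks

The generators produce the simplest data whose correct classification
requires exactly what working memory adds.

- **Order task**: two binary motifs (30% spike density, drawn once per
  seed and shared by all samples) are placed one per half-train, centred and
  jittered by up to ±2 steps; the label encodes their order.  Both classes
  therefore have identical per-neuron marginal spike-count distributions
  (verified by a two-sample KS test at n = 2000), so a readout blind to
  spike timing cannot systematically beat chance.
- **Density task**: the class-specific motif occupies exactly one uniformly
  chosen aligned window; classes differ only in which motif appears.
- Background activity is independent Bernoulli noise (default 2% per
  neuron-step) OR-ed over the motifs.

Defaults: 2000 samples, T = 32, 16 input neurons, 8-step motifs, jitter 2,
sized so that a full 30-epoch, 5-seed comparison runs in well under a minute
per configuration on one CPU core.

What the generators do *not* emulate: realistic image or event-camera
statistics, spatial correlation structure, class imbalance, or
sensor noise.  Passing results demonstrate the temporal-integration
mechanism, not performance on natural data.

## Cost models

Parameter counts: `Ni·Nj·Nk` dense vs `Ni·Nj + Nk` factorized (exact
integer identities; note the counts tie at the degenerate point
`Ni·Nj = Nk = 2`).  Membrane-state memory traffic per layer, neuron group
and sample: the classic schedule fetches and stores state every step
(`2T`); the working-memory schedule touches it only at window boundaries
(`2⌈T/mem_len⌉`), a reduction of exactly `mem_len` when `mem_len | T`.
Both formulas are cross-checked by an instrumented simulation that counts
actual fetch/store events and confirms the scheduling change leaves the
dynamics bit-identical.  Input/output spike traffic is the same under both
schedules and is excluded; weight-memory traffic is not modelled.

## Numerical and design choices

- Threshold comparison is `≥` so that drive exactly at threshold fires.
- Time-to-first-spike (latency) encoding maps value `v > 0` to
  `t = round((1−v)(T−1))`; `v = 0` emits no spike rather than the
  latest-possible one, since a zero-intensity input should inject nothing.
- Rate coding uses independent per-step Bernoulli draws with `p = value`,
  the standard discrete-time realization of Poisson rate coding.
- Drive, window and fusion computations are linear in the input train;
  superposition holds to 1e-12 and is property-tested.
- Equality comparisons between the factorized and dense drive paths are
  exact up to accumulation order (observed ≤ 1e-15 on random instances,
  asserted < 1e-10).
- Wall-clock quantities (single-sample inference latency in sweeps) are
  always reported and never asserted.

## Limitations

- Dense layers only; no convolutional or residual stacks, so results on
  natural image/event benchmarks are out of reach of this package.
- No trainable per-synapse delays, recurrence, attention, or
  segment-level truncated BPTT.
- CPU NumPy only: practical for thousands of samples and tens of
  timesteps, not for large-scale training.
- The hardware access model counts memory events; it is not a
  cycle-accurate or energy model.
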