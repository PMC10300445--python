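"""Synaptic drive under multi-delay dendrites and working-memory windowing.

A layer connects ``Ni`` presynaptic to ``Nj`` postsynaptic neurons through
``Nk`` dendrite groups, group ``k`` carrying its own integer transmission
delay ``d_k``.  The dense drive is

    I_j(t) = sum_k sum_i w_ijk * s_i(t - d_k)

with spikes at negative times equal to zero.  Factorizing the weight tensor
``w_ijk`` into a spatial matrix ``W1`` (Ni x Nj) and a shared temporal vector
``w2`` (length Nk) cuts the parameter count from Ni*Nj*Nk to Ni*Nj + Nk and
turns the drive into a spatial projection followed by a causal 1-D
convolution in time.

Four temporal regimes are supported:

``classic``
    Single synapse, delay 0 — the baseline SNN drive.
``overlap``
    Overlapping working memory: each step sees the last ``Nk`` steps through
    the delay taps (causal convolution).
``segment``
    Non-overlapping working memory: time is cut into windows of length
    ``mem_len``; all spikes inside a window are aggregated once and the
    resulting drive is fed back constantly for the whole window.  Spike
    timing *within* a window is thereby rectified away.
``fusion``
    A static readout over the entire train, used as the decoding layer: one
    output vector per sample, no leak, no threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_neuron import (
    CurrentTrace,
    LIFParams,
    MembraneTrace,
    SpikeTrain,
    lif_run,
)

__all__ = [
    "DenseDelayKernel",
    "FactorizedDelayKernel",
    "WorkingMemoryConfig",
    "FusionHead",
    "LayerSpec",
    "NetworkSpec",
    "dense_delay_drive",
    "factorized_delay_drive",
    "segment_drive",
    "temporal_fusion",
    "layer_forward",
]

Mode = Literal["classic", "overlap", "segment", "fusion"]


def _check_delays(delays: np.ndarray) -> np.ndarray:
    delays = np.asarray(delays, dtype=np.int64)
    if delays.ndim != 1 or delays.size == 0:
        raise ValueError("delays must be a nonempty 1-D integer vector")
    if (delays < 0).any():
        raise ValueError("delays must be nonnegative")
    if (np.diff(delays) <= 0).any():
        raise ValueError("delays must be sorted ascending without duplicates")
    return delays


@dataclass(frozen=True)
class DenseDelayKernel:
    """Full Ni x Nj x Nk delay-weight tensor with per-group delays.

    Serves as the brute-force reference for the factorized kernel; the
    factorized path must agree with it exactly on rank-1 tensors
    ``w_ijk = w2[k] * W1[i, j]``.
    """

    W: np.ndarray
    delays: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 3:
            raise ValueError(f"dense kernel must be 3-D (Ni x Nj x Nk), got {W.shape}")
        delays = _check_delays(self.delays)
        if W.shape[2] != delays.size:
            raise ValueError(
                f"kernel has {W.shape[2]} dendrite groups but {delays.size} delays"
            )
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "delays", delays)

    @property
    def n_params(self) -> int:
        return self.W.size


@dataclass(frozen=True)
class FactorizedDelayKernel:
    """Rank-1 factorization of the delay-weight tensor.

    ``W1`` is the Ni x Nj spatial weight matrix, ``w2`` the length-Nk
    temporal weight vector shared across all synapses; the implied tensor is
    ``w_ijk = w2[k] * W1[i, j]``.  Stores exactly Ni*Nj + Nk parameters.
    """

    W1: np.ndarray
    w2: np.ndarray
    delays: np.ndarray

    def __post_init__(self) -> None:
        W1 = np.asarray(self.W1, dtype=np.float64)
        w2 = np.asarray(self.w2, dtype=np.float64)
        if W1.ndim != 2:
            raise ValueError(f"W1 must be 2-D (Ni x Nj), got shape {W1.shape}")
        if w2.ndim != 1:
            raise ValueError(f"w2 must be 1-D, got shape {w2.shape}")
        delays = _check_delays(self.delays)
        if w2.size != delays.size:
            raise ValueError(
                f"w2 has {w2.size} taps but there are {delays.size} delays"
            )
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "delays", delays)

    @property
    def n_params(self) -> int:
        return self.W1.size + self.w2.size

    def to_dense(self) -> DenseDelayKernel:
        """Expand to the equivalent dense tensor (for oracle checks)."""
        W = self.W1[:, :, None] * self.w2[None, None, :]
        return DenseDelayKernel(W=W, delays=self.delays)

    @classmethod
    def classic(cls, W1: np.ndarray) -> "FactorizedDelayKernel":
        """Single-synapse kernel: delays {0}, w2 {1} — the baseline drive."""
        return cls(W1=W1, w2=np.ones(1), delays=np.zeros(1, dtype=np.int64))


@dataclass(frozen=True)
class WorkingMemoryConfig:
    """Selects the temporal regime of a layer.

    ``mem_len`` (the working-memory length L) is required in segment mode,
    where the window index at step t is ``floor(t / mem_len)``.  In strict
    mode T must be divisible by mem_len; with ``pad_final_window`` the last
    short window is zero-padded instead.
    """

    mode: Mode = "classic"
    mem_len: int = 1
    pad_final_window: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("classic", "overlap", "segment", "fusion"):
            raise ValueError(f"unknown working-memory mode {self.mode!r}")
        if self.mem_len < 1:
            raise ValueError("mem_len must be >= 1")


def dense_delay_drive(S: SpikeTrain, kernel: DenseDelayKernel) -> CurrentTrace:
    """Drive from the full delay tensor: I[t, j] = sum_k sum_i W[i,j,k] s_i(t - d_k).

    Brute-force path kept as the oracle for the factorized implementation.
    """
    s = S.data
    T, Ni = s.shape
    if kernel.W.shape[0] != Ni:
        raise ValueError(
            f"kernel expects {kernel.W.shape[0]} input neurons, train has {Ni}"
        )
    Nj = kernel.W.shape[1]
    I = np.zeros((T, Nj))
    for k, d in enumerate(kernel.delays):
        if d >= T:
            continue
        # s_i(t - d) = 0 for t < d (causal zero padding)
        shifted = np.zeros_like(s)
        shifted[d:] = s[: T - d]
        I += shifted @ kernel.W[:, :, k]
    return CurrentTrace(I)


def factorized_delay_drive(
    S: SpikeTrain, kernel: FactorizedDelayKernel
) -> CurrentTrace:
    """Factorized drive: spatial projection, then causal temporal taps.

    I[t, j] = sum_k w2[k] * sum_i W1[i, j] * s_i(t - d_k).  Identical to
    :func:`dense_delay_drive` on the rank-1 tensor w2[k] * W1[i, j].
    """
    s = S.data
    T, Ni = s.shape
    if kernel.W1.shape[0] != Ni:
        raise ValueError(
            f"kernel expects {kernel.W1.shape[0]} input neurons, train has {Ni}"
        )
    P = s @ kernel.W1  # T x Nj spatial projection
    I = np.zeros_like(P)
    for wk, d in zip(kernel.w2, kernel.delays):
        if d >= T:
            continue
        I[d:] += wk * P[: T - d]
    return CurrentTrace(I)


def _window_starts(T: int, mem_len: int, pad: bool) -> range:
    if mem_len > T:
        raise ValueError(f"mem_len {mem_len} exceeds train length {T}")
    if T % mem_len and not pad:
        raise ValueError(
            f"train length {T} is not divisible by mem_len {mem_len}; "
            "enable pad_final_window to zero-pad the last window"
        )
    return range(0, T, mem_len)


def segment_drive(
    S: SpikeTrain,
    kernel: FactorizedDelayKernel,
    mem_len: int,
    pad_final_window: bool = False,
) -> CurrentTrace:
    """Non-overlapping working-memory drive.

    Time is divided into windows of length ``mem_len``.  Within window m
    (steps mL .. mL+L-1) the drive is the constant

        drive_m[j] = sum_p w2[p] * sum_i W1[i, j] * s_i(mL + p)

    where p indexes within-window position in ascending time.  All spikes of
    the window are aggregated once and fed to the neuron throughout the
    window, so spike timing inside a window is not informative (with uniform
    w2, the drive is invariant to any within-window permutation).
    """
    if kernel.w2.size != mem_len:
        raise ValueError(
            f"segment mode needs one temporal tap per window position: "
            f"w2 has {kernel.w2.size} taps, mem_len is {mem_len}"
        )
    s = S.data
    T, Ni = s.shape
    if kernel.W1.shape[0] != Ni:
        raise ValueError(
            f"kernel expects {kernel.W1.shape[0]} input neurons, train has {Ni}"
        )
    P = s @ kernel.W1  # T x Nj
    Nj = P.shape[1]
    I = np.empty((T, Nj))
    for start in _window_starts(T, mem_len, pad_final_window):
        stop = min(start + mem_len, T)
        w = kernel.w2[: stop - start]
        drive_m = w @ P[start:stop]  # length-Nj constant for the window
        I[start:stop] = drive_m
    return CurrentTrace(I)


@dataclass(frozen=True)
class FusionHead:
    """Temporal fusion decoding layer.

    A static readout over the whole input train of fixed length T:

        o_j = sum_t w_time[t] * sum_i W1[i, j] * s_i(t)

    Every timestep is weighted by one tap of ``w_time``; the readout is
    emitted once per sample (logits), with no leak and no threshold.  A
    ``trainable_time`` = False head with uniform taps degrades to a plain
    spike-count readout.
    """

    W1: np.ndarray
    w_time: np.ndarray
    trainable_time: bool = True

    def __post_init__(self) -> None:
        W1 = np.asarray(self.W1, dtype=np.float64)
        w_time = np.asarray(self.w_time, dtype=np.float64)
        if W1.ndim != 2:
            raise ValueError(f"W1 must be 2-D (Ni x Nj), got shape {W1.shape}")
        if w_time.ndim != 1:
            raise ValueError("w_time must be 1-D")
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "w_time", w_time)

    @property
    def T(self) -> int:
        return self.w_time.size


def temporal_fusion(S: SpikeTrain, head: FusionHead) -> np.ndarray:
    """Apply the fusion readout: o = w_time @ (S @ W1), length Nj."""
    if S.T != head.T:
        raise ValueError(
            f"fusion head expects T={head.T} timesteps, train has {S.T}"
        )
    if S.N != head.W1.shape[0]:
        raise ValueError(
            f"fusion head expects {head.W1.shape[0]} input neurons, train has {S.N}"
        )
    return head.w_time @ (S.data @ head.W1)


@dataclass(frozen=True)
class LayerSpec:
    """One hidden layer: a factorized delay kernel, a temporal regime, and
    the LIF parameters its output neurons use."""

    kernel: FactorizedDelayKernel
    lif: LIFParams = field(default_factory=LIFParams)
    wm: WorkingMemoryConfig = field(default_factory=WorkingMemoryConfig)

    def __post_init__(self) -> None:
        if self.wm.mode == "classic":
            if self.kernel.w2.size != 1 or self.kernel.delays[0] != 0:
                raise ValueError(
                    "classic mode requires delays {0} and a single temporal tap"
                )
        if self.wm.mode == "segment" and self.kernel.w2.size != self.wm.mem_len:
            raise ValueError(
                f"segment mode: w2 must have mem_len={self.wm.mem_len} taps, "
                f"got {self.kernel.w2.size}"
            )
        if self.wm.mode == "fusion":
            raise ValueError("fusion is a head, not a hidden-layer mode")

    @property
    def n_in(self) -> int:
        return self.kernel.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.kernel.W1.shape[1]


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered stack of spiking layers topped by a fusion (or count) readout.

    All layers of a stack share one delay-set convention; adjacent layer
    widths must match, and the head width must match the last layer.
    """

    layers: tuple[LayerSpec, ...]
    head: FusionHead

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        for a, b in zip(layers, layers[1:]):
            if a.n_out != b.n_in:
                raise ValueError(
                    f"adjacent layer widths differ: {a.n_out} -> {b.n_in}"
                )
        if layers and layers[-1].n_out != self.head.W1.shape[0]:
            raise ValueError(
                f"head expects {self.head.W1.shape[0]} inputs, last layer "
                f"emits {layers[-1].n_out}"
            )
        object.__setattr__(self, "layers", layers)


def layer_drive(S: SpikeTrain, spec: LayerSpec) -> CurrentTrace:
    """Dispatch to the drive computation matching the layer's regime."""
    mode = spec.wm.mode
    if mode == "classic" or mode == "overlap":
        return factorized_delay_drive(S, spec.kernel)
    if mode == "segment":
        return segment_drive(
            S, spec.kernel, spec.wm.mem_len, spec.wm.pad_final_window
        )
    raise ValueError(f"unknown working-memory mode {mode!r}")


def layer_forward(
    S: SpikeTrain, spec: LayerSpec, V0: np.ndarray | None = None
) -> MembraneTrace:
    """Drive computation followed by the LIF recurrence.

    Classic mode (delays {0}, single unit tap) reproduces the baseline SNN
    layer exactly.
    """
    return lif_run(layer_drive(S, spec), spec.lif, V0)
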