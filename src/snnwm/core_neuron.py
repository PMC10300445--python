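"""Discrete-time leaky integrate-and-fire (LIF) dynamics.

The membrane potential of neuron ``j`` evolves as

    V_j(t) = exp(-1/tau) * V_j(t-1) + I_j(t)

where ``I_j(t)`` is the summed synaptic drive at step ``t``.  When the
potential reaches the threshold ``theta`` (comparison is ``>=``, i.e. the
Heaviside convention H(0) = 1) the neuron emits a spike and the potential is
hard-reset to the resting value ``v_rest``.  Setting the leak factor to 1
recovers the non-leaky integrate-and-fire (I&F) neuron.

Time is 0-indexed throughout: a trace of length ``T`` covers steps
``t = 0 .. T-1`` and spikes at negative times are identically zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "SpikeTrain",
    "CurrentTrace",
    "MembraneTrace",
    "leak_factor",
    "lif_step",
    "lif_run",
]


def leak_factor(tau: float) -> float:
    """Membrane decay coefficient ``exp(-1/tau)`` for time constant ``tau``.

    Parameters
    ----------
    tau
        Membrane time constant in units of simulation timesteps.  Must be
        positive; ``tau = inf`` gives a leak of exactly 1 (pure integrator).

    Returns
    -------
    float
        Decay factor in ``(0, 1]``.
    """
    if not tau > 0:
        raise ValueError(f"membrane time constant must be positive, got {tau!r}")
    return math.exp(-1.0 / tau)


@dataclass(frozen=True)
class LIFParams:
    """Parameters of a discrete-time LIF neuron.

    Attributes
    ----------
    tau
        Membrane time constant (timesteps, > 0).  The derived leak factor is
        ``exp(-1/tau)``.
    theta
        Firing threshold.
    v_rest
        Resting potential the membrane is reset to after a spike.
    """

    tau: float = 2.0
    theta: float = 1.0
    v_rest: float = 0.0
    #: Decay factor exp(-1/tau); derived, do not set.
    leak: float = field(init=False)

    # The spike response kernel is fixed to the identity K(s) = s: presynaptic
    # spikes contribute their weight directly to the drive, with no PSP shape.

    def __post_init__(self) -> None:
        object.__setattr__(self, "leak", leak_factor(self.tau))


def _as_2d(data: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(data)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (T x N), got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have T >= 1 and N >= 1, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class SpikeTrain:
    """Binary spike raster, time-major: ``data[t, i]`` is 1 iff neuron ``i``
    fires at step ``t``."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.data, "spike train")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("spike train entries must be 0 or 1")
        object.__setattr__(self, "data", arr.astype(np.float64))

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CurrentTrace:
    """Real-valued synaptic drive entering the membrane update, shape T x N."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_2d(self.data, "current trace").astype(np.float64)
        if not np.isfinite(arr).all():
            raise ValueError("current trace entries must be finite")
        object.__setattr__(self, "data", arr)

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MembraneTrace:
    """Post-reset membrane potentials and the emitted spikes, both T x N.

    Wherever ``spikes`` is 1 the recorded potential equals ``v_rest`` (hard
    reset applied at the spiking step itself).
    """

    V: np.ndarray
    spikes: SpikeTrain

    def __post_init__(self) -> None:
        if self.V.shape != self.spikes.data.shape:
            raise ValueError("membrane and spike records must have equal shape")


def lif_step(
    V_prev: np.ndarray, I_t: np.ndarray, params: LIFParams
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the membrane one timestep.

    Computes ``V_mid = leak * V_prev + I_t``, emits ``spikes = H(V_mid -
    theta)`` with ``H(0) = 1``, and hard-resets spiking entries to
    ``v_rest``.

    Returns
    -------
    (V_new, spikes)
        Post-reset potentials and the binary spike vector, same shape as
        the inputs.
    """
    V_prev = np.asarray(V_prev, dtype=np.float64)
    I_t = np.asarray(I_t, dtype=np.float64)
    if V_prev.shape != I_t.shape:
        raise ValueError(
            f"membrane state {V_prev.shape} and drive {I_t.shape} shapes differ"
        )
    V_mid = params.leak * V_prev + I_t
    spikes = (V_mid >= params.theta).astype(np.float64)
    V_new = V_mid * (1.0 - spikes) + params.v_rest * spikes
    return V_new, spikes


def lif_run(
    drive: CurrentTrace, params: LIFParams, V0: np.ndarray | None = None
) -> MembraneTrace:
    """Run the LIF recurrence over a full drive trace.

    Parameters
    ----------
    drive
        T x N synaptic drive.
    params
        Neuron parameters shared by all N neurons.
    V0
        Initial membrane state (length N); defaults to ``v_rest``.
    """
    I = drive.data
    T, N = I.shape
    if V0 is None:
        V = np.full(N, params.v_rest, dtype=np.float64)
    else:
        V = np.asarray(V0, dtype=np.float64).copy()
        if V.shape != (N,):
            raise ValueError(f"V0 must have length {N}, got shape {V.shape}")
    V_rec = np.empty((T, N))
    s_rec = np.empty((T, N))
    for t in range(T):
        V, s = lif_step(V, I[t], params)
        V_rec[t] = V
        s_rec[t] = s
    return MembraneTrace(V=V_rec, spikes=SpikeTrain(s_rec))
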