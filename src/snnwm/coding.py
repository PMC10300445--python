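"""Spike encoders and spike-train serialization.

Three encoders for static real-valued inputs in [0, 1]:

- **direct**: the value is injected unchanged as input current at every
  timestep (no spikes; the first layer integrates an analog drive);
- **rate**: per-step Bernoulli spiking with probability equal to the value —
  the standard discrete-time realization of Poisson rate coding;
- **latency**: a single spike whose timing encodes the value linearly,
  strongest input firing first; a zero value emits no spike.

Also provides the compact bit-string notation for single-neuron trains
(``"010110"`` = spikes at t = 1, 3, 4) and a plain-text event-list CSV
format for spike rasters.
"""

from __future__ import annotations

import numpy as np

from .core_neuron import CurrentTrace, SpikeTrain

__all__ = [
    "direct_encode",
    "rate_encode",
    "latency_encode",
    "parse_bitstring",
    "format_bitstring",
    "read_events",
    "write_events",
]


def _check_unit_interval(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError(f"values must be a 1-D vector, got shape {values.shape}")
    if (values < 0).any() or (values > 1).any():
        raise ValueError("encoder inputs must lie in [0, 1]; normalize upstream")
    return values


def direct_encode(values: np.ndarray, T: int) -> CurrentTrace:
    """Constant-current coding: row t equals ``values`` for every t < T."""
    values = _check_unit_interval(values)
    if T < 1:
        raise ValueError("T must be >= 1")
    return CurrentTrace(np.tile(values, (T, 1)))


def rate_encode(values: np.ndarray, T: int, seed: int) -> SpikeTrain:
    """Poisson-style rate coding via independent per-step Bernoulli draws.

    Each neuron spikes at each step with probability equal to its value, so
    the empirical firing rate converges to the value as T grows.
    Reproducible for a fixed seed.
    """
    values = _check_unit_interval(values)
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    spikes = (rng.random((T, values.size)) < values).astype(np.float64)
    return SpikeTrain(spikes)


def latency_encode(values: np.ndarray, T: int) -> SpikeTrain:
    """Time-to-first-spike coding: one spike at ``round((1 - v) * (T - 1))``.

    Larger values fire earlier (v = 1 at t = 0); v = 0 emits no spike at
    all, so a dark pixel injects nothing rather than the latest-possible
    event.  Timing is monotone: v1 > v2 > 0 implies t(v1) <= t(v2).
    """
    values = _check_unit_interval(values)
    if T < 2:
        raise ValueError("latency coding needs T >= 2")
    spikes = np.zeros((T, values.size))
    active = values > 0
    times = np.rint((1.0 - values[active]) * (T - 1)).astype(np.int64)
    spikes[times, np.flatnonzero(active)] = 1.0
    return SpikeTrain(spikes)


def parse_bitstring(bits: str) -> SpikeTrain:
    """Parse a single-neuron train written as a 0/1 string.

    ``"010110"`` is a train of duration 6 with spikes at t = 1, 3, 4
    (0-indexed positions of the '1' characters).
    """
    if not bits:
        raise ValueError("bit string must be nonempty")
    bad = set(bits) - {"0", "1"}
    if bad:
        raise ValueError(f"bit string may contain only 0/1, found {sorted(bad)}")
    data = np.fromiter((c == "1" for c in bits), dtype=np.float64, count=len(bits))
    return SpikeTrain(data[:, None])


def format_bitstring(S: SpikeTrain) -> str:
    """Inverse of :func:`parse_bitstring` for single-neuron trains."""
    if S.N != 1:
        raise ValueError(f"bit-string notation is single-neuron; train has N={S.N}")
    return "".join("1" if v else "0" for v in S.data[:, 0])


def write_events(S: SpikeTrain, path) -> None:
    """Write a spike raster as an event-list CSV.

    Format: a comment line ``# T=<int> N=<int>`` declaring the raster shape,
    a header ``t,neuron``, then one row per spike event sorted time-major.
    Lossless together with :func:`read_events`.
    """
    ts, ns = np.nonzero(S.data)
    with open(path, "w") as fh:
        fh.write(f"# T={S.T} N={S.N}\n")
        fh.write("t,neuron\n")
        for t, n in zip(ts, ns):
            fh.write(f"{t},{n}\n")


def read_events(path) -> SpikeTrain:
    """Read an event-list CSV written by :func:`write_events`.

    An optional third ``polarity`` column is accepted and ignored.  Events
    outside the declared T x N bounds, duplicate events, and malformed rows
    are rejected with the offending line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '# T=<int> N=<int>' header comment")
    try:
        fields = dict(part.split("=") for part in lines[0].lstrip("# ").split())
        T, N = int(fields["T"]), int(fields["N"])
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{path}: malformed shape declaration: {lines[0]!r}") from exc
    if len(lines) < 2 or lines[1].split(",")[:2] != ["t", "neuron"]:
        raise ValueError(f"{path}: line 2 must be the 't,neuron[,polarity]' header")
    data = np.zeros((T, N))
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2-3 fields, got {len(parts)}")
        try:
            t, n = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer event indices") from exc
        if not (0 <= t < T) or not (0 <= n < N):
            raise ValueError(
                f"{path}:{lineno}: event ({t}, {n}) outside declared T={T} N={N}"
            )
        if data[t, n]:
            raise ValueError(f"{path}:{lineno}: duplicate event ({t}, {n})")
        data[t, n] = 1.0
    return SpikeTrain(data)
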