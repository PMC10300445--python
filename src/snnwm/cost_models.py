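"""Closed-form resource accounting for factorized kernels and working memory.

Two efficiency claims are modelled:

- **parameters**: the dense delay tensor holds Ni*Nj*Nk weights; the
  factorized kernel holds Ni*Nj + Nk — only Nk more than a single-synapse
  layer.
- **membrane-state memory traffic**: a classic LIF layer fetches and stores
  its membrane state once per timestep (2*T accesses per neuron group per
  sample).  Under non-overlapping working memory the state is fetched at the
  start and stored at the end of each window only, giving 2*ceil(T/mem_len)
  accesses.  Input/output spike traffic is identical in both schemes and is
  excluded.

Weight-memory traffic is not modelled.  Counts are per layer, per neuron
group, per sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

__all__ = ["CostReport", "parameter_count", "state_memory_accesses", "cost_report"]


def parameter_count(Ni: int, Nj: int, Nk: int, factorized: bool) -> int:
    """Weight count of a delay layer: Ni*Nj*Nk dense, Ni*Nj + Nk factorized."""
    if Ni < 1 or Nj < 1 or Nk < 1:
        raise ValueError("layer dimensions must be positive")
    return Ni * Nj + Nk if factorized else Ni * Nj * Nk


def state_memory_accesses(T: int, mem_len: int, scheme: str) -> int:
    """Membrane-state fetch+store count over a T-step run.

    ``classic`` touches state every step (2*T); ``wm`` touches it only at
    window boundaries (2*ceil(T/mem_len)).  With mem_len dividing T the
    reduction factor is exactly mem_len.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 1 <= mem_len <= T:
        raise ValueError(f"mem_len must be in [1, T={T}], got {mem_len}")
    if scheme == "classic":
        return 2 * T
    if scheme == "wm":
        return 2 * math.ceil(T / mem_len)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class CostReport:
    """Side-by-side accounting for one layer configuration."""

    dense_params: int
    factorized_params: int
    classic_state_accesses: int
    wm_state_accesses: int

    @property
    def access_reduction_factor(self) -> float:
        return self.classic_state_accesses / self.wm_state_accesses

    @property
    def param_reduction_factor(self) -> float:
        return self.dense_params / self.factorized_params

    def to_json(self) -> str:
        d = asdict(self)
        d["access_reduction_factor"] = self.access_reduction_factor
        d["param_reduction_factor"] = self.param_reduction_factor
        return json.dumps(d, indent=2)


def cost_report(Ni: int, Nj: int, Nk: int, T: int, mem_len: int) -> CostReport:
    """Full report for a layer of Ni x Nj synapses with Nk delay taps run
    for T steps under working-memory length mem_len."""
    return CostReport(
        dense_params=parameter_count(Ni, Nj, Nk, factorized=False),
        factorized_params=parameter_count(Ni, Nj, Nk, factorized=True),
        classic_state_accesses=state_memory_accesses(T, mem_len, "classic"),
        wm_state_accesses=state_memory_accesses(T, mem_len, "wm"),
    )


class AccessCountingState:
    """Instrumented membrane-state store for cross-checking the formulas.

    Simulates the hardware dataflow: ``fetch`` at the start and ``store`` at
    the end of each scheduling unit (one timestep classically; one window
    under working memory).  The counts must reproduce
    :func:`state_memory_accesses` exactly.
    """

    def __init__(self, V0):
        self._V = V0
        self.fetches = 0
        self.stores = 0

    def fetch(self):
        self.fetches += 1
        return self._V

    def store(self, V) -> None:
        self.stores += 1
        self._V = V

    @property
    def accesses(self) -> int:
        return self.fetches + self.stores
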