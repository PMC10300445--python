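"""HDF5 checkpointing of network weights.

Layout: ``/layers/<idx>/W1``, ``/layers/<idx>/w2``, ``/layers/<idx>/delays``
plus LIF and working-memory settings as group attributes; the readout under
``/head/W1`` and ``/head/w_time``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core_neuron import LIFParams
from .memory_layers import (
    FactorizedDelayKernel,
    FusionHead,
    LayerSpec,
    NetworkSpec,
    WorkingMemoryConfig,
)

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(net: NetworkSpec, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        layers = f.create_group("layers")
        for i, spec in enumerate(net.layers):
            g = layers.create_group(str(i))
            g.create_dataset("W1", data=spec.kernel.W1)
            g.create_dataset("w2", data=spec.kernel.w2)
            g.create_dataset("delays", data=spec.kernel.delays)
            g.attrs["tau"] = spec.lif.tau
            g.attrs["theta"] = spec.lif.theta
            g.attrs["v_rest"] = spec.lif.v_rest
            g.attrs["mode"] = spec.wm.mode
            g.attrs["mem_len"] = spec.wm.mem_len
        head = f.create_group("head")
        head.create_dataset("W1", data=net.head.W1)
        head.create_dataset("w_time", data=net.head.w_time)
        head.attrs["trainable_time"] = net.head.trainable_time


def load_checkpoint(path: str | Path) -> NetworkSpec:
    with h5py.File(path, "r") as f:
        layers = []
        group = f["layers"]
        for i in sorted(group, key=int):
            g = group[i]
            layers.append(LayerSpec(
                kernel=FactorizedDelayKernel(
                    W1=g["W1"][...],
                    w2=g["w2"][...],
                    delays=g["delays"][...].astype(np.int64),
                ),
                lif=LIFParams(tau=float(g.attrs["tau"]),
                              theta=float(g.attrs["theta"]),
                              v_rest=float(g.attrs["v_rest"])),
                wm=WorkingMemoryConfig(mode=str(g.attrs["mode"]),
                                       mem_len=int(g.attrs["mem_len"])),
            ))
        head = FusionHead(
            W1=f["head/W1"][...],
            w_time=f["head/w_time"][...],
            trainable_time=bool(f["head"].attrs["trainable_time"]),
        )
    return NetworkSpec(layers=tuple(layers), head=head)
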