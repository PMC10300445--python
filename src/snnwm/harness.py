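"""Experiment orchestration: YAML configs, multi-seed runs, memory sweeps.

An experiment config describes a synthetic task, a network, a training
setup, the seeds to repeat over, and optionally a list of working-memory
lengths to sweep.  ``run_experiment`` executes every (sweep value, seed)
cell — generate data, build the network, train, evaluate — and writes
per-run and aggregated (mean, sd) metrics.  Everything except wall-clock
timing fields is deterministic for a fixed config.

Timing (single-sample inference latency per sweep value) is always reported,
never asserted: it is hardware-dependent.
"""

from __future__ import annotations

import json
import statistics
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic_tasks import Dataset, TaskSpec, make_task, split_dataset
from .training import TrainingConfig, evaluate, init_network, train
from .io import save_checkpoint
from .memory_layers import NetworkSpec
from .training import network_forward

__all__ = ["NetworkConfig", "ExperimentConfig", "validate_config", "run_experiment"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description: hidden widths, temporal regime, readout."""

    hidden: tuple[int, ...] = (32,)
    mode: str = "segment"
    mem_len: int = 4
    tau: float = 2.0
    theta: float = 1.0
    fusion: bool = True

    def build(self, n_in: int, n_classes: int, T: int, seed: int,
              mem_len: int | None = None) -> NetworkSpec:
        return init_network(
            n_in=n_in, hidden=list(self.hidden), n_classes=n_classes, T=T,
            mode=self.mode, mem_len=mem_len or self.mem_len,
            tau=self.tau, theta=self.theta, seed=seed, fusion=self.fusion,
        )


@dataclass(frozen=True)
class ExperimentConfig:
    task: TaskSpec = field(default_factory=TaskSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    sweep: tuple[int, ...] | None = None
    seeds: tuple[int, ...] = (0,)
    train_fraction: float = 0.8
    output_dir: str | None = None


def _collect_errors(section: str, builder, payload: dict, errors: list[str]):
    try:
        return builder(**payload)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def validate_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config.

    Structural and semantic problems (unknown fields, negative learning
    rate, mem_len not dividing T in segment mode, ...) are aggregated into a
    single error listing every offending field.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    known = {"task", "network", "training", "sweep", "seeds",
             "train_fraction", "output_dir"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown top-level key {key!r}")
    task = _collect_errors("task", TaskSpec, raw.get("task", {}), errors)
    net_raw = dict(raw.get("network", {}))
    if "hidden" in net_raw:
        net_raw["hidden"] = tuple(net_raw["hidden"])
    network = _collect_errors("network", NetworkConfig, net_raw, errors)
    training = _collect_errors("training", TrainingConfig,
                               raw.get("training", {}), errors)
    sweep = raw.get("sweep")
    if sweep is not None:
        sweep = tuple(int(v) for v in sweep)
        if any(v < 1 for v in sweep):
            errors.append("sweep: mem_len values must be >= 1")
    seeds = tuple(int(s) for s in raw.get("seeds", [0]))
    if task is not None and network is not None and network.mode == "segment":
        for L in (sweep or (network.mem_len,)):
            if task.T % L:
                errors.append(
                    f"segment mode: mem_len {L} does not divide T={task.T} "
                    "(strict mode)"
                )
    frac = float(raw.get("train_fraction", 0.8))
    if not 0 < frac < 1:
        errors.append("train_fraction must be in (0, 1)")
    if errors:
        raise ValueError("invalid experiment config:\n  " + "\n  ".join(errors))
    return ExperimentConfig(task=task, network=network, training=training,
                            sweep=sweep, seeds=seeds, train_fraction=frac,
                            output_dir=raw.get("output_dir"))


def _inference_latency(net: NetworkSpec, data: Dataset, n_probe: int = 32
                       ) -> float:
    """Mean single-sample forward latency in seconds (reported, not asserted)."""
    n = min(n_probe, len(data))
    t0 = time.perf_counter()
    for i in range(n):
        network_forward(data.spikes[i:i + 1], net)
    return (time.perf_counter() - t0) / n


def run_one(cfg: ExperimentConfig, seed: int, mem_len: int | None = None
            ) -> dict:
    """One (seed, mem_len) cell: generate, split, build, train, evaluate."""
    task = replace(cfg.task, seed=seed)
    data = make_task(task)
    tr, te = split_dataset(data, (cfg.train_fraction, 1 - cfg.train_fraction),
                           seed=seed)
    net = cfg.network.build(task.n_in, data.n_classes, task.T, seed=seed,
                            mem_len=mem_len)
    training = replace(cfg.training, seed=seed)
    trained, hist = train(net, (tr, te), training)
    metrics = evaluate(trained, te)
    return {
        "seed": seed,
        "mem_len": mem_len or cfg.network.mem_len,
        "test_accuracy": metrics["accuracy"],
        "per_class_accuracy": metrics["per_class_accuracy"],
        "mean_firing_rate": metrics["mean_firing_rate"],
        "final_train_accuracy": hist.train_accuracy[-1],
        "final_loss": hist.loss[-1],
        "inference_latency_s": _inference_latency(trained, te),
        "_network": trained,
        "_history": hist,
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full (sweep x seeds) grid and aggregate.

    Returns ``{"runs": [...], "aggregate": {mem_len: {mean, sd, ...}}}``;
    if ``cfg.output_dir`` is set, also writes ``metrics.json`` (timing
    fields included but clearly named), per-run histories and checkpoints.
    """
    sweep = cfg.sweep or (cfg.network.mem_len,)
    runs = []
    for L in sweep:
        for seed in cfg.seeds:
            runs.append(run_one(cfg, seed, mem_len=L))
    aggregate = {}
    for L in sweep:
        accs = [r["test_accuracy"] for r in runs if r["mem_len"] == L]
        lats = [r["inference_latency_s"] for r in runs if r["mem_len"] == L]
        aggregate[int(L)] = {
            "mean_test_accuracy": statistics.fmean(accs),
            "sd_test_accuracy": statistics.stdev(accs) if len(accs) > 1 else 0.0,
            "mean_inference_latency_s": statistics.fmean(lats),
            "n_seeds": len(accs),
        }
    results = {"runs": runs, "aggregate": aggregate}
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = [
            {k: v for k, v in r.items() if not k.startswith("_")}
            for r in runs
        ]
        (out / "metrics.json").write_text(json.dumps(
            {"runs": serializable, "aggregate": aggregate}, indent=2))
        for r in runs:
            tag = f"mem{r['mem_len']}_seed{r['seed']}"
            r["_history"].to_json(out / f"history_{tag}.json")
            save_checkpoint(r["_network"], out / f"checkpoint_{tag}.h5")
    return results
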