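"""Configuration files and persistent simulation records.

Run configurations are YAML files mirroring :class:`ModelParams` plus an
experiment name with overrides; unknown keys are rejected with an explicit
listing.  Simulation records are stored as HDF5 containers (array-heavy)
with the parameter snapshot embedded, so a reloaded record reproduces every
analysis output; derived tables are exported as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .engine import ProbeResult, SimulationRecord
from .params import ModelParams

FORMAT_VERSION = 1

_TOP_KEYS = {"params", "experiment", "experiment_args", "seed", "reps", "out"}


@dataclass
class RunConfig:
    """Parsed run configuration."""

    params: ModelParams = field(default_factory=ModelParams)
    experiment: str = "formation"
    experiment_args: dict = field(default_factory=dict)
    seed: int = 0
    reps: int = 1
    out: str | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "experiment": self.experiment,
            "experiment_args": self.experiment_args,
            "seed": self.seed,
            "reps": self.reps,
            "out": self.out,
        }


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, filling defaults for missing keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParams.from_dict(raw.get("params") or {})
    return RunConfig(
        params=params,
        experiment=raw.get("experiment", "formation"),
        experiment_args=raw.get("experiment_args") or {},
        seed=int(raw.get("seed", 0)),
        reps=int(raw.get("reps", 1)),
        out=raw.get("out"),
    )


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def _write_optional(g: h5py.Group, name: str, arr) -> None:
    if arr is not None:
        g.create_dataset(name, data=np.asarray(arr), compression="gzip",
                         compression_opts=4)


def save_record(record: SimulationRecord, path) -> None:
    """Persist a simulation record as an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["seed"] = record.seed
        f.attrs["t_start"] = record.t_start
        f.attrs["t_end"] = record.t_end
        f.attrs["params"] = json.dumps(record.params.to_dict())
        gp = f.create_group("patterns")
        for name, idx in record.patterns.items():
            gp.create_dataset(name, data=np.asarray(idx, dtype=np.int64))
        gw = f.create_group("weights")
        _write_optional(gw, "times", record.weight_times)
        for key, vals in record.weight_stats.items():
            gw.create_dataset(key, data=vals)
        if record.dense_weight_times is not None:
            gd = f.create_group("dense_weights")
            _write_optional(gd, "times", record.dense_weight_times)
            for key, vals in record.dense_within.items():
                _write_optional(gd, key, vals)
        if record.pulse_times is not None:
            gf = f.create_group("pulses")
            _write_optional(gf, "times", record.pulse_times)
            gf.create_dataset(
                "patterns",
                data=np.array(record.pulse_patterns, dtype="S16"))
            _write_optional(gf, "fields", record.pulse_fields)
            _write_optional(gf, "rates", record.pulse_rates)
        if record.rate_times is not None:
            gr = f.create_group("rates")
            _write_optional(gr, "times", record.rate_times)
            _write_optional(gr, "mean", record.rate_mean)
            _write_optional(gr, "max", record.rate_max)
        gpr = f.create_group("probes")
        for i, pr in enumerate(record.probes):
            g = gpr.create_group(f"{i:06d}")
            g.attrs["time"] = pr.time
            g.attrs["pattern"] = pr.pattern
            g.create_dataset("times", data=pr.times)
            g.create_dataset("rates", data=pr.rates, compression="gzip",
                             compression_opts=4)
        gs = f.create_group("final_state")
        _write_optional(gs, "r", record.final_r)
        _write_optional(gs, "theta", record.final_theta)
        _write_optional(gs, "W", record.final_W)
        ge = f.create_group("events")
        ge.create_dataset("times", data=np.array([t for t, _ in record.events]))
        ge.create_dataset("labels",
                          data=np.array([m for _, m in record.events],
                                        dtype="S64"))


def load_record(path) -> SimulationRecord:
    """Load a record written by :func:`save_record`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"record format version {version} is not supported "
                f"(expected {FORMAT_VERSION})")
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        record = SimulationRecord(
            params=params,
            seed=int(f.attrs["seed"]),
            patterns={k: f["patterns"][k][()] for k in f["patterns"]},
            t_start=float(f.attrs["t_start"]),
            t_end=float(f.attrs["t_end"]),
        )
        gw = f["weights"]
        record.weight_times = gw["times"][()] if "times" in gw else None
        record.weight_stats = {k: gw[k][()] for k in gw if k != "times"}
        if "dense_weights" in f:
            gd = f["dense_weights"]
            record.dense_weight_times = gd["times"][()]
            record.dense_within = {k: gd[k][()] for k in gd if k != "times"}
        if "pulses" in f:
            gf = f["pulses"]
            record.pulse_times = gf["times"][()]
            record.pulse_patterns = [s.decode() for s in gf["patterns"][()]]
            record.pulse_fields = gf["fields"][()]
            record.pulse_rates = gf["rates"][()]
        if "rates" in f:
            gr = f["rates"]
            record.rate_times = gr["times"][()]
            record.rate_mean = gr["mean"][()]
            record.rate_max = gr["max"][()]
        for key in sorted(f["probes"]):
            g = f["probes"][key]
            record.probes.append(ProbeResult(
                time=float(g.attrs["time"]),
                pattern=str(g.attrs["pattern"]),
                times=g["times"][()],
                rates=g["rates"][()],
            ))
        gs = f["final_state"]
        record.final_r = gs["r"][()] if "r" in gs else None
        record.final_theta = gs["theta"][()] if "theta" in gs else None
        record.final_W = gs["W"][()] if "W" in gs else None
        ge = f["events"]
        record.events = [
            (float(t), lbl.decode())
            for t, lbl in zip(ge["times"][()], ge["labels"][()])
        ]
        return record
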