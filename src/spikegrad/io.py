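"""Readers/writers and run configuration shared by all commands.

Formats:

- Event lists: delimited text with header ``time_bin,neuron_id``, one event
  per row, integer bin indices (inputs are assumed pre-binned).  Round trips
  with dense rasters bit-exactly given the raster dimensions.
- Datasets: a directory of per-sample event-list files plus ``labels.csv``
  and a ``meta.json`` with dimensions and the generating task spec.
- Forward caches: one HDF5 file per run with groups ``layer_<l>`` holding the
  named arrays ``a, z, u, s, f_prime``.
- Run configuration: YAML, validated strictly (unknown keys are rejected so
  typos fail fast); every run directory receives a ``manifest.json`` with the
  config hash, seed and library versions for exact reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dynamics import LayerCache, SpikeRaster
from .synthetic import PATTERN_KINDS, Dataset, TaskSpec

__all__ = [
    "RunConfig",
    "NetworkConfig",
    "parse_config",
    "dump_config",
    "read_events",
    "write_events",
    "read_dataset",
    "write_dataset",
    "read_caches",
    "write_caches",
    "write_manifest",
]


# --------------------------------------------------------------------------
# event lists

EVENT_HEADER = ["time_bin", "neuron_id"]


def write_events(raster: SpikeRaster, path: str | Path) -> None:
    """Write a raster as an event list (header ``time_bin,neuron_id``)."""
    t, i = np.nonzero(raster.data)
    pd.DataFrame({"time_bin": t, "neuron_id": i}).to_csv(path, index=False)


def read_events(path: str | Path, T: int, n_neurons: int) -> SpikeRaster:
    """Read an event list into a dense (T, N) raster.

    Events outside ``[0, T) x [0, N)`` and duplicate (bin, neuron) rows are
    rejected with the offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_HEADER:
        raise ValueError(f"{path}: expected header {','.join(EVENT_HEADER)!r}, got {list(df.columns)}")
    data = np.zeros((T, n_neurons), dtype=np.int8)
    for row_idx, (t, i) in enumerate(zip(df["time_bin"], df["neuron_id"]), start=2):
        try:
            t, i = int(t), int(i)
            ok = 0 <= t < T and 0 <= i < n_neurons and float(t).is_integer()
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ValueError(f"{path}, line {row_idx}: event ({t}, {i}) outside "
                             f"[0, {T}) x [0, {n_neurons}) or malformed")
        if data[t, i]:
            raise ValueError(f"{path}, line {row_idx}: duplicate event ({t}, {i})")
        data[t, i] = 1
    return SpikeRaster(data)


# --------------------------------------------------------------------------
# datasets

def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, T, N = dataset.rasters.shape
    meta = {"n_samples": int(n), "T": int(T), "n_neurons": int(N)}
    if dataset.spec is not None:
        meta["task_spec"] = asdict(dataset.spec)
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame({"sample": range(n), "label": dataset.labels}).to_csv(
        directory / "labels.csv", index=False)
    for i in range(n):
        write_events(dataset.raster(i), directory / f"sample_{i:05d}.csv")


def read_dataset(directory: str | Path) -> Dataset:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    labels = pd.read_csv(directory / "labels.csv").sort_values("sample")["label"].to_numpy()
    n, T, N = meta["n_samples"], meta["T"], meta["n_neurons"]
    rasters = np.empty((n, T, N), dtype=np.int8)
    for i in range(n):
        rasters[i] = read_events(directory / f"sample_{i:05d}.csv", T, N).data
    spec = TaskSpec(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in meta.get("task_spec", {}).items()}) \
        if "task_spec" in meta else None
    return Dataset(rasters=rasters, labels=labels, spec=spec)


# --------------------------------------------------------------------------
# forward caches

def write_caches(caches: list[LayerCache], path: str | Path) -> None:
    """Persist per-layer forward tensors to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        for l, cache in enumerate(caches):
            grp = f.create_group(f"layer_{l}")
            grp.create_dataset("a", data=cache.a)
            grp.create_dataset("z", data=cache.z)
            grp.create_dataset("u", data=cache.u)
            grp.create_dataset("s", data=cache.s.data)
            grp.create_dataset("f_prime", data=cache.f_prime)


def read_caches(path: str | Path) -> list[LayerCache]:
    caches = []
    with h5py.File(path, "r") as f:
        for l in range(len(f)):
            grp = f[f"layer_{l}"]
            caches.append(LayerCache(a=grp["a"][()], z=grp["z"][()], u=grp["u"][()],
                                     s=SpikeRaster(grp["s"][()]),
                                     f_prime=grp["f_prime"][()]))
    return caches


# --------------------------------------------------------------------------
# run configuration (strict: unknown keys rejected)

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurrogateConfig(_Strict):
    family: str = "exponential"
    scale: float = Field(default=1.0, ge=0.0)
    width: float = Field(default=1.0, gt=0.0)


class NetworkConfig(_Strict):
    layer_sizes: list[int] = Field(min_length=2)
    alpha: float = Field(default=1.0, gt=0.0, le=1.0)
    theta: float = Field(default=1.0, gt=0.0)
    T: int = Field(default=100, ge=1)
    surrogate: SurrogateConfig = SurrogateConfig()
    weights_file: str | None = None
    weight_gain: float = Field(default=3.0, gt=0.0)

    @field_validator("layer_sizes")
    @classmethod
    def _positive_sizes(cls, v: list[int]) -> list[int]:
        if any(s < 1 for s in v):
            raise ValueError("layer sizes must be >= 1")
        return v


class TaskConfig(_Strict):
    class_count: int = Field(default=2, ge=1)
    n_in: int = Field(default=20, ge=1)
    T: int = Field(default=100, ge=1)
    pattern: str = "latency_order"
    n_train: int = Field(default=200, ge=1)
    n_test: int = Field(default=100, ge=1)
    burst_rate: float = Field(default=0.6, ge=0.0, le=1.0)
    background_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    burst_width: int = Field(default=20, ge=1)

    @field_validator("pattern")
    @classmethod
    def _known_pattern(cls, v: str) -> str:
        if v not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern {v!r}; choose from {PATTERN_KINDS}")
        return v

    def to_spec(self, seed: int) -> TaskSpec:
        return TaskSpec(class_count=self.class_count, n_in=self.n_in, T=self.T,
                        pattern=self.pattern, seed=seed, n_train=self.n_train,
                        n_test=self.n_test, burst_rate=self.burst_rate,
                        background_rate=self.background_rate,
                        burst_width=self.burst_width)


class TrainSection(_Strict):
    epochs: int = Field(default=50, ge=1)
    lr: float = Field(default=1e-3, ge=0.0)
    batch_size: int = Field(default=16, ge=1)
    algorithm: str = "exodus"
    loss: str = "sum_over_time_ce"

    @field_validator("algorithm")
    @classmethod
    def _known_algo(cls, v: str) -> str:
        if v not in ("exodus", "slayer", "bptt"):
            raise ValueError(f"unknown algorithm {v!r}")
        return v


class ExperimentSection(_Strict):
    scales: list[float] = [0.01, 0.1, 1.0, 10.0]
    seeds: list[int] = [0, 1, 2, 3, 4]
    n_steps: int = Field(default=15, ge=1)
    lr: float = Field(default=1e-3, ge=0.0)
    batch_size: int = Field(default=8, ge=1)


class RunConfig(_Strict):
    """Top-level validated run configuration with documented defaults."""

    seed: int = 0
    tolerance: float = Field(default=1e-10, gt=0.0)
    out_dir: str = "runs"
    network: NetworkConfig | None = None
    task: TaskConfig = TaskConfig()
    train: TrainSection = TrainSection()
    experiment: ExperimentSection = ExperimentSection()


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (fail-fast on unknown keys)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig) -> str:
    """Canonical YAML form of a configuration (round trips with parse)."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def write_manifest(out_dir: str | Path, config: RunConfig, command: str,
                   seed: int) -> Path:
    """Record what produced a run directory: config hash, seed, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = dump_config(config)
    from . import __version__
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config.model_dump(),
        "versions": {"spikegrad": __version__, "numpy": np.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
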