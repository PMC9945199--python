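"""Seedable generators for spike rasters and small classification tasks.

These stand in for binned event-sensor recordings (event cameras, silicon
cochleas): binary rasters over ~100 time bins and a few tens of input
channels.  Three task families are provided:

- ``poisson_rate``: classes differ in stationary firing rate — solvable from
  spike counts alone, no temporal processing needed.
- ``latency_order``: two fixed sub-populations each emit one elevated-rate
  burst; the *order* of the two bursts encodes the class.  Per-class expected
  spike counts are equal per neuron by construction, so any counts-only
  classifier is at chance and the task is discriminable only through time.
- ``burst_position``: a fixed-width burst across all inputs whose onset bin
  depends on the class.

All randomness flows through one explicit ``numpy.random.Generator``; a
fixed seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SpikeRaster

__all__ = ["TaskSpec", "Dataset", "poisson_raster", "make_task"]

PATTERN_KINDS = ("poisson_rate", "latency_order", "burst_position")


@dataclass(frozen=True)
class TaskSpec:
    """Synthetic classification task parameters.

    Defaults define the desk-scale study task: 2 classes, 20 input channels,
    100 time bins, 200 training and 100 test samples.  ``burst_rate`` and
    ``background_rate`` are per-bin spike probabilities inside and outside
    the structured windows; ``burst_width`` is the window length in bins
    (latency_order / burst_position patterns).
    """

    class_count: int = 2
    n_in: int = 20
    T: int = 100
    pattern: str = "latency_order"
    seed: int = 0
    n_train: int = 200
    n_test: int = 100
    burst_rate: float = 0.6
    background_rate: float = 0.02
    burst_width: int = 20
    poisson_rates: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERN_KINDS}")
        if self.class_count < 1 or self.n_in < 1 or self.T < 1:
            raise ValueError("class_count, n_in and T must be >= 1")
        for r in (self.burst_rate, self.background_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.pattern == "latency_order":
            if self.n_in < 2:
                raise ValueError("latency_order needs at least 2 input neurons")
            if self.class_count != 2:
                raise ValueError("latency_order is a 2-class pattern")
            if self.T < 2 * self.burst_width:
                raise ValueError("T too small for two non-overlapping bursts")
        if self.pattern == "burst_position" and self.T < self.burst_width:
            raise ValueError("T too small for the requested burst width")


@dataclass
class Dataset:
    """Labelled spike rasters: ``rasters`` (n_samples, T, N) int8 in {0,1},
    ``labels`` (n_samples,) int."""

    rasters: np.ndarray
    labels: np.ndarray
    spec: TaskSpec | None = None

    def __len__(self) -> int:
        return self.rasters.shape[0]

    def raster(self, i: int) -> SpikeRaster:
        return SpikeRaster(self.rasters[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self.raster(i), int(self.labels[i])


def poisson_raster(rate: np.ndarray, seed: int | np.random.Generator) -> SpikeRaster:
    """Independent Bernoulli draws per (bin, neuron) from a probability matrix."""
    rate = np.asarray(rate, dtype=np.float64)
    if rate.ndim != 2:
        raise ValueError("rate must be a (T, N) matrix")
    if rate.min() < 0.0 or rate.max() > 1.0:
        raise ValueError("per-bin spike probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SpikeRaster((rng.random(rate.shape) < rate).astype(np.int8))


def _rate_matrix(spec: TaskSpec, label: int) -> np.ndarray:
    """Per-bin spike probability matrix for one sample of class ``label``."""
    T, N, w = spec.T, spec.n_in, spec.burst_width
    rate = np.full((T, N), spec.background_rate)
    if spec.pattern == "poisson_rate":
        rates = spec.poisson_rates or tuple(
            0.05 + 0.10 * c for c in range(spec.class_count))
        rate[:] = rates[label]
    elif spec.pattern == "latency_order":
        # Sub-population A = first half of channels, B = second half.  One
        # early and one late burst window; the class swaps which population
        # takes which window, so per-neuron expected counts are class-free.
        half = N // 2
        early = slice(0, w)
        late = slice(T - w, T)
        a, b = slice(0, half), slice(half, N)
        first, second = ((a, b) if label == 0 else (b, a))
        rate[early, first] = spec.burst_rate
        rate[late, second] = spec.burst_rate
    else:  # burst_position
        span = T - w
        start = 0 if spec.class_count == 1 else round(label * span / (spec.class_count - 1))
        rate[start:start + w, :] = spec.burst_rate
    return rate


def make_task(spec: TaskSpec) -> tuple[Dataset, Dataset]:
    """Generate the train and test splits for a task specification.

    Labels are assigned round-robin so class frequencies are balanced; all
    draws come from a single generator seeded with ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    splits = []
    for n_samples in (spec.n_train, spec.n_test):
        rasters = np.empty((n_samples, spec.T, spec.n_in), dtype=np.int8)
        labels = np.arange(n_samples) % spec.class_count
        for i, label in enumerate(labels):
            rasters[i] = poisson_raster(_rate_matrix(spec, int(label)), rng).data
        splits.append(Dataset(rasters=rasters, labels=labels.astype(int), spec=spec))
    return splits[0], splits[1]
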