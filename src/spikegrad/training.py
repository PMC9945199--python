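"""Losses over spike outputs, a minimal SGD trainer, and the surrogate-scale
stability experiment.

The trainer is deliberately plain: minibatch stochastic gradient descent on
the weight gradients produced by one of three interchangeable backward
algorithms — the reset-aware exact pass ("exodus"), the diagonal
approximation ("slayer"), or the unrolled adjoint oracle ("bptt").  The
forward dynamics, seeding, initial weights and data order are identical
across algorithms, so any trajectory difference is attributable to the
backward pass alone.  No learning-rate schedules, momentum or augmentation.

The stability experiment mirrors the classic observation that, without
reset-aware corrections, gradient magnitudes are highly sensitive to the
surrogate scale: as the scale grows, diagonal-approximation gradients grow
multiplicatively toward the input layer, while the exact gradients remain
comparatively stable; for very small scales both vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_softmax, softmax

from .dynamics import (
    LayerParams,
    NeuronConfig,
    SpikeRaster,
    SurrogateSpec,
    forward_network,
)
from .exodus import exodus_backward
from .reference import bptt_oracle, slayer_backward
from .synthetic import Dataset, TaskSpec, make_task

__all__ = [
    "LossSpec",
    "TrainConfig",
    "ExperimentConfig",
    "History",
    "GradNormLog",
    "TrainingDiverged",
    "loss_and_eout",
    "make_dense_net",
    "train",
    "evaluate_accuracy",
    "gradient_scale_experiment",
]

ALGORITHMS = ("exodus", "slayer", "bptt")
LOSS_KINDS = ("sum_over_time_ce", "max_over_time_ce")


class TrainingDiverged(RuntimeError):
    """Raised when a non-finite loss or gradient is encountered."""


@dataclass(frozen=True)
class LossSpec:
    """Readout and loss over the output spike raster.

    ``sum_over_time_ce``: class logits are per-class spike counts summed over
    time, followed by softmax cross-entropy.  ``max_over_time_ce``: logits are
    the per-class maximum over time of the epsilon-filtered output trace
    (requires the output layer's spike-response kernel); the gradient is
    routed through the earliest arg-max bin of the filtered trace.
    """

    kind: str = "sum_over_time_ce"
    class_count: int = 2

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; choose from {LOSS_KINDS}")
        if self.class_count < 1:
            raise ValueError("class_count must be >= 1")


def _logits(output: SpikeRaster, spec: LossSpec, epsilon: np.ndarray | None):
    """Return (logits, extras) where extras carries what the gradient needs."""
    s = output.data.astype(np.float64)
    if spec.kind == "sum_over_time_ce":
        return s.sum(axis=0), None
    if epsilon is None:
        raise ValueError("max_over_time_ce requires the output layer's epsilon kernel")
    T = s.shape[0]
    eps = np.asarray(epsilon, dtype=np.float64)[:T]
    trace = np.empty_like(s)
    for c in range(s.shape[1]):
        trace[:, c] = np.convolve(s[:, c], eps)[:T]
    n_star = trace.argmax(axis=0)  # argmax returns the earliest maximizing bin
    return trace[n_star, np.arange(s.shape[1])], (n_star, eps)


def loss_and_eout(output: SpikeRaster, label: int, spec: LossSpec,
                  epsilon: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy loss and its gradient wrt the output raster.

    For the sum-over-time readout the gradient is constant in time:
    ``e_out[n, c] = softmax(logits)_c - 1{c == label}`` for every bin n.  For
    the max-over-time readout the softmax residual is routed through the
    earliest arg-max bin of each class's filtered trace and spread backward
    by the epsilon kernel.
    """
    if output.n_neurons != spec.class_count:
        raise ValueError(f"output raster has {output.n_neurons} units, expected {spec.class_count}")
    if not (0 <= label < spec.class_count):
        raise ValueError(f"label {label} out of range for {spec.class_count} classes")
    logits, extras = _logits(output, spec, epsilon)
    loss = float(-log_softmax(logits)[label])
    residual = softmax(logits)
    residual[label] -= 1.0
    T = output.T
    if spec.kind == "sum_over_time_ce":
        e_out = np.tile(residual, (T, 1))
    else:
        n_star, eps = extras
        e_out = np.zeros((T, spec.class_count))
        for c in range(spec.class_count):
            k = np.arange(n_star[c] + 1)
            e_out[k, c] = residual[c] * eps[n_star[c] - k]
    return loss, e_out


def predict_label(output: SpikeRaster, spec: LossSpec,
                  epsilon: np.ndarray | None = None) -> int:
    """Arg-max of the logits defined by the loss in force."""
    logits, _ = _logits(output, spec, epsilon)
    return int(np.argmax(logits))


def make_dense_net(sizes: tuple[int, ...], alpha: float, theta: float, T: int,
                   surrogate: SurrogateSpec, rng: np.random.Generator,
                   weight_gain: float = 3.0) -> list[LayerParams]:
    """Stack of dense LIF/IF layers with Gaussian weights of standard
    deviation ``weight_gain / sqrt(fan_in)`` (large enough that early layers
    spike on sparse binary input)."""
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output size")
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, weight_gain / np.sqrt(n_in), size=(n_out, n_in))
        layers.append(LayerParams(weights=w, neuron=NeuronConfig.lif(alpha, theta, T),
                                  surrogate=surrogate))
    return layers


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    lr: float = 1e-3
    batch_size: int = 16
    loss: LossSpec = field(default_factory=LossSpec)
    seed: int = 0
    forward_method: str = "auto"
    error_on_divergence: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class History:
    """Step- and epoch-level training log plus the final weights."""

    algorithm: str
    steps: pd.DataFrame
    epochs: pd.DataFrame
    final_weights: list[np.ndarray]
    diverged: bool = False

    @property
    def step_losses(self) -> np.ndarray:
        return self.steps["loss"].to_numpy()


def _sample_gradients(model: list[LayerParams], raster: SpikeRaster, label: int,
                      algorithm: str, loss_spec: LossSpec, forward_method: str):
    """Loss, predicted label and per-layer weight gradients for one sample."""
    eps_out = model[-1].neuron.kernels.epsilon
    caches = forward_network(model, raster, method=forward_method)
    output = caches[-1].s
    loss, e_out = loss_and_eout(output, label, loss_spec, epsilon=eps_out)
    pred = predict_label(output, loss_spec, epsilon=eps_out)
    if algorithm == "exodus":
        gs = exodus_backward(caches, model, raster, e_out)
    elif algorithm == "slayer":
        gs = slayer_backward(caches, model, raster, e_out)
    else:  # bptt: independent oracle does its own (identical) forward
        gs = bptt_oracle(model, raster, e_out)
    return loss, pred, gs.weight_grads


def train(model: list[LayerParams], task: Dataset, algorithm: str,
          config: TrainConfig) -> tuple[list[LayerParams], History]:
    """Minibatch SGD with batch-averaged weight gradients.

    Returns the trained model (the input list is not mutated) and a history
    with one row per optimization step (batch loss, per-layer gradient
    two-norms) and per epoch (mean loss, training accuracy over the
    predictions made during that epoch).  A non-finite loss or gradient
    raises :class:`TrainingDiverged` (or, with ``error_on_divergence=False``,
    stops training and flags the history).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    model = [layer.with_weights(layer.weights.copy()) for layer in model]
    rng = np.random.default_rng(config.seed)
    n = len(task)
    step_rows, epoch_rows = [], []
    diverged = False
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses, correct, seen = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            grads = [np.zeros_like(layer.weights) for layer in model]
            batch_loss = 0.0
            finite = True
            try:
                for i in idx:
                    with np.errstate(over="ignore", invalid="ignore"):
                        loss, pred, w_grads = _sample_gradients(
                            model, task.raster(int(i)), int(task.labels[i]),
                            algorithm, config.loss, config.forward_method)
                    batch_loss += loss
                    correct += int(pred == int(task.labels[i]))
                    seen += 1
                    for g, wg in zip(grads, w_grads):
                        g += wg
            except ValueError as exc:
                # overflow inside a backward pass surfaces as a finiteness
                # rejection; anything else is a genuine usage error
                if "finite" not in str(exc):
                    raise
                finite = False
            batch_loss /= len(idx)
            finite = finite and np.isfinite(batch_loss) and all(np.isfinite(g).all() for g in grads)
            if not finite:
                if config.error_on_divergence:
                    raise TrainingDiverged(
                        f"non-finite loss/gradient at epoch {epoch}, step {step} ({algorithm})")
                diverged = True
                break
            norms = [float(np.linalg.norm(g) / len(idx)) for g in grads]
            step_rows.append({"step": step, "epoch": epoch, "loss": batch_loss,
                              **{f"grad_norm_l{l}": v for l, v in enumerate(norms)}})
            model = [layer.with_weights(layer.weights - config.lr * g / len(idx))
                     for layer, g in zip(model, grads)]
            epoch_losses.append(batch_loss)
            step += 1
        if epoch_losses:
            epoch_rows.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                               "accuracy": correct / max(seen, 1)})
        if diverged:
            break
    history = History(algorithm=algorithm, steps=pd.DataFrame(step_rows),
                      epochs=pd.DataFrame(epoch_rows),
                      final_weights=[layer.weights.copy() for layer in model],
                      diverged=diverged)
    return model, history


def evaluate_accuracy(model: list[LayerParams], task: Dataset, loss_spec: LossSpec,
                      forward_method: str = "auto") -> float:
    """Fraction of samples whose logit arg-max matches the label."""
    eps_out = model[-1].neuron.kernels.epsilon
    correct = 0
    for raster, label in task:
        caches = forward_network(model, raster, method=forward_method)
        correct += int(predict_label(caches[-1].s, loss_spec, epsilon=eps_out) == label)
    return correct / len(task)


@dataclass(frozen=True)
class ExperimentConfig:
    """Surrogate-scale stability sweep on a deep synthetic task.

    A fresh network (identical weights across algorithms and scales for a
    given seed) is trained for ``n_steps`` minibatch steps at each surrogate
    scale, and per-layer weight-gradient two-norms are logged at every step.
    At least three layers are required so that growth "toward the input
    layer" is observable; the default is a 5-layer IF stack on the
    latency-order task.
    """

    scales: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    algorithms: tuple[str, ...] = ("exodus", "slayer")
    layer_sizes: tuple[int, ...] = (20, 16, 16, 16, 16, 2)
    alpha: float = 1.0
    theta: float = 1.0
    surrogate_family: str = "exponential"
    surrogate_width: float = 1.0
    n_steps: int = 15
    lr: float = 1e-3
    batch_size: int = 8
    n_samples: int = 120
    task: TaskSpec | None = None

    def __post_init__(self) -> None:
        if not self.scales or not self.seeds:
            raise ValueError("need at least one scale and one seed")
        if len(self.layer_sizes) < 4:
            raise ValueError("need >= 3 layers to observe growth toward the input layer")


@dataclass
class GradNormLog:
    """Long-format log of per-layer weight-gradient two-norms:
    columns algorithm, scale, seed, step, layer, grad_norm, diverged."""

    frame: pd.DataFrame

    def mean_norms(self) -> pd.DataFrame:
        """Mean over steps of the per-layer gradient norms."""
        return (self.frame.groupby(["algorithm", "scale", "seed", "layer"])["grad_norm"]
                .mean().reset_index())

    def first_last_ratio(self) -> pd.DataFrame:
        """Per (algorithm, scale, seed): mean first-layer norm divided by mean
        last-layer norm — the depth-amplification factor of the backward pass."""
        m = self.mean_norms()
        last = m["layer"].max()
        wide = m.pivot_table(index=["algorithm", "scale", "seed"], columns="layer",
                             values="grad_norm")
        out = wide.reset_index()[["algorithm", "scale", "seed"]]
        out["ratio"] = (wide[0] / wide[last]).to_numpy()
        return out

    def median_ratio(self) -> pd.DataFrame:
        """Median over seeds of the first/last-layer ratio."""
        r = self.first_last_ratio()
        return r.groupby(["algorithm", "scale"])["ratio"].median().reset_index()


def gradient_scale_experiment(config: ExperimentConfig) -> GradNormLog:
    """Run the stability sweep and return the gradient-norm log.

    For each seed the task data and initial weights are fixed; for each
    surrogate scale and algorithm the same network is trained for a short
    stretch of SGD and the per-layer gradient two-norms of every step are
    recorded.  Divergence (non-finite gradients) truncates that run's log and
    is flagged rather than raised.
    """
    rows = []
    for seed in config.seeds:
        task_spec = config.task or TaskSpec(n_in=config.layer_sizes[0],
                                            class_count=config.layer_sizes[-1],
                                            n_train=config.n_samples, n_test=1,
                                            seed=seed)
        train_set, _ = make_task(task_spec)
        T = task_spec.T
        epochs = max(1, int(np.ceil(config.n_steps * config.batch_size / len(train_set))))
        for scale in config.scales:
            surrogate = SurrogateSpec(family=config.surrogate_family, scale=scale,
                                      width=config.surrogate_width)
            for algorithm in config.algorithms:
                rng = np.random.default_rng(seed)  # identical init across arms
                model = make_dense_net(config.layer_sizes, config.alpha, config.theta,
                                       T, surrogate, rng)
                cfg = TrainConfig(epochs=epochs, lr=config.lr,
                                  batch_size=config.batch_size,
                                  loss=LossSpec(class_count=config.layer_sizes[-1]),
                                  seed=seed, error_on_divergence=False)
                _, hist = train(model, train_set, algorithm, cfg)
                steps = hist.steps.head(config.n_steps)
                n_layers = len(config.layer_sizes) - 1
                for _, row in steps.iterrows():
                    for layer in range(n_layers):
                        rows.append({"algorithm": algorithm, "scale": scale,
                                     "seed": seed, "step": int(row["step"]),
                                     "layer": layer,
                                     "grad_norm": row[f"grad_norm_l{layer}"],
                                     "diverged": hist.diverged})
    return GradNormLog(frame=pd.DataFrame(rows))
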