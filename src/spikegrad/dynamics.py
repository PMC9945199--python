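"""Discrete-time forward dynamics of feedforward spiking networks.

The neuron model is the Spike Response Model (SRM): the membrane potential of
a neuron is the causal convolution of its weighted input spike train with a
spike-response kernel ``epsilon``, plus the convolution of its *own* past
output spikes with a reset kernel ``nu`` (applied with a one-bin delay).  A
spike is emitted whenever the membrane potential reaches or exceeds the firing
threshold ``theta``; exact equality fires.

Leaky integrate-and-fire (LIF) neurons are the SRM special case with
geometric kernels ``epsilon[n] = alpha**n`` and ``nu[n] = -theta * alpha**n``,
where ``alpha = exp(-dt/tau)`` in (0, 1] is the per-bin membrane decay factor;
``alpha == 1`` is the non-leaky integrate-and-fire (IF) neuron.  For these
kernels the convolutional dynamics are equivalent to the O(T) state-space
recursion ``u[n] = alpha * u[n-1] + a[n] - theta * s[n-1]``.

Conventions: time bins are 0-based; all state at n < 0 is zero; kernels are
truncated at the simulation horizon T (exact for the finite sums involved);
the reset is "soft" (threshold-trace subtraction, no clamp to zero); at most
one spike per neuron per bin.  Spikes are stored as 0/1 integers, all other
state in float64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeRaster",
    "KernelPair",
    "NeuronConfig",
    "SurrogateSpec",
    "LayerParams",
    "LayerCache",
    "make_lif_kernels",
    "make_zero_reset_kernels",
    "surrogate_derivative",
    "forward_layer",
    "forward_layer_recurrent",
    "forward_network",
]

SURROGATE_FAMILIES = ("exponential", "fast_sigmoid", "piecewise_linear", "constant")


@dataclass(frozen=True)
class SpikeRaster:
    """Binary spike raster over ``T`` time bins and ``N`` neurons.

    ``data`` has shape ``(T, N)`` with entries in {0, 1}; ``dt`` is the
    time-bin width and is metadata only (the dynamics are expressed per bin).
    """

    data: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"raster must be a T x N matrix with T,N >= 1, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("raster entries must all be 0 or 1")
        object.__setattr__(self, "data", arr.astype(np.int8, copy=False))

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class KernelPair:
    """Spike-response kernel ``epsilon`` and reset kernel ``nu``, length T each.

    ``alpha``/``reset_scale`` are set by the geometric constructors
    (:func:`make_lif_kernels`, :func:`make_zero_reset_kernels`) and mark the
    kernels as ``epsilon[n] = alpha**n``, ``nu[n] = -reset_scale * alpha**n``,
    which enables the O(T) recursions.  Kernels built from raw vectors leave
    them ``None`` and are handled by the generic (quadratic) code paths.
    """

    epsilon: np.ndarray
    nu: np.ndarray
    alpha: float | None = None
    reset_scale: float | None = None

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=np.float64)
        nu = np.asarray(self.nu, dtype=np.float64)
        if eps.ndim != 1 or nu.ndim != 1 or eps.shape != nu.shape or eps.size < 1:
            raise ValueError("epsilon and nu must be 1-d vectors of equal length >= 1")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "nu", nu)

    @property
    def T(self) -> int:
        return self.epsilon.size

    @property
    def is_geometric(self) -> bool:
        return self.alpha is not None and self.reset_scale is not None


def make_lif_kernels(alpha: float, theta: float, T: int) -> KernelPair:
    """LIF/IF kernels ``epsilon[n] = alpha**n`` and ``nu[n] = -theta * alpha**n``."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if theta <= 0.0:
        raise ValueError(f"theta must be positive, got {theta}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    powers = alpha ** np.arange(T, dtype=np.float64)
    return KernelPair(epsilon=powers, nu=-theta * powers, alpha=float(alpha), reset_scale=float(theta))


def make_zero_reset_kernels(alpha: float, T: int) -> KernelPair:
    """Geometric spike-response kernel with the reset kernel set identically to 0.

    This is the forward/backward model implicitly assumed by the SLAYER
    gradient approximation: the neuron's own output spikes do not feed back
    into its membrane potential.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    powers = alpha ** np.arange(T, dtype=np.float64)
    return KernelPair(epsilon=powers, nu=np.zeros(T), alpha=float(alpha), reset_scale=0.0)


@dataclass(frozen=True)
class NeuronConfig:
    """Per-layer neuron parameters: decay ``alpha``, threshold ``theta``, kernels.

    If the physical parameters ``tau`` (membrane time constant) and ``delta``
    (simulation step) are given they must be consistent with
    ``alpha == exp(-delta/tau)`` to within 1e-12.
    """

    alpha: float
    theta: float
    kernels: KernelPair
    tau: float | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.theta <= 0.0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if (self.tau is None) != (self.delta is None):
            raise ValueError("tau and delta must be given together")
        if self.tau is not None and self.delta is not None:
            if abs(self.alpha - math.exp(-self.delta / self.tau)) >= 1e-12:
                raise ValueError("alpha is inconsistent with exp(-delta/tau)")

    @classmethod
    def lif(cls, alpha: float, theta: float, T: int, *, tau: float | None = None,
            delta: float | None = None) -> "NeuronConfig":
        return cls(alpha=alpha, theta=theta, kernels=make_lif_kernels(alpha, theta, T),
                   tau=tau, delta=delta)

    @classmethod
    def integrate_and_fire(cls, theta: float, T: int) -> "NeuronConfig":
        """Non-leaky IF neuron: the ``alpha == 1`` case."""
        return cls.lif(1.0, theta, T)

    @classmethod
    def no_reset(cls, alpha: float, theta: float, T: int) -> "NeuronConfig":
        """Neuron whose reset kernel is identically zero (SLAYER's forward model)."""
        return cls(alpha=alpha, theta=theta, kernels=make_zero_reset_kernels(alpha, T))


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate-derivative family used in place of the spike nonlinearity's
    derivative during the backward pass.

    ``scale`` multiplies the derivative everywhere (the "gradient scale"
    hyperparameter); ``width`` controls how sharply it is peaked around the
    firing threshold.  Families (``v = |u - theta|``):

    - ``exponential``:       ``scale * exp(-width * v)``
    - ``fast_sigmoid``:      ``scale / (1 + width * v)**2``
    - ``piecewise_linear``:  ``scale * max(0, 1 - width * v)``
    - ``constant``:          ``scale`` everywhere (analysis/testing aid: makes
      the reset-propagation products closed-form)
    """

    family: str = "exponential"
    scale: float = 1.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in SURROGATE_FAMILIES:
            raise ValueError(f"unknown surrogate family {self.family!r}; choose from {SURROGATE_FAMILIES}")
        if self.scale < 0.0 or not np.isfinite(self.scale):
            raise ValueError(f"scale must be finite and >= 0, got {self.scale}")
        if self.width <= 0.0 or not np.isfinite(self.width):
            raise ValueError(f"width must be finite and positive, got {self.width}")


def surrogate_derivative(u: np.ndarray, neuron: NeuronConfig, spec: SurrogateSpec) -> np.ndarray:
    """Elementwise surrogate derivative f'(u); the diagonal entries of the
    backward-pass Jacobian of the spike nonlinearity.

    Nonnegative and finite for all finite ``u``; peaks (value = ``scale``)
    at the firing threshold for every non-constant family.
    """
    u = np.asarray(u, dtype=np.float64)
    if not np.isfinite(u).all():
        raise ValueError("membrane potentials must be finite")
    if spec.family == "constant":
        return np.full_like(u, spec.scale)
    v = np.abs(u - neuron.theta)
    if spec.family == "exponential":
        return spec.scale * np.exp(-spec.width * v)
    if spec.family == "fast_sigmoid":
        return spec.scale / (1.0 + spec.width * v) ** 2
    # piecewise_linear
    return spec.scale * np.maximum(0.0, 1.0 - spec.width * v)


@dataclass(frozen=True)
class LayerParams:
    """Dense layer: input weights (N_out x N_in), neuron config, surrogate."""

    weights: np.ndarray
    neuron: NeuronConfig
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-d matrix (N_out x N_in)")
        object.__setattr__(self, "weights", w)

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]

    @property
    def n_in(self) -> int:
        return self.weights.shape[1]

    def with_weights(self, w: np.ndarray) -> "LayerParams":
        return replace(self, weights=w)


@dataclass(frozen=True)
class LayerCache:
    """Forward tensors of one layer, all shape (T, N): weighted input ``a``,
    post-synaptic response ``z``, membrane potential ``u``, spikes ``s``, and
    the surrogate derivative ``f_prime`` evaluated at ``u`` during the forward
    pass (the backward pass must reuse exactly these values)."""

    a: np.ndarray
    z: np.ndarray
    u: np.ndarray
    s: SpikeRaster
    f_prime: np.ndarray


def _validate_layer_input(params: LayerParams, input_spikes: SpikeRaster) -> None:
    if input_spikes.n_neurons != params.n_in:
        raise ValueError(
            f"input raster has {input_spikes.n_neurons} neurons but weights expect {params.n_in}")
    if params.neuron.kernels.T < input_spikes.T:
        raise ValueError("kernels shorter than the simulation horizon")


def forward_layer(params: LayerParams, input_spikes: SpikeRaster) -> LayerCache:
    """Reference (convolutional) forward pass of one SRM layer.

    Per time bin n: ``a[n] = W s_in[n]``; ``z[n] = sum_{k<=n} eps[n-k] a[k]``;
    ``u[n] = z[n] + sum_{k<=n-1} nu[n-1-k] s[k]`` (unit-delay reset);
    ``s[n] = 1{u[n] >= theta}``.  Cost O(T^2) per neuron; exact for any
    kernel pair.
    """
    _validate_layer_input(params, input_spikes)
    T = input_spikes.T
    eps = params.neuron.kernels.epsilon[:T]
    nu = params.neuron.kernels.nu[:T]
    theta = params.neuron.theta

    s_in = input_spikes.data.astype(np.float64)
    a = s_in @ params.weights.T  # (T, N_out)
    n_out = a.shape[1]

    # Causal convolution of each input column with epsilon, truncated at T.
    z = np.empty_like(a)
    for j in range(n_out):
        z[:, j] = np.convolve(a[:, j], eps)[:T]

    u = np.empty_like(a)
    s = np.zeros((T, n_out), dtype=np.int8)
    for n in range(T):
        reset = np.zeros(n_out)
        if n > 0:
            # sum_{k=0}^{n-1} nu[n-1-k] * s[k]
            reset = (s[:n].astype(np.float64) * nu[:n][::-1, None]).sum(axis=0)
        u[n] = z[n] + reset
        s[n] = u[n] >= theta

    f_prime = surrogate_derivative(u, params.neuron, params.surrogate)
    return LayerCache(a=a, z=z, u=u, s=SpikeRaster(s, dt=input_spikes.dt), f_prime=f_prime)


def forward_layer_recurrent(params: LayerParams, input_spikes: SpikeRaster) -> LayerCache:
    """O(T) state-space forward pass, valid for geometric (LIF/IF) kernels.

    ``z[n] = alpha z[n-1] + a[n]``; ``r[n] = alpha r[n-1] - c s[n-1]`` with
    ``c`` the reset scale (theta for LIF, 0 for a zero reset kernel);
    ``u[n] = z[n] + r[n]``.  Agrees with :func:`forward_layer` to float64
    round-off on every cached field.
    """
    _validate_layer_input(params, input_spikes)
    kern = params.neuron.kernels
    if not kern.is_geometric:
        raise ValueError("recurrent forward requires geometric (LIF/IF-style) kernels")
    alpha, c = kern.alpha, kern.reset_scale
    theta = params.neuron.theta

    T = input_spikes.T
    s_in = input_spikes.data.astype(np.float64)
    a = s_in @ params.weights.T
    n_out = a.shape[1]

    z = np.empty_like(a)
    u = np.empty_like(a)
    s = np.zeros((T, n_out), dtype=np.int8)
    z_prev = np.zeros(n_out)
    r_prev = np.zeros(n_out)
    s_prev = np.zeros(n_out)
    for n in range(T):
        z_prev = alpha * z_prev + a[n]
        r_prev = alpha * r_prev - c * s_prev
        z[n] = z_prev
        u[n] = z_prev + r_prev
        spike = u[n] >= theta
        s[n] = spike
        s_prev = spike.astype(np.float64)

    f_prime = surrogate_derivative(u, params.neuron, params.surrogate)
    return LayerCache(a=a, z=z, u=u, s=SpikeRaster(s, dt=input_spikes.dt), f_prime=f_prime)


def forward_network(layers: list[LayerParams], input_spikes: SpikeRaster,
                    method: str = "auto") -> list[LayerCache]:
    """Forward pass through a stack of dense SRM layers.

    ``method``: "conv" forces the convolutional reference path, "recurrent"
    the O(T) path (geometric kernels only), "auto" picks the recurrent path
    whenever the layer's kernels permit it.
    """
    if method not in ("auto", "conv", "recurrent"):
        raise ValueError(f"unknown forward method {method!r}")
    caches: list[LayerCache] = []
    current = input_spikes
    for idx, layer in enumerate(layers):
        if current.n_neurons != layer.n_in:
            raise ValueError(f"layer {idx}: expected {layer.n_in} inputs, got {current.n_neurons}")
        if method == "conv":
            cache = forward_layer(layer, current)
        elif method == "recurrent":
            cache = forward_layer_recurrent(layer, current)
        else:
            fwd = forward_layer_recurrent if layer.neuron.kernels.is_geometric else forward_layer
            cache = fwd(layer, current)
        caches.append(cache)
        current = cache.s
    return caches
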