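"""Exact reset-aware backward pass for feedforward SRM/LIF/IF networks.

Vectorizing a layer's dynamics over time creates a cyclic dependency between
the membrane potential u[.] and the layer's own output spikes s[.] (through
the reset kernel), so the chain rule cannot be applied node-by-node.  The
Implicit Function Theorem resolves the cycle: treating the post-synaptic
response z[.] as the independent variable and (u[.], s[.]) as dependent,
the Jacobian ds[.]/dz[.] exists and its blocks sigma_m[n] = ds[n]/dz[m]
satisfy a forward-substitution recursion

    sigma_m[n] = 0                              for n < m
    sigma_m[n] = f'[n]                          for n = m
    sigma_m[n] = f'[n] * (nu * sigma_m)[n-1]    for n > m

with f'[n] the (diagonal) surrogate derivative cached during the forward
pass.  For geometric LIF/IF kernels this collapses to the closed form
``sigma_m[n] = -theta * f'[n] * f'[m] * chi_m[n]`` with
``chi_m[n] = prod_{k=m+1}^{n-1} (alpha - theta f'[k])``, and the
loss-to-input gradients d[n] admit an O(T) backward recursion

    d[n] = e[n] * f'[n] + d[n+1] * (alpha - theta * f'[n]).

Per-layer chaining (all 0-based over n in [0, T)):

    e[n]     = d_next[n] @ W_next                (loss wrt layer output spikes,
                                                  downstream path)
    d[n]     = sum_{m>=n} sum_{k>=m} e[k] sigma_m[k] eps[m-n]
                                                 (loss wrt weighted input)
    dL/dW    = sum_n outer(d[n], s_in[n])

The resulting weight gradients are equal (to float64 round-off) to those of
backpropagation through time over the fully unrolled graph; dropping the
reset kernel from sigma (sigma diagonal) recovers the SLAYER approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import LayerCache, LayerParams, SpikeRaster

__all__ = [
    "GradientSet",
    "OpCounter",
    "sigma_generic",
    "sigma_lif",
    "chi_closed_form",
    "zeta_products",
    "backprop_e",
    "backprop_d_generic",
    "backprop_d_lif",
    "weight_gradient",
    "exodus_backward",
]

# Generic-path sigma tensors are materialized as (T, T, N) arrays; beyond this
# horizon the quadratic memory is unreasonable and the fast path must be used.
MAX_GENERIC_T = 256


@dataclass
class GradientSet:
    """Per-layer backward tensors: ``e[l]`` (T x N_l, loss wrt output spikes,
    downstream path), ``d[l]`` (T x N_l, loss wrt weighted input) and
    ``weight_grads[l]`` (N_l x N_{l-1}, loss wrt the layer's input weights)."""

    e: list[np.ndarray]
    d: list[np.ndarray]
    weight_grads: list[np.ndarray]

    def __post_init__(self) -> None:
        for name in ("e", "d", "weight_grads"):
            for arr in getattr(self, name):
                if not np.isfinite(arr).all():
                    raise ValueError(f"non-finite entries in GradientSet.{name}")

    @property
    def n_layers(self) -> int:
        return len(self.weight_grads)


class OpCounter:
    """Tallies scalar multiply-accumulate work executed by an instrumented
    routine (used to verify O(T) scaling by operation count, not wall clock)."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)


def _check_fprime(f_prime: np.ndarray) -> np.ndarray:
    f_prime = np.asarray(f_prime, dtype=np.float64)
    if f_prime.ndim != 2:
        raise ValueError("f_prime must have shape (T, N)")
    if not np.isfinite(f_prime).all():
        raise ValueError("surrogate derivatives must be finite")
    return f_prime


def sigma_generic(f_prime: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Jacobian blocks sigma[n, m, :] = ds[n]/dz[m] by forward substitution.

    Exact for any reset kernel ``nu`` (length >= T); O(T^3) time and O(T^2 N)
    memory, intended as the reference/oracle for the closed-form LIF path and
    for small horizons only.
    """
    f_prime = _check_fprime(f_prime)
    T, N = f_prime.shape
    nu = np.asarray(nu, dtype=np.float64)
    if nu.ndim != 1 or nu.size < T:
        raise ValueError("reset kernel must be a vector of length >= T")
    if T > MAX_GENERIC_T:
        raise ValueError(f"generic sigma limited to T <= {MAX_GENERIC_T}")
    sig = np.zeros((T, T, N))
    for m in range(T):
        sig[m, m] = f_prime[m]
        for n in range(m + 1, T):
            # (nu * sigma_m)[n-1] = sum_{k=m}^{n-1} nu[n-1-k] sigma_m[k]
            conv = (sig[m:n, m] * nu[: n - m][::-1, None]).sum(axis=0)
            sig[n, m] = f_prime[n] * conv
    return sig


def chi_closed_form(f_prime: np.ndarray, alpha: float, theta: float,
                    n: int, m: int) -> np.ndarray:
    """Diagonal of the reset-propagation product chi_m[n] for LIF/IF kernels:
    1 for n == m+1, ``prod_{k=m+1}^{n-1} (alpha - theta * f'[k])`` for
    n > m+1.  Returns a length-N vector; requires n > m."""
    f_prime = _check_fprime(f_prime)
    if n <= m:
        raise ValueError("chi_m[n] is defined for n > m only")
    N = f_prime.shape[1]
    if n == m + 1:
        return np.ones(N)
    return np.prod(alpha - theta * f_prime[m + 1: n], axis=0)


def sigma_lif(f_prime: np.ndarray, alpha: float, theta: float) -> np.ndarray:
    """Closed-form sigma for LIF/IF kernels:
    sigma[n, m] = f'[n] (n == m), -theta f'[n] f'[m] chi_m[n] (n > m), else 0.

    Equals :func:`sigma_generic` with the matching geometric kernels to
    float64 round-off; still O(T^2 N) memory (reference path only).
    """
    f_prime = _check_fprime(f_prime)
    T, N = f_prime.shape
    if T > MAX_GENERIC_T:
        raise ValueError(f"materialized sigma limited to T <= {MAX_GENERIC_T}")
    g = alpha - theta * f_prime  # (T, N)
    sig = np.zeros((T, T, N))
    for m in range(T):
        sig[m, m] = f_prime[m]
        chi = np.ones(N)
        for n in range(m + 1, T):
            if n > m + 1:
                chi = chi * g[n - 1]
            sig[n, m] = -theta * f_prime[n] * f_prime[m] * chi
    return sig


def zeta_products(f_prime: np.ndarray, alpha: float, theta: float) -> np.ndarray:
    """Auxiliary products zeta[n, k] = prod_{m=n}^{k-1} (alpha - theta f'[m])
    for k >= n (1 at k == n; zero below the diagonal).  Shape (T, T, N).
    Materialized for verification only; the O(T) path never forms it."""
    f_prime = _check_fprime(f_prime)
    T, N = f_prime.shape
    g = alpha - theta * f_prime
    zeta = np.zeros((T, T, N))
    for n in range(T):
        zeta[n, n] = 1.0
        for k in range(n + 1, T):
            zeta[n, k] = zeta[n, k - 1] * g[k - 1]
    return zeta


def backprop_e(d_next: np.ndarray, weights_next: np.ndarray) -> np.ndarray:
    """Loss wrt a layer's output spikes via the downstream layer:
    e[n] = d_next[n] @ W_next (per-time matrix product)."""
    d_next = np.asarray(d_next, dtype=np.float64)
    weights_next = np.asarray(weights_next, dtype=np.float64)
    if d_next.ndim != 2 or d_next.shape[1] != weights_next.shape[0]:
        raise ValueError("shape mismatch between d_next and weights_next")
    return d_next @ weights_next


def backprop_d_generic(e: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """Loss wrt the weighted input by the literal double sum
    d[n] = sum_{m=n}^{T-1} sum_{k=m}^{T-1} e[k] sigma[k, m] eps[m-n].

    Reference path for any SRM kernel; O(T^2 N) after precomputing the inner
    sums S[m] = sum_{k>=m} e[k] sigma[k, m].
    """
    e = np.asarray(e, dtype=np.float64)
    T, N = e.shape
    if sigma.shape != (T, T, N):
        raise ValueError(f"sigma must have shape {(T, T, N)}, got {sigma.shape}")
    epsilon = np.asarray(epsilon, dtype=np.float64)
    if epsilon.size < T:
        raise ValueError("epsilon kernel shorter than horizon")
    # S[m] = sum_{k=m}^{T-1} e[k] * sigma[k, m]
    S = np.empty((T, N))
    for m in range(T):
        S[m] = (e[m:] * sigma[m:, m]).sum(axis=0)
    d = np.empty((T, N))
    for n in range(T):
        d[n] = (S[n:] * epsilon[: T - n, None]).sum(axis=0)
    return d


def backprop_d_lif(e: np.ndarray, f_prime: np.ndarray, alpha: float, theta: float,
                   counter: OpCounter | None = None) -> np.ndarray:
    """O(T) evaluation of d for geometric kernels via the backward recursion

        d[T-1] = e[T-1] * f'[T-1]
        d[n]   = e[n] * f'[n] + d[n+1] * (alpha - theta * f'[n])

    obtained by substituting the zeta recursion into
    d[n] = sum_{k>=n} e[k] f'[k] zeta_n[k].  ``theta`` is the reset strength
    taken from the kernel pair (the firing threshold for LIF/IF, 0 for a zero
    reset kernel, in which case this is the SLAYER backward recursion).
    Neurons are independent; cost is linear in T per neuron.
    """
    e = np.asarray(e, dtype=np.float64)
    f_prime = _check_fprime(f_prime)
    if e.shape != f_prime.shape:
        raise ValueError("e and f_prime must have matching (T, N) shapes")
    if not np.isfinite(e).all():
        raise ValueError("e must be finite")
    T, N = e.shape
    d = np.empty((T, N))
    d[T - 1] = e[T - 1] * f_prime[T - 1]
    if counter is not None:
        counter.add(N)
    for n in range(T - 2, -1, -1):
        d[n] = e[n] * f_prime[n] + d[n + 1] * (alpha - theta * f_prime[n])
        if counter is not None:
            # per bin and neuron: e*f', theta*f', alpha - (.), d*(.), final add
            counter.add(5 * N)
    return d


def weight_gradient(d: np.ndarray, s_in: SpikeRaster | np.ndarray) -> np.ndarray:
    """Loss wrt a layer's input weights: sum over time of outer products
    d[n] s_in[n]^T, where s_in is the layer's input spike train."""
    d = np.asarray(d, dtype=np.float64)
    s = s_in.data if isinstance(s_in, SpikeRaster) else np.asarray(s_in)
    if d.ndim != 2 or s.ndim != 2 or d.shape[0] != s.shape[0]:
        raise ValueError("d and input raster must share the time dimension")
    return d.T @ s.astype(np.float64)


def _layer_d(layer: LayerParams, cache: LayerCache, e: np.ndarray, method: str,
             counter: OpCounter | None = None) -> np.ndarray:
    kern = layer.neuron.kernels
    use_fast = kern.is_geometric if method == "auto" else (method == "fast")
    if use_fast:
        if not kern.is_geometric:
            raise ValueError("fast path requires geometric (LIF/IF-style) kernels")
        return backprop_d_lif(e, cache.f_prime, kern.alpha, kern.reset_scale, counter)
    T = e.shape[0]
    sigma = sigma_generic(cache.f_prime, kern.nu[:T])
    return backprop_d_generic(e, sigma, kern.epsilon[:T])


def exodus_backward(caches: list[LayerCache], layers: list[LayerParams],
                    input_spikes: SpikeRaster, e_out: np.ndarray,
                    method: str = "auto") -> GradientSet:
    """Full reset-aware backward sweep through a layer stack.

    ``caches`` must come from a forward pass of ``layers`` on ``input_spikes``;
    ``e_out`` is the loss gradient wrt the output layer's spike raster
    (T x N_L).  ``method``: "fast" forces the O(T) LIF/IF recursion,
    "generic" the sigma-based reference path, "auto" dispatches per layer on
    the kernel family.  Returns per-layer e, d and weight gradients.
    """
    if len(caches) != len(layers) or not layers:
        raise ValueError("caches and layers must be non-empty and match")
    if method not in ("auto", "fast", "generic"):
        raise ValueError(f"unknown backward method {method!r}")
    L = len(layers)
    e_out = np.asarray(e_out, dtype=np.float64)
    if e_out.shape != caches[-1].u.shape:
        raise ValueError(f"e_out must have shape {caches[-1].u.shape}, got {e_out.shape}")
    for cache, layer in zip(caches, layers):
        if cache.u.shape[1] != layer.n_out:
            raise ValueError("cache/parameter layer-size mismatch")

    e_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    d_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    w_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    e = e_out
    for l in range(L - 1, -1, -1):
        e_list[l] = e
        d = _layer_d(layers[l], caches[l], e, method)
        d_list[l] = d
        s_in = input_spikes if l == 0 else caches[l - 1].s
        w_list[l] = weight_gradient(d, s_in)
        if l > 0:
            e = backprop_e(d, layers[l].weights)
    return GradientSet(e=e_list, d=d_list, weight_grads=w_list)
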