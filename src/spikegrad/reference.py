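"""Baseline gradient algorithms: the SLAYER approximation and an independent
unrolled-BPTT oracle.

SLAYER back-propagates through the time-vectorized layer graph but ignores
the reset kernel when differentiating the spike nonlinearity: the Jacobian
blocks ds[n]/dz[m] are kept only on the diagonal (m == n), where they equal
the surrogate derivative.  Its e and weight-gradient formulas are identical
to the reset-aware pipeline; only d differs.  For geometric kernels this
yields the recursion ``d[n] = e[n] f'[n] + alpha d[n+1]`` — exactly the
reset-aware recursion with the reset strength set to zero.

The BPTT oracle differentiates the surrogate-relaxed, fully unrolled
spatio-temporal graph by a hand-written reverse sweep (reverse in time,
top-down in layers within each time bin).  It shares no backward code with
the reset-aware implementation, making their agreement a genuine
cross-check.  Note that finite differences of the true loss would NOT be a
valid oracle: surrogate gradients deliberately differ from the derivative of
the discontinuous spike function; the oracle differentiates the same
surrogate-relaxed graph that surrogate-gradient BPTT training uses, treating
every occurrence of s[n] (the downstream path *and* the reset path) as
having derivative f'(u[n]) — the reset-path term is precisely what SLAYER
drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import LayerCache, LayerParams, SpikeRaster, surrogate_derivative
from .exodus import (
    GradientSet,
    backprop_d_generic,
    backprop_d_lif,
    backprop_e,
    weight_gradient,
)

__all__ = ["OracleReport", "slayer_backward", "bptt_oracle", "compare_gradients"]


@dataclass
class OracleReport:
    """Per-layer agreement between two GradientSets at a stated tolerance."""

    max_abs: list[float]
    rel: list[float]
    tol: float
    passed: bool
    worst: tuple[int, str, float] = field(default=(0, "", 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "layer": range(len(self.max_abs)),
            "max_abs_deviation": self.max_abs,
            "relative_deviation": self.rel,
        })


def _slayer_d(layer: LayerParams, cache: LayerCache, e: np.ndarray, method: str) -> np.ndarray:
    kern = layer.neuron.kernels
    use_fast = (kern.alpha is not None) if method == "auto" else (method == "fast")
    if use_fast:
        if kern.alpha is None:
            raise ValueError("fast SLAYER path requires a geometric spike-response kernel")
        return backprop_d_lif(e, cache.f_prime, kern.alpha, 0.0)
    T, N = e.shape
    sigma = np.zeros((T, T, N))
    sigma[np.arange(T), np.arange(T)] = cache.f_prime
    return backprop_d_generic(e, sigma, kern.epsilon[:T])


def slayer_backward(caches: list[LayerCache], layers: list[LayerParams],
                    input_spikes: SpikeRaster, e_out: np.ndarray,
                    method: str = "auto") -> GradientSet:
    """SLAYER backward sweep: identical pipeline to the reset-aware one except
    that the within-layer Jacobian ds/dz is truncated to its diagonal
    (equivalently, the reset kernel is zero in the backward pass)."""
    if len(caches) != len(layers) or not layers:
        raise ValueError("caches and layers must be non-empty and match")
    if method not in ("auto", "fast", "generic"):
        raise ValueError(f"unknown backward method {method!r}")
    L = len(layers)
    e_out = np.asarray(e_out, dtype=np.float64)
    if e_out.shape != caches[-1].u.shape:
        raise ValueError(f"e_out must have shape {caches[-1].u.shape}, got {e_out.shape}")

    e_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    d_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    w_list: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    e = e_out
    for l in range(L - 1, -1, -1):
        e_list[l] = e
        d = _slayer_d(layers[l], caches[l], e, method)
        d_list[l] = d
        s_in = input_spikes if l == 0 else caches[l - 1].s
        w_list[l] = weight_gradient(d, s_in)
        if l > 0:
            e = backprop_e(d, layers[l].weights)
    return GradientSet(e=e_list, d=d_list, weight_grads=w_list)


def bptt_oracle(layers: list[LayerParams], input_spikes: SpikeRaster,
                e_out: np.ndarray) -> GradientSet:
    """Ground-truth gradients by reverse-mode sweep over the fully unrolled
    time-by-layer graph (LIF/IF-style geometric kernels only).

    Runs its own O(T) recurrent forward simulation
    ``u[n] = alpha u[n-1] + a[n] - c s[n-1]`` and a hand-written adjoint
    sweep, reusing only the forward-side surrogate evaluation.  Complexity
    O(N^2 T); no code shared with the reset-aware backward pass.
    """
    if not layers:
        raise ValueError("empty layer stack")
    for layer in layers:
        if not layer.neuron.kernels.is_geometric:
            raise ValueError("BPTT oracle supports geometric (LIF/IF-style) kernels only")
    L = len(layers)
    T = input_spikes.T

    # --- forward: unrolled state recursion, caching spikes and f' per layer
    spikes: list[np.ndarray] = []   # float (T, N_l)
    fps: list[np.ndarray] = []      # surrogate derivative at u, (T, N_l)
    cur = input_spikes.data.astype(np.float64)
    for layer in layers:
        alpha = layer.neuron.kernels.alpha
        c = layer.neuron.kernels.reset_scale
        theta = layer.neuron.theta
        a = cur @ layer.weights.T
        n_out = a.shape[1]
        u = np.empty((T, n_out))
        s = np.empty((T, n_out))
        u_prev = np.zeros(n_out)
        s_prev = np.zeros(n_out)
        for n in range(T):
            u_prev = alpha * u_prev + a[n] - c * s_prev
            u[n] = u_prev
            s_prev = (u_prev >= theta).astype(np.float64)
            s[n] = s_prev
        spikes.append(s)
        fps.append(surrogate_derivative(u, layer.neuron, layer.surrogate))
        cur = s

    e_out = np.asarray(e_out, dtype=np.float64)
    if e_out.shape != spikes[-1].shape:
        raise ValueError(f"e_out must have shape {spikes[-1].shape}, got {e_out.shape}")

    # --- backward: adjoints of u per layer, reverse in time, top-down in layers
    gu = [np.zeros_like(s) for s in spikes]       # dL/du^(l)[n] (== dL/da^(l)[n])
    e_down = [np.zeros_like(s) for s in spikes]   # downstream-path dL/ds^(l)[n]
    for n in range(T - 1, -1, -1):
        for l in range(L - 1, -1, -1):
            gu_next = gu[l][n + 1] if n + 1 < T else 0.0
            if l == L - 1:
                ed = e_out[n]
            else:
                ed = layers[l + 1].weights.T @ gu[l + 1][n]
            e_down[l][n] = ed
            c = layers[l].neuron.kernels.reset_scale
            alpha = layers[l].neuron.kernels.alpha
            gs_total = ed - c * gu_next
            gu[l][n] = fps[l][n] * gs_total + alpha * gu_next

    w_grads = []
    for l in range(L):
        s_in = input_spikes.data.astype(np.float64) if l == 0 else spikes[l - 1]
        w_grads.append(gu[l].T @ s_in)
    return GradientSet(e=e_down, d=gu, weight_grads=w_grads)


def _pairs(gs_a: GradientSet, gs_b: GradientSet, fields: tuple[str, ...]):
    for name in fields:
        la, lb = getattr(gs_a, name), getattr(gs_b, name)
        if len(la) != len(lb):
            raise ValueError(f"GradientSets have different layer counts in {name}")
        for l, (a, b) in enumerate(zip(la, lb)):
            if a.shape != b.shape:
                raise ValueError(f"shape mismatch in {name}, layer {l}: {a.shape} vs {b.shape}")
            yield name, l, a, b


def compare_gradients(gs_a: GradientSet, gs_b: GradientSet, tol: float,
                      fields: tuple[str, ...] = ("weight_grads", "e", "d")) -> OracleReport:
    """Elementwise deviations between two GradientSets and a pass/fail verdict.

    Per layer: max-abs deviation over the selected fields, and that deviation
    relative to the larger of the two sets' max-abs entries (0 when both
    vanish).  Passes when every max-abs deviation is <= ``tol``.
    """
    L = gs_a.n_layers
    max_abs = [0.0] * L
    scale = [0.0] * L
    worst = (0, "", -1.0)
    for name, l, a, b in _pairs(gs_a, gs_b, fields):
        dev = float(np.max(np.abs(a - b))) if a.size else 0.0
        scale[l] = max(scale[l], float(np.max(np.abs(a))), float(np.max(np.abs(b))))
        if dev > max_abs[l]:
            max_abs[l] = dev
        if dev > worst[2]:
            worst = (l, name, dev)
    rel = [m / s if s > 0 else 0.0 for m, s in zip(max_abs, scale)]
    return OracleReport(max_abs=max_abs, rel=rel, tol=tol,
                        passed=all(m <= tol for m in max_abs), worst=worst)
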