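"""Reset-aware backward pass: sigma/chi/zeta tensors, the oracle chain from
the literal double sum to the O(T) recursion, and the full layer sweep."""

import dataclasses

import numpy as np
import pytest

from spikegrad import (
    LayerParams,
    NeuronConfig,
    OpCounter,
    SpikeRaster,
    SurrogateSpec,
    backprop_d_generic,
    backprop_d_lif,
    backprop_e,
    chi_closed_form,
    exodus_backward,
    forward_network,
    make_lif_kernels,
    sigma_generic,
    sigma_lif,
    weight_gradient,
    zeta_products,
)

from conftest import random_lif_stack


def literal_double_sum_d(e, sigma, epsilon):
    """Unvectorized transcription of the d definition, used as a test oracle:
    d[n] = sum_{m=n}^{T-1} sum_{k=m}^{T-1} e[k] sigma[k, m] eps[m-n]."""
    T, N = e.shape
    d = np.zeros((T, N))
    for n in range(T):
        for m in range(n, T):
            for k in range(m, T):
                d[n] += e[k] * sigma[k, m] * epsilon[m - n]
    return d


class TestSigma:
    def test_triangular_support_and_diagonal(self, rng):
        T, N = 10, 3
        fp = rng.uniform(0.1, 1.0, size=(T, N))
        sig = sigma_generic(fp, make_lif_kernels(0.9, 1.0, T).nu)
        for m in range(T):
            np.testing.assert_allclose(sig[m, m], fp[m])       # n = m: f'[n]
            for n in range(m):
                np.testing.assert_array_equal(sig[n, m], 0.0)  # n < m: zero

    def test_constant_surrogate_if_closed_form(self):
        # IF (alpha=1), theta=1, f' == c: unrolling the recursion gives
        # sigma_m[n] = -c^2 (1-c)^(n-m-1) for n > m.
        T, c = 8, 0.3
        fp = np.full((T, 1), c)
        sig = sigma_generic(fp, make_lif_kernels(1.0, 1.0, T).nu)
        for m in range(T):
            for n in range(m + 1, T):
                assert sig[n, m, 0] == pytest.approx(-c * c * (1 - c) ** (n - m - 1))

    def test_closed_form_matches_forward_substitution(self, rng):
        for trial in range(100):
            T = int(rng.integers(2, 25))
            N = int(rng.integers(1, 9))
            alpha = (1.0, 0.9, 0.5)[trial % 3]
            theta = float(rng.uniform(0.5, 2.0))
            fp = rng.uniform(0.0, 1.2, size=(T, N))
            kern = make_lif_kernels(alpha, theta, T)
            np.testing.assert_allclose(sigma_lif(fp, alpha, theta),
                                       sigma_generic(fp, kern.nu), rtol=0, atol=1e-10)

    def test_zero_surrogate_kills_reset_terms(self):
        sig = sigma_lif(np.zeros((6, 2)), 0.9, 1.0)
        np.testing.assert_array_equal(sig, 0.0)

    def test_nonfinite_surrogate_rejected(self):
        with pytest.raises(ValueError):
            sigma_generic(np.array([[np.nan]]), np.array([-1.0]))


class TestChi:
    def test_adjacent_times_give_identity(self, rng):
        fp = rng.uniform(0, 1, size=(6, 4))
        np.testing.assert_array_equal(chi_closed_form(fp, 0.9, 1.0, 3, 2), 1.0)

    def test_zero_surrogate_reduces_to_alpha_power(self):
        fp = np.zeros((10, 2))
        for m, n in [(0, 2), (0, 9), (3, 7)]:
            np.testing.assert_allclose(chi_closed_form(fp, 0.8, 1.0, n, m),
                                       0.8 ** (n - m - 1))

    def test_constant_surrogate_if_power_law(self):
        fp = np.full((10, 1), 0.25)
        for m, n in [(1, 3), (0, 9)]:
            assert chi_closed_form(fp, 1.0, 1.0, n, m)[0] == pytest.approx(
                0.75 ** (n - m - 1))

    def test_requires_n_greater_than_m(self):
        with pytest.raises(ValueError):
            chi_closed_form(np.zeros((4, 1)), 0.9, 1.0, 2, 2)


class TestZeta:
    def test_recursion_and_boundary(self, rng):
        T, N, alpha, theta = 7, 3, 0.9, 1.0
        fp = rng.uniform(0, 1, size=(T, N))
        zeta = zeta_products(fp, alpha, theta)
        g = alpha - theta * fp
        for n in range(T):
            np.testing.assert_array_equal(zeta[n, n], 1.0)
            for k in range(n + 1, T):
                np.testing.assert_allclose(zeta[n, k], g[n] * zeta[n + 1, k])


class TestBackpropE:
    def test_identity_weights_pass_through(self, rng):
        d = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(backprop_e(d, np.eye(3)), d)

    def test_single_step_hand_product(self):
        np.testing.assert_allclose(
            backprop_e(np.array([[1.0, 2.0]]), np.array([[1.0, 0.0], [0.0, 3.0]])),
            [[1.0, 6.0]])

    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(backprop_e(np.zeros((4, 2)), np.ones((2, 3))), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backprop_e(np.zeros((4, 2)), np.ones((3, 3)))


class TestBackpropD:
    def test_generic_matches_literal_double_sum(self, rng):
        for _ in range(20):
            T, N = int(rng.integers(1, 12)), int(rng.integers(1, 5))
            fp = rng.uniform(0, 1, size=(T, N))
            kern = make_lif_kernels(0.9, 1.0, T)
            sig = sigma_generic(fp, kern.nu)
            e = rng.normal(size=(T, N))
            np.testing.assert_allclose(backprop_d_generic(e, sig, kern.epsilon),
                                       literal_double_sum_d(e, sig, kern.epsilon),
                                       rtol=0, atol=1e-12)

    def test_unit_horizon_collapse(self, rng):
        # T=1: d[0] = e[0] * f'[0] (eps[0] = 1).
        e, fp = rng.normal(size=(1, 3)), rng.uniform(0, 1, size=(1, 3))
        sig = sigma_lif(fp, 0.9, 1.0)
        np.testing.assert_allclose(backprop_d_generic(e, sig, np.ones(1)), e * fp)

    def test_zero_loss_gradient_gives_zero_d(self):
        sig = sigma_lif(np.full((5, 2), 0.4), 1.0, 1.0)
        np.testing.assert_array_equal(
            backprop_d_generic(np.zeros((5, 2)), sig, np.ones(5)), 0.0)

    def test_two_step_hand_formula(self, rng):
        # T=2, one neuron: d[1] = e[1] f'[1];
        # d[0] = e[0] f'[0] + e[1] f'[1] (alpha - theta f'[0]).
        alpha, theta = 0.9, 1.3
        e, fp = rng.normal(size=(2, 1)), rng.uniform(0, 1, size=(2, 1))
        d = backprop_d_lif(e, fp, alpha, theta)
        assert d[1, 0] == pytest.approx(e[1, 0] * fp[1, 0])
        expect = e[0, 0] * fp[0, 0] + e[1, 0] * fp[1, 0] * (alpha - theta * fp[0, 0])
        assert d[0, 0] == pytest.approx(expect)

    def test_recursion_matches_zeta_sum_and_generic(self, rng):
        # Oracle chain: literal sigma double sum == literal zeta sum == O(T)
        # recursion, for LIF kernels.
        for trial in range(100):
            T, N = int(rng.integers(2, 33)), int(rng.integers(1, 9))
            alpha = (1.0, 0.9, 0.5)[trial % 3]
            theta = float(rng.uniform(0.5, 2.0))
            fp = rng.uniform(0, 1.2, size=(T, N))
            e = rng.normal(size=(T, N))
            kern = make_lif_kernels(alpha, theta, T)
            d_fast = backprop_d_lif(e, fp, alpha, theta)
            d_generic = backprop_d_generic(e, sigma_generic(fp, kern.nu), kern.epsilon)
            np.testing.assert_allclose(d_fast, d_generic, rtol=0, atol=1e-10)
            # literal zeta-weighted sum: d[n] = sum_{k>=n} e[k] f'[k] zeta_n[k]
            zeta = zeta_products(fp, alpha, theta)
            d_zeta = np.array([(e * fp * zeta[n]).sum(axis=0) for n in range(T)])
            np.testing.assert_allclose(d_fast, d_zeta, rtol=0, atol=1e-10)

    def test_zero_surrogate_gives_zero_d(self):
        np.testing.assert_array_equal(
            backprop_d_lif(np.ones((6, 2)), np.zeros((6, 2)), 0.9, 1.0), 0.0)

    def test_operation_count_linear_in_horizon(self, rng):
        counts = {}
        for T in (32, 64):
            e, fp = rng.normal(size=(T, 4)), rng.uniform(0, 1, size=(T, 4))
            counter = OpCounter()
            backprop_d_lif(e, fp, 0.9, 1.0, counter)
            counts[T] = counter.count
        assert counts[64] <= 2.2 * counts[32]


class TestWeightGradient:
    def test_silent_presynaptic_layer_gives_zero(self, rng):
        d = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(
            weight_gradient(d, SpikeRaster(np.zeros((5, 2), dtype=int))), 0.0)

    def test_single_outer_product(self):
        g = weight_gradient(np.array([[1.0, -1.0]]), SpikeRaster(np.array([[1, 0]])))
        np.testing.assert_array_equal(g, [[1, 0], [-1, 0]])

    def test_permutation_symmetry(self, rng):
        d = rng.normal(size=(6, 3))
        s = (rng.random((6, 4)) < 0.5).astype(int)
        g = weight_gradient(d, SpikeRaster(s))
        perm_out, perm_in = rng.permutation(3), rng.permutation(4)
        g_perm = weight_gradient(d[:, perm_out], SpikeRaster(s[:, perm_in]))
        np.testing.assert_array_equal(g_perm, g[np.ix_(perm_out, perm_in)])


class TestExodusBackward:
    def test_zero_loss_gradient_gives_all_zero(self, rng):
        layers, raster, _ = random_lif_stack(rng, (4, 3, 2), 12, 0.9)
        caches = forward_network(layers, raster)
        gs = exodus_backward(caches, layers, raster, np.zeros((12, 2)))
        for grads in (gs.e, gs.d, gs.weight_grads):
            for g in grads:
                np.testing.assert_array_equal(g, 0.0)

    def test_single_layer_unit_horizon_closed_form(self, rng):
        # L=1, T=1: dL/dW = (e_out * f'[0]) outer s_in[0].
        layer = LayerParams(weights=rng.normal(size=(2, 3)),
                            neuron=NeuronConfig.lif(0.9, 1.0, 1))
        raster = SpikeRaster(np.array([[1, 0, 1]]))
        caches = forward_network([layer], raster)
        e_out = rng.normal(size=(1, 2))
        gs = exodus_backward(caches, [layer], raster, e_out)
        expect = np.outer(e_out[0] * caches[0].f_prime[0], raster.data[0])
        np.testing.assert_allclose(gs.weight_grads[0], expect)

    def test_fast_and_generic_paths_agree(self, rng):
        for trial in range(15):
            sizes = [int(rng.integers(1, 7)) for _ in range(int(rng.integers(2, 4)))]
            layers, raster, e_out = random_lif_stack(rng, sizes, int(rng.integers(2, 25)),
                                                     (1.0, 0.9, 0.5)[trial % 3])
            caches = forward_network(layers, raster)
            gs_f = exodus_backward(caches, layers, raster, e_out, method="fast")
            gs_g = exodus_backward(caches, layers, raster, e_out, method="generic")
            for a, b in zip(gs_f.weight_grads, gs_g.weight_grads):
                np.testing.assert_allclose(a, b, rtol=0, atol=1e-10)

    def test_backward_uses_cached_surrogate_values(self, rng):
        # The surrogate derivative is evaluated once in the forward pass; the
        # backward pass must consume exactly those cached values, so altering
        # the cache must alter the gradients (no silent re-evaluation from u).
        layers, raster, e_out = random_lif_stack(rng, (3, 2), 10, 0.9)
        caches = forward_network(layers, raster)
        gs = exodus_backward(caches, layers, raster, e_out)
        tampered = [dataclasses.replace(c, f_prime=2.0 * c.f_prime + 0.1) for c in caches]
        gs2 = exodus_backward(tampered, layers, raster, e_out)
        assert not np.allclose(gs.weight_grads[0], gs2.weight_grads[0])

    def test_cache_parameter_mismatch_rejected(self, rng):
        layers, raster, e_out = random_lif_stack(rng, (3, 4, 2), 10, 0.9)
        caches = forward_network(layers, raster)
        with pytest.raises(ValueError):
            exodus_backward(caches[:1], layers, raster, e_out)
        with pytest.raises(ValueError):
            exodus_backward(caches, layers, raster, np.zeros((10, 5)))
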