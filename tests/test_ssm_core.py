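"""Diagonal-SSM numerics: initialization, ZOH discretization, kernels,
and the FFT-convolution / recurrence equivalence."""

import cmath

import numpy as np
import pytest

from cardiossm.ssm_core import (
    ContinuousDiagonalSSM,
    DiscreteDiagonalSSM,
    causal_fft_convolve,
    discretize_zoh,
    init_s4d,
    load_ssm,
    materialize_kernel,
    recurrent_scan,
    save_ssm,
)


class TestInit:
    def test_linear_init_mode_placement(self):
        ssm = init_s4d(1, 4, (1e-3, 1e-1), seed=7)
        np.testing.assert_allclose(ssm.a[0], [-0.5 + 0j, -0.5 + np.pi * 1j])

    def test_seeded_determinism(self):
        a = init_s4d(3, 16, (1e-3, 1e-1), seed=7)
        b = init_s4d(3, 16, (1e-3, 1e-1), seed=7)
        for x, y in [(a.a, b.a), (a.c, b.c), (a.d, b.d), (a.log_delta, b.log_delta)]:
            np.testing.assert_array_equal(x, y)

    def test_stability_by_construction(self):
        ssm = init_s4d(2, 8, seed=0)
        assert np.all(ssm.a.real == -0.5)
        d = discretize_zoh(ssm)
        assert np.all(np.abs(d.a_bar) <= 1.0)

    def test_delta_within_range(self):
        ssm = init_s4d(5, 8, (1e-3, 1e-1), seed=3)
        assert np.all((ssm.delta >= 1e-3) & (ssm.delta <= 1e-1))

    @pytest.mark.parametrize("bad", [3, 7, 1])
    def test_odd_state_size_rejected(self, bad):
        with pytest.raises(ValueError, match="even"):
            init_s4d(1, bad, seed=0)

    @pytest.mark.parametrize("rng_pair", [(0.0, 0.1), (-1e-3, 0.1), (0.1, 0.1)])
    def test_bad_delta_range_rejected(self, rng_pair):
        with pytest.raises(ValueError):
            init_s4d(1, 4, rng_pair, seed=0)

    def test_unstable_mode_rejected(self):
        with pytest.raises(ValueError, match="real"):
            ContinuousDiagonalSSM(
                a=[[0.1 + 1j]], b=[[1.0]], c=[[1.0]], d=[0.0], log_delta=[-2.0]
            )


class TestZOH:
    def test_scalar_closed_form(self):
        # a = -1, delta = ln 2  =>  a_bar = 1/2, b_bar = (1/2 - 1)/(-1) = 1/2
        ssm = ContinuousDiagonalSSM(
            a=[[-1.0 + 0j]], b=[[1.0]], c=[[1.0]], d=[0.0],
            log_delta=[np.log(np.log(2.0))],
        )
        d = discretize_zoh(ssm)
        np.testing.assert_allclose(d.a_bar[0, 0], 0.5, rtol=1e-12)
        np.testing.assert_allclose(d.b_bar[0, 0], 0.5, rtol=1e-12)

    def test_zero_mode_limit(self):
        ssm = ContinuousDiagonalSSM(
            a=[[0.0 + 0j]], b=[[1.0]], c=[[1.0]], d=[0.0], log_delta=[np.log(0.01)]
        )
        d = discretize_zoh(ssm)
        np.testing.assert_allclose(d.a_bar[0, 0], 1.0)
        np.testing.assert_allclose(d.b_bar[0, 0], 0.01)

    def test_zero_step_identity(self):
        # delta -> 0 gives a_bar -> 1, b_bar -> 0 for any stable a
        ssm = ContinuousDiagonalSSM(
            a=[[-2.0 + 3j]], b=[[1.5 - 0.5j]], c=[[1.0]], d=[0.0],
            log_delta=[np.log(1e-300)],
        )
        d = discretize_zoh(ssm)
        np.testing.assert_allclose(d.a_bar[0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(abs(d.b_bar[0, 0]), 0.0, atol=1e-12)

    def test_matches_independent_scalar_evaluation(self, rng):
        # oracle: per-mode cmath evaluation of exp(da) and (exp(da)-1)/a
        n = 1000
        a = -rng.uniform(1e-6, 5.0, n) + 1j * rng.normal(0, 20, n)
        delta = rng.uniform(1e-4, 0.5, n)
        b = rng.normal(size=n) + 1j * rng.normal(size=n)
        # delta is per-channel, so store one mode per channel
        ssm = ContinuousDiagonalSSM(
            a=a[:, None], b=b[:, None], c=np.ones((n, 1)), d=np.zeros(n),
            log_delta=np.log(delta),
        )
        d = discretize_zoh(ssm)
        for i in range(n):
            ab = cmath.exp(delta[i] * a[i])
            bb = (cmath.exp(delta[i] * a[i]) - 1.0) / a[i] * b[i]
            assert abs(d.a_bar[i, 0] - ab) <= 1e-12 * abs(ab)
            assert abs(d.b_bar[i, 0] - bb) <= 1e-12 * max(abs(bb), 1e-300)
        assert np.all(np.abs(d.a_bar) <= 1.0 + 1e-15)


class TestKernel:
    def test_single_real_mode_power_series(self):
        d = DiscreteDiagonalSSM(a_bar=[[0.5]], b_bar=[[0.5]], c=[[1.0]], d=[0.0])
        k = materialize_kernel(d, 4, conjugate_pairs=False)
        np.testing.assert_allclose(k.values[0], [0.5, 0.25, 0.125, 0.0625])

    def test_length_one(self):
        d = DiscreteDiagonalSSM(
            a_bar=[[0.3 + 0.1j, 0.2j]], b_bar=[[1.0, 0.5]],
            c=[[2.0 + 1j, 1.0]], d=[0.0],
        )
        k = materialize_kernel(d, 1)
        expected = 2.0 * np.real(np.sum(d.c * d.b_bar))
        np.testing.assert_allclose(k.values[0, 0], expected)

    def test_conjugate_pair_reduction_residue(self, rng):
        # explicit full-spectrum evaluation: modes plus their conjugates give
        # an imaginary part that must cancel to ~machine precision
        ssm = init_s4d(2, 16, seed=4)
        d = discretize_zoh(ssm)
        L = 256
        n = np.arange(L)
        full = np.concatenate([d.c * d.b_bar, np.conj(d.c * d.b_bar)], axis=1)
        full_a = np.concatenate([d.a_bar, np.conj(d.a_bar)], axis=1)
        k_full = np.einsum("hm,hmn->hn", full, full_a[:, :, None] ** n)
        assert np.abs(k_full.imag).max() < 1e-10
        k = materialize_kernel(d, L)
        np.testing.assert_allclose(k.values, k_full.real, atol=1e-10)

    def test_nonpositive_length_rejected(self):
        d = DiscreteDiagonalSSM(a_bar=[[0.5]], b_bar=[[1.0]], c=[[1.0]], d=[0.0])
        with pytest.raises(ValueError):
            materialize_kernel(d, 0)

    def test_decay_envelope(self):
        ssm = init_s4d(3, 8, seed=9)
        d = discretize_zoh(ssm)
        k = materialize_kernel(d, 128)
        env = 2 * np.sum(
            np.abs(d.c * d.b_bar)[:, :, None]
            * np.abs(d.a_bar)[:, :, None] ** np.arange(128),
            axis=1,
        )
        assert np.all(np.abs(k.values) <= env + 1e-12)
        assert np.all(np.diff(env, axis=1) <= 1e-12)  # non-increasing bound


class TestConvolutionVsRecurrence:
    def test_impulse_reproduces_kernel(self):
        ssm = init_s4d(2, 8, seed=1)
        d = discretize_zoh(ssm)
        k = materialize_kernel(d, 32)
        u = np.zeros((2, 32))
        u[:, 0] = 1.0
        y = causal_fft_convolve(u, k)
        np.testing.assert_allclose(y, k.values, atol=1e-10)

    def test_zero_input(self):
        ssm = init_s4d(1, 4, seed=2)
        k = materialize_kernel(discretize_zoh(ssm), 16)
        np.testing.assert_array_equal(causal_fft_convolve(np.zeros((1, 16)), k), 0)

    def test_length_mismatch_rejected(self):
        ssm = init_s4d(1, 4, seed=2)
        k = materialize_kernel(discretize_zoh(ssm), 16)
        with pytest.raises(ValueError, match="length"):
            causal_fft_convolve(np.zeros((1, 17)), k)

    @pytest.mark.parametrize("seed", range(25))
    def test_fft_matches_recurrence(self, seed):
        g = np.random.default_rng(seed)
        h = int(g.integers(1, 5))
        n = 2 * int(g.integers(1, 17))
        L = int(g.integers(2, 513))
        ssm = init_s4d(h, n, seed=g)
        d = discretize_zoh(ssm)
        u = g.standard_normal((h, L))
        y_fft = causal_fft_convolve(u, materialize_kernel(d, L)) + d.d[:, None] * u
        y_scan = recurrent_scan(d, u)
        scale = max(1.0, np.abs(y_scan).max())
        assert np.abs(y_fft - y_scan).max() / scale < 1e-5

    def test_causality(self):
        g = np.random.default_rng(0)
        ssm = init_s4d(2, 8, seed=3)
        k = materialize_kernel(discretize_zoh(ssm), 64)
        u = g.standard_normal((2, 64))
        y0 = causal_fft_convolve(u, k)
        m = 40
        u2 = u.copy()
        u2[:, m] += 1.0
        y1 = causal_fft_convolve(u2, k)
        np.testing.assert_allclose(y0[:, :m], y1[:, :m], atol=1e-9)
        assert np.abs(y1[:, m:] - y0[:, m:]).max() > 1e-8

    def test_real_output_from_real_input(self):
        ssm = init_s4d(2, 16, seed=5)
        d = discretize_zoh(ssm)
        u = np.random.default_rng(1).standard_normal((2, 100))
        y = recurrent_scan(d, u)
        assert np.isrealobj(y)


class TestRecurrentScan:
    def test_first_step_closed_form(self):
        d = DiscreteDiagonalSSM(
            a_bar=[[0.7 + 0.1j]], b_bar=[[0.4 - 0.2j]], c=[[1.0 + 1j]], d=[0.3]
        )
        u = np.array([[2.0]])
        y = recurrent_scan(d, u)
        expected = 2 * np.real((1 + 1j) * (0.4 - 0.2j)) * 2.0 + 0.3 * 2.0
        np.testing.assert_allclose(y[0, 0], expected)

    def test_zero_input_gives_zero(self):
        ssm = init_s4d(1, 4, seed=0)
        y = recurrent_scan(discretize_zoh(ssm), np.zeros((1, 20)))
        np.testing.assert_array_equal(y, 0)

    def test_memoryless_when_a_bar_zero(self):
        # a_bar = 0 wipes state each step: y_n = 2 Re(C B) u_n + D u_n
        d = DiscreteDiagonalSSM(
            a_bar=[[0.0, 0.0]], b_bar=[[0.5, 0.25j]], c=[[1.0 + 1j, 2.0]], d=[0.1]
        )
        u = np.random.default_rng(3).standard_normal((1, 10))
        gain = 2 * np.real(np.sum(d.c * d.b_bar)) + 0.1
        np.testing.assert_allclose(recurrent_scan(d, u), gain * u, atol=1e-12)


def test_serialization_round_trip(tmp_path):
    ssm = init_s4d(3, 8, seed=11)
    path = tmp_path / "ssm.npz"
    save_ssm(ssm, path)
    back = load_ssm(path)
    for x, y in [(ssm.a, back.a), (ssm.b, back.b), (ssm.c, back.c),
                 (ssm.d, back.d), (ssm.log_delta, back.log_delta)]:
        np.testing.assert_array_equal(x, y)
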