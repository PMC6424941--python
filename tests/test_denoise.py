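"""Denoising: operators, energy, and the PDHG solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import t1forge as tf
from t1forge.denoise import _stack_weights


SPACINGS = [(1.0, 1.0, 1.0), (1.4, 1.4, 8.0), (0.5, 2.0, 3.0)]


class TestOperators:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        shape=st.tuples(st.integers(2, 7), st.integers(2, 7), st.integers(2, 7)),
        spacing=st.sampled_from(SPACINGS),
    )
    def test_divergence_is_negative_adjoint(self, seed, shape, spacing):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(shape)
        p = rng.standard_normal((3,) + shape)
        lhs = np.sum(tf.gradient(u, spacing) * p)
        rhs = -np.sum(u * tf.divergence(p, spacing))
        scale = np.linalg.norm(u) * np.linalg.norm(p)
        assert abs(lhs - rhs) <= 1e-12 * scale

    def test_constant_volume_zero_gradient_unit_weights(self):
        vol = np.full((5, 5, 3), 7.0)
        wg = tf.weighted_gradient(vol, h=5.0, spacing=(1, 1, 1))
        assert np.all(wg == 0)
        assert np.all(tf.gradient_weights(vol, 5.0, (1, 1, 1)) == 1.0)

    def test_ramp_weight_value(self):
        # m(x) = x, unit spacing: unweighted gradient 1, w = exp(-1/25)
        x = np.arange(8, dtype=float)
        vol = np.broadcast_to(x[:, None, None], (8, 4, 3)).copy()
        wg = tf.weighted_gradient(vol, h=5.0, spacing=(1, 1, 1))
        interior = wg[0, :-1]
        expected = np.exp(-1.0 / 25.0)
        assert expected == pytest.approx(0.9608, abs=1e-4)
        assert np.allclose(interior, expected)
        assert np.allclose(wg[1:], 0)

    def test_step_edge_weight_vanishes(self):
        vol = np.zeros((8, 4, 3))
        vol[4:] = 1000.0  # step height >> h
        w = tf.gradient_weights(vol, h=5.0, spacing=(1, 1, 1))
        assert w[3].max() < 1e-9  # at the edge
        assert np.all(w[[0, 1, 5, 6]] == 1.0)  # flat regions untouched

    def test_nonpositive_h_rejected(self):
        with pytest.raises(ValueError, match="h"):
            tf.weighted_gradient(np.zeros((3, 3, 3)), h=0.0, spacing=(1, 1, 1))

    def test_anisotropic_spacing_scales_gradient(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((6, 6, 6))
        g_mm = tf.gradient(vol, (1.4, 1.4, 8.0))
        g_ix = tf.gradient(vol, (1.0, 1.0, 1.0))
        assert np.allclose(g_mm[2], g_ix[2] / 8.0)


def _loop_energy(candidate, observed, params):
    """Slow direct evaluation of the energy by explicit summation (oracle)."""
    sp = candidate.voxel_spacing_mm
    n = candidate.n
    fid = 0.0
    for i in range(n):
        fid += np.sum((candidate.data[i] - observed.data[i]) ** 2)
    nx, ny, nz = candidate.grid_shape
    reg = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                total = 0.0
                for i in range(n):
                    vol = candidate.data[i]
                    gx = (vol[x + 1, y, z] - vol[x, y, z]) / sp[0] if x < nx - 1 else 0.0
                    gy = (vol[x, y + 1, z] - vol[x, y, z]) / sp[1] if y < ny - 1 else 0.0
                    gz = (vol[x, y, z + 1] - vol[x, y, z]) / sp[2] if z < nz - 1 else 0.0
                    g2 = gx * gx + gy * gy + gz * gz
                    w = np.exp(-g2 / params.h**2)
                    total += w * w * g2
                reg += np.sqrt(1.0 + params.beta**2 * total)
    return fid + params.lam * reg


class TestEnergy:
    def test_constant_candidate_equals_lambda_v(self):
        data = np.full((2, 4, 4, 2), 5.0)
        stack = tf.ContrastStack(data, [100.0, np.inf])
        e = tf.beltrami_energy(stack, stack, tf.DenoiseParams(lam=0.7))
        assert e == pytest.approx(0.7 * 32)  # lam * number of voxels

    def test_lambda_zero_is_pure_fidelity(self, random_stack):
        other = random_stack.copy()
        other.data += 0.5
        e = tf.beltrami_energy(other, random_stack, tf.DenoiseParams(lam=0.0))
        assert e == pytest.approx(np.sum((other.data - random_stack.data) ** 2))

    def test_single_voxel_perturbation_vs_loop_oracle(self):
        data = np.full((2, 5, 4, 3), 2.0)
        observed = tf.ContrastStack(data, [100.0, np.inf], (1.4, 1.4, 8.0))
        cand = observed.copy()
        cand.data[0, 2, 1, 1] += 0.75
        params = tf.DenoiseParams(lam=0.3, beta=1.5, h=2.0)
        e = tf.beltrami_energy(cand, observed, params)
        assert e == pytest.approx(_loop_energy(cand, observed, params), rel=1e-12)
        # fidelity contribution is exactly delta^2
        e0 = tf.beltrami_energy(cand, observed, tf.DenoiseParams(lam=0.0))
        assert e0 == pytest.approx(0.75**2)

    def test_random_stack_vs_loop_oracle(self, random_stack):
        rng = np.random.default_rng(3)
        cand = random_stack.copy()
        cand.data += 0.2 * rng.standard_normal(cand.data.shape)
        params = tf.DenoiseParams(lam=0.25, beta=1.0, h=5.0)
        assert tf.beltrami_energy(cand, random_stack, params) == pytest.approx(
            _loop_energy(cand, random_stack, params), rel=1e-12
        )

    def test_shape_mismatch_rejected(self, random_stack):
        other = tf.ContrastStack(
            np.zeros((3, 4, 4, 4)), random_stack.contrast_times_ms
        )
        with pytest.raises(ValueError, match="mismatch"):
            tf.beltrami_energy(other, random_stack, tf.DenoiseParams())


class TestSolver:
    def test_identity_at_lambda_zero(self, random_stack):
        out, report = tf.denoise_stack(random_stack, tf.DenoiseParams(lam=0.0))
        assert np.array_equal(out.data, random_stack.data)
        assert report.converged

    def test_noise_sd_reduced_on_constant_stack(self):
        rng = np.random.default_rng(5)
        clean = np.full((3, 16, 16, 4), 1000.0)
        noisy = clean + rng.normal(0, 20.0, clean.shape)
        stack = tf.ContrastStack(noisy, [100.0, 400.0, np.inf], (1.4, 1.4, 8.0))
        out, _ = tf.denoise_stack(stack)
        for i in range(3):
            assert out.data[i].std() < stack.data[i].std()

    def test_output_metadata_preserved(self, random_stack):
        out, _ = tf.denoise_stack(random_stack)
        assert out.grid_shape == random_stack.grid_shape
        assert out.n == random_stack.n
        assert np.array_equal(out.contrast_times_ms, random_stack.contrast_times_ms)
        assert out.voxel_spacing_mm == random_stack.voxel_spacing_mm

    def test_energy_of_output_below_input(self, random_stack):
        params = tf.DenoiseParams()
        out, report = tf.denoise_stack(random_stack, params)
        w_final = _stack_weights(
            out.data / report.normalization_scale, params.h,
            random_stack.voxel_spacing_mm,
        )
        scaled_out = out.copy()
        scaled_out.data /= report.normalization_scale
        scaled_in = random_stack.copy()
        scaled_in.data /= report.normalization_scale
        e_out = tf.beltrami_energy(scaled_out, scaled_in, params, weights=w_final)
        e_in = tf.beltrami_energy(scaled_in, scaled_in, params, weights=w_final)
        assert e_out < e_in

    def test_shift_equivariance_without_normalization(self, random_stack):
        params = tf.DenoiseParams(normalize=False, max_iters=200, tol=1e-9)
        out1, _ = tf.denoise_stack(random_stack, params)
        shifted = random_stack.copy()
        shifted.data += 100.0
        out2, _ = tf.denoise_stack(shifted, params)
        assert np.allclose(out2.data, out1.data + 100.0, atol=1e-6)

    def test_contrast_permutation_symmetry(self, random_stack):
        params = tf.DenoiseParams(max_iters=100)
        out, _ = tf.denoise_stack(random_stack, params)
        perm = [2, 0, 1]
        permuted = tf.ContrastStack(
            random_stack.data[perm],
            random_stack.contrast_times_ms[perm],
            random_stack.voxel_spacing_mm,
        )
        out_p, _ = tf.denoise_stack(permuted, params)
        assert np.allclose(out_p.data, out.data[perm], atol=1e-10)

    def test_pdhg_matches_descent_oracle_small(self):
        """Fixed-weight PDHG solution equals a long-run first-order descent."""
        rng = np.random.default_rng(0)
        st_ = tf.ContrastStack(
            rng.standard_normal((2, 5, 5, 3)), [300.0, np.inf], (1.0, 1.0, 1.0)
        )
        params = tf.DenoiseParams(
            weight_update_every=0, normalize=False, max_iters=3000, tol=1e-12
        )
        out, report = tf.denoise_stack(st_, params)
        m = _descent_oracle(st_, params, n_iter=5000)
        assert np.linalg.norm(out.data - m) / np.linalg.norm(m) < 1e-6

    def test_step_size_validation(self, random_stack):
        with pytest.raises(ValueError, match="convergence condition"):
            tf.denoise_stack(
                random_stack, tf.DenoiseParams(tau=100.0, sigma_dual=100.0)
            )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(lam=-0.1),
            dict(beta=0.0),
            dict(h=-1.0),
            dict(max_iters=0),
            dict(tol=0.0),
            dict(weight_update_every=-1),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            tf.DenoiseParams(**bad)


def _descent_oracle(stack, params, n_iter=5000):
    """Plain gradient descent on the identical fixed-weight energy (oracle).

    Independent of the PDHG path: evaluates the smooth energy's gradient
    directly and takes fixed steps of 1/Lipschitz.
    """
    sp = stack.voxel_spacing_mm
    n = stack.n
    w = _stack_weights(stack.data, params.h, sp)
    lam, beta = params.lam, params.beta
    d = stack.data.copy()
    m = d.copy()
    L = tf.operator_norm_bound(stack.grid_shape, sp)
    step = 1.0 / (2.0 + lam * beta**2 * L * L)
    for _ in range(n_iter):
        wg = np.stack([w[i][None] * tf.gradient(m[i], sp) for i in range(n)])
        g2 = np.sum(wg * wg, axis=(0, 1))
        root = np.sqrt(1.0 + beta**2 * g2)
        grad_reg = np.stack(
            [-tf.divergence(w[i][None] * (wg[i] * beta**2 / root[None]), sp)
             for i in range(n)]
        )
        m = m - step * (2.0 * (m - d) + lam * grad_reg)
    return m
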