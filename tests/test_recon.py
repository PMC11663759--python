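"""Proximal operators, Step-1 solver, and the full LLRS ADMM."""

import numpy as np
import pytest
import scipy.linalg

from smsmap.operators import CoilMaps, ImageSeries, KSpaceData, ifft_centered
from smsmap.phantom import make_coil_maps, make_vial_phantom, simulate_acquisition
from smsmap.recon import (
    ReconParams,
    _svt_batch,
    reconstruct_llrs,
    soft_threshold,
    solve_step1,
    svt,
    zero_filled,
)
from smsmap.sampling import SamplingPattern, make_super_caipirinha
from smsmap.sequence import build_default_schedule


def _rand_c(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


class TestSvt:
    def test_zero_threshold_is_identity(self, rng):
        M = _rand_c(rng, (5, 3))
        np.testing.assert_allclose(svt(M, 0.0), M, atol=1e-12)

    def test_threshold_above_spectrum_gives_zero(self, rng):
        M = _rand_c(rng, (5, 3))
        smax = np.linalg.svd(M, compute_uv=False)[0]
        assert not svt(M, smax + 1e-9).any()

    def test_matches_nuclear_norm_prox_optimality(self, rng):
        # svt(M, tau) must minimize 0.5||Z-M||_F^2 + tau ||Z||_*: check the
        # objective against random perturbations and an independent SVD route
        M = _rand_c(rng, (5, 3))
        tau = 0.3
        Z = svt(M, tau)

        def objective(A):
            return 0.5 * np.linalg.norm(A - M) ** 2 + tau * np.sum(
                scipy.linalg.svdvals(A)
            )

        f0 = objective(Z)
        for _ in range(200):
            step = 10 ** rng.uniform(-4, -1)
            pert = Z + step * _rand_c(rng, Z.shape)
            assert objective(pert) >= f0 - 1e-12
        # independent closed form via scipy
        U, s, Vh = scipy.linalg.svd(M, full_matrices=False)
        Z_ref = (U * np.maximum(s - tau, 0.0)) @ Vh
        np.testing.assert_allclose(Z, Z_ref, atol=1e-12)

    def test_batched_path_matches_direct_svd_path(self, rng):
        M = _rand_c(rng, (40, 9, 4))
        tau = 0.5
        out, nuc = _svt_batch(M, tau)
        ref = np.stack([svt(m, tau) for m in M])
        np.testing.assert_allclose(out, ref, atol=1e-10)
        assert nuc == pytest.approx(
            sum(np.linalg.svd(m, compute_uv=False).sum() for m in ref), abs=1e-8
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.nan, 1.0]]), 0.1)


class TestSoftThreshold:
    def test_zero_threshold_is_identity(self, rng):
        c = _rand_c(rng, 20)
        np.testing.assert_array_equal(soft_threshold(c, 0.0), c)

    def test_below_threshold_zeroed(self, rng):
        c = 0.1 * _rand_c(rng, 20)
        assert not soft_threshold(c, 1.0).any()

    def test_real_scalar_closed_form(self):
        assert soft_threshold(np.array([1.5]), 0.5)[0] == pytest.approx(1.0)

    def test_complex_shrinks_magnitude_keeps_phase(self, rng):
        c = _rand_c(rng, 50)
        out = soft_threshold(c, 0.2)
        nz = np.abs(c) > 0.2
        np.testing.assert_allclose(np.abs(out[nz]), np.abs(c[nz]) - 0.2, atol=1e-12)
        np.testing.assert_allclose(np.angle(out[nz]), np.angle(c[nz]), atol=1e-12)


class TestStep1:
    def test_matches_dense_solve(self, rng):
        mb, T, nx, ny, nc = 2, 3, 8, 8, 2
        coils = make_coil_maps(nx, ny, mb, nc, seed=3)
        pat = make_super_caipirinha(ny, mb, 2, T, center_lines=2)
        from smsmap.operators import forward

        xt = _rand_c(rng, (mb, T, nx, ny))
        y = forward(ImageSeries(xt), coils, pat)
        params = ReconParams(
            mu1=0.01, mu2=0.005, block=3, cg_tol=1e-13, cg_max_iter=500
        )
        z = np.zeros((mb, nx * ny, 9, T), complex)
        v = np.zeros((mb, T, nx, ny), complex)
        x_cg, _ = solve_step1(y, z, v, coils, params)

        n = mb * T * nx * ny
        A = np.zeros((y.samples.size, n), complex)
        for i in range(n):
            e = np.zeros(n, complex)
            e[i] = 1.0
            A[:, i] = forward(
                ImageSeries(e.reshape(mb, T, nx, ny)), coils, pat
            ).samples.ravel()
        c = params.mu1 * 9 + params.mu2
        H = A.conj().T @ A + c * np.eye(n)
        x_dense = np.linalg.solve(H, A.conj().T @ y.samples.ravel())
        np.testing.assert_allclose(x_cg.ravel(), x_dense, atol=1e-8)

    def test_normal_operator_positive_definite(self, rng):
        mb, T, nx, ny = 2, 2, 8, 8
        coils = make_coil_maps(nx, ny, mb, 3, seed=5)
        pat = make_super_caipirinha(ny, mb, 2, T, center_lines=2)
        from smsmap.recon import _NormalSystem

        system = _NormalSystem(coils.sens, pat.mask, 0.01)
        for _ in range(10):
            u = _rand_c(rng, (T, nx, ny, mb))
            assert np.vdot(u, system.matvec(u)).real > 0

    def test_unregularized_full_sampling_unit_coil_is_inverse_fft(self, rng):
        T, nx, ny = 2, 8, 8
        coils = CoilMaps(np.ones((1, 1, nx, ny), dtype=complex))
        pat = SamplingPattern(
            mask=np.ones((T, ny, 1), dtype=bool),
            r_inplane=1,
            mb=1,
            super_shifts=np.zeros(T, dtype=int),
            center_lines=0,
            acs_mask=np.ones((1, ny), dtype=bool),
        )
        yk = _rand_c(rng, (1, T, nx, ny, 1))
        y = KSpaceData(yk, pat)
        params = ReconParams(cg_tol=1e-12, cg_max_iter=50)
        x, _ = solve_step1(y, None, None, coils, params)
        expected = ifft_centered(yk, axes=(-3, -2, -1))[0, :, :, :, 0][None]
        np.testing.assert_allclose(x, expected, atol=1e-10)


class TestLlrs:
    def test_default_params_match_published_settings(self):
        p = ReconParams()
        assert p.block == 7
        assert p.alpha == pytest.approx(10.0**-3.75)
        assert p.mu1 == pytest.approx(10.0**-2.75)
        assert p.beta == pytest.approx(1e-4)
        assert p.mu2 == pytest.approx(1e-3)
        assert p.max_iter == 100

    def test_noiseless_fully_sampled_consistency(self):
        # alpha, beta -> 0 with full sampling: the solution is the data
        schedule = build_default_schedule(60.0)
        phantom = make_vial_phantom(32, 32, 1)
        pat = make_super_caipirinha(32, 1, 1, schedule.n_imaging, center_lines=0)
        coils = CoilMaps(np.ones((1, 1, 32, 32), dtype=complex))
        sim = simulate_acquisition(phantom, schedule, pat, coils, noise_sd=0.0)
        params = ReconParams(alpha=1e-12, beta=1e-12, max_iter=10, block=3)
        recon, _ = reconstruct_llrs(sim.kspace, coils, params)
        nrmse = np.linalg.norm(recon.data - sim.truth.data) / np.linalg.norm(
            sim.truth.data
        )
        assert nrmse < 1e-3

    def test_llrs_beats_zero_filled_on_multiband_problem(self, standard_problem):
        sim = standard_problem["sim"]
        coils = standard_problem["coils"]
        recon, _ = reconstruct_llrs(sim.kspace, coils, ReconParams(max_iter=25))
        err = np.linalg.norm(recon.data - sim.truth.data)
        err_zf = np.linalg.norm(zero_filled(sim.kspace, coils).data - sim.truth.data)
        assert err < err_zf

    def test_deterministic_given_seed_with_tiled_blocks(self, standard_problem):
        sim = standard_problem["sim"]
        coils = standard_problem["coils"]
        params = ReconParams(block=3, block_mode="shifted_nonoverlap", max_iter=4, seed=11)
        r1, _ = reconstruct_llrs(sim.kspace, coils, params)
        r2, _ = reconstruct_llrs(sim.kspace, coils, params)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_cg_sense_inverts_unitary_system_and_beats_zero_fill(
        self, rng, standard_problem
    ):
        from smsmap.recon import cg_sense

        T, nx, ny = 3, 16, 16
        coils = CoilMaps(np.ones((1, 1, nx, ny), dtype=complex))
        pat = SamplingPattern(
            mask=np.ones((T, ny, 1), dtype=bool),
            r_inplane=1,
            mb=1,
            super_shifts=np.zeros(T, dtype=int),
            center_lines=0,
            acs_mask=np.ones((1, ny), dtype=bool),
        )
        x = _rand_c(rng, (1, T, nx, ny))
        from smsmap.operators import forward

        y = forward(ImageSeries(x), coils, pat)
        np.testing.assert_allclose(cg_sense(y, coils).data, x, atol=1e-10)

        sim = standard_problem["sim"]
        cmaps = standard_problem["coils"]
        err = np.linalg.norm(cg_sense(sim.kspace, cmaps, max_iter=15).data - sim.truth.data)
        err_zf = np.linalg.norm(zero_filled(sim.kspace, cmaps).data - sim.truth.data)
        assert err < err_zf

    def test_all_zero_input_rejected(self, standard_problem):
        pat = standard_problem["pattern"]
        coils = standard_problem["coils"]
        shape = standard_problem["sim"].kspace.samples.shape
        with pytest.raises(ValueError, match="zero"):
            reconstruct_llrs(KSpaceData(np.zeros(shape, complex), pat), coils)
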