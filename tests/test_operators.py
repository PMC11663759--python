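"""Adjointness, unitarity and normal-operator identities of the encoding chain."""

import numpy as np
import pytest

from smsmap.operators import (
    CoilMaps,
    ImageSeries,
    KSpaceData,
    adjoint,
    assemble_blocks,
    extract_blocks,
    forward,
    wavelet_adjoint,
    wavelet_forward,
)
from smsmap.phantom import make_coil_maps
from smsmap.sampling import SamplingPattern, make_super_caipirinha


def _rand_c(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _full_pattern(T, ny, mb=1):
    return SamplingPattern(
        mask=np.ones((T, ny, mb), dtype=bool),
        r_inplane=1,
        mb=mb,
        super_shifts=np.zeros(T, dtype=int),
        center_lines=0,
        acs_mask=np.ones((mb, ny), dtype=bool),
    )


class TestEncodingOperator:
    def test_randomized_adjoint(self, rng):
        mb, T, nx, ny, nc = 3, 4, 16, 16, 5
        coils = make_coil_maps(nx, ny, mb, nc, seed=3)
        pat = make_super_caipirinha(ny, mb, 2, T, center_lines=4)
        x = ImageSeries(_rand_c(rng, (mb, T, nx, ny)))
        y = _rand_c(rng, (nc, T, nx, ny, mb))
        lhs = np.vdot(forward(x, coils, pat).samples, y)
        rhs = np.vdot(x.data, adjoint(KSpaceData(y, pat), coils).data)
        assert abs(lhs - rhs) / (np.linalg.norm(x.data) * np.linalg.norm(y)) < 1e-10

    def test_forward_is_linear(self, rng):
        mb, T, nx, ny = 2, 3, 8, 8
        coils = make_coil_maps(nx, ny, mb, 3, seed=1)
        pat = make_super_caipirinha(ny, mb, 2, T, center_lines=2)
        a, b = 1.7 - 0.3j, -0.8 + 2.1j
        x1 = _rand_c(rng, (mb, T, nx, ny))
        x2 = _rand_c(rng, (mb, T, nx, ny))
        lhs = forward(ImageSeries(a * x1 + b * x2), coils, pat).samples
        rhs = (
            a * forward(ImageSeries(x1), coils, pat).samples
            + b * forward(ImageSeries(x2), coils, pat).samples
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_parseval_full_sampling_unit_coil(self, rng):
        T, nx, ny = 3, 16, 16
        coils = CoilMaps(np.ones((1, 1, nx, ny), dtype=complex))
        pat = _full_pattern(T, ny)
        x = ImageSeries(_rand_c(rng, (1, T, nx, ny)))
        y = forward(x, coils, pat)
        assert np.linalg.norm(y.samples) == pytest.approx(
            np.linalg.norm(x.data), abs=1e-12
        )

    def test_adjoint_of_forward_is_identity_when_unitary(self, rng):
        T, nx, ny = 3, 16, 16
        coils = CoilMaps(np.ones((1, 1, nx, ny), dtype=complex))
        pat = _full_pattern(T, ny)
        x = ImageSeries(_rand_c(rng, (1, T, nx, ny)))
        back = adjoint(forward(x, coils, pat), coils)
        np.testing.assert_allclose(back.data, x.data, atol=1e-12)

    def test_adjoint_of_zero_is_zero(self):
        T, nx, ny = 2, 8, 8
        coils = CoilMaps(np.ones((1, 1, nx, ny), dtype=complex))
        pat = _full_pattern(T, ny)
        out = adjoint(KSpaceData(np.zeros((1, T, nx, ny, 1), complex), pat), coils)
        assert not out.data.any()

    def test_shape_mismatch_rejected(self, rng):
        coils = make_coil_maps(8, 8, 2, 3, seed=0)
        pat = make_super_caipirinha(8, 2, 2, 3, center_lines=2)
        with pytest.raises(ValueError, match="inconsistent"):
            forward(ImageSeries(_rand_c(rng, (2, 3, 16, 16))), coils, pat)


class TestBlockOperator:
    def test_overlap_normal_operator_is_block_squared_identity(self, rng):
        T, nx, ny, b = 3, 16, 16, 7
        x = _rand_c(rng, (T, nx, ny))
        back = assemble_blocks(extract_blocks(x, b), b, (T, nx, ny))
        np.testing.assert_allclose(back, b * b * x, atol=1e-10)

    def test_tiled_normal_operator_is_identity(self, rng):
        T, nx, ny, b = 2, 21, 21, 7
        x = _rand_c(rng, (T, nx, ny))
        shift = (2, 5)
        blocks = extract_blocks(x, b, mode="shifted_nonoverlap", shift=shift)
        back = assemble_blocks(
            blocks, b, (T, nx, ny), mode="shifted_nonoverlap", shift=shift
        )
        np.testing.assert_allclose(back, x, atol=1e-12)

    @pytest.mark.parametrize("mode,shape", [("overlap", (3, 12, 12)), ("shifted_nonoverlap", (3, 15, 15))])
    def test_randomized_adjoint(self, rng, mode, shape):
        b = 5 if mode == "shifted_nonoverlap" else 3
        x = _rand_c(rng, shape)
        blocks = extract_blocks(x, b, mode=mode)
        u = _rand_c(rng, blocks.shape)
        lhs = np.vdot(blocks, u)
        rhs = np.vdot(x, assemble_blocks(u, b, shape, mode=mode))
        assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(u)) < 1e-10

    def test_block_one_gives_single_voxel_series(self, rng):
        T, nx, ny = 4, 6, 6
        x = _rand_c(rng, (T, nx, ny))
        blocks = extract_blocks(x, 1)
        assert blocks.shape == (nx * ny, 1, T)
        np.testing.assert_array_equal(
            blocks[:, 0, :], x.reshape(T, -1).T
        )

    def test_even_block_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            extract_blocks(_rand_c(rng, (2, 8, 8)), 4)


class TestWavelet:
    def test_roundtrip_and_isometry(self, rng):
        x = _rand_c(rng, (2, 3, 32, 32))
        c = wavelet_forward(x)
        np.testing.assert_allclose(wavelet_adjoint(c), x, atol=1e-12)
        assert np.linalg.norm(c) == pytest.approx(np.linalg.norm(x), abs=1e-10)

    def test_randomized_adjoint(self, rng):
        x = _rand_c(rng, (32, 32))
        c = wavelet_forward(x)
        y = _rand_c(rng, c.shape)
        lhs = np.vdot(c, y)
        rhs = np.vdot(x, wavelet_adjoint(y))
        assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-10

    def test_constant_image_has_zero_detail_coefficients(self):
        n = 8
        c = wavelet_forward(np.ones((n, n)))
        approx = n // 2**3
        detail = c.copy()
        detail[:approx, :approx] = 0
        np.testing.assert_allclose(detail, 0, atol=1e-12)

    def test_indivisible_size_rejected(self, rng):
        with pytest.raises(ValueError, match="pad"):
            wavelet_forward(_rand_c(rng, (12, 12)))
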