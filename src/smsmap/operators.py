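"""Linear operator algebra of the SMS encoding model ``y = D F E x``.

``E`` multiplies each slice image by each coil sensitivity, ``F`` is the
centered orthonormal 3D Fourier transform over (x, y, z=slice), and ``D``
zeroes the unsampled (contrast, ky, kz) entries. Every operator has an exact
adjoint under the standard complex inner product; the reconstruction relies on
``sum_i Bi^H Bi = block^2 * I`` (overlapping blocks with periodic wrap) and on
``W^H W = I`` (orthonormal wavelet), which make the ADMM normal matrix a
shifted identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pywt
from scipy import fft as spfft

from smsmap.sampling import SamplingPattern

__all__ = [
    "ImageSeries",
    "CoilMaps",
    "KSpaceData",
    "forward",
    "adjoint",
    "extract_blocks",
    "assemble_blocks",
    "wavelet_forward",
    "wavelet_adjoint",
]

WAVELET = "db4"
WAVELET_LEVELS = 3
_WAVELET_MODE = "periodization"


@dataclass
class ImageSeries:
    """Multislice multicontrast complex image series.

    ``data`` has shape (mb, n_contrasts, nx, ny): per simultaneous slice, one
    complex image per imaging heartbeat.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float] = (1.875, 1.875)
    slice_spacing_mm: float = 20.8  # 8 mm slice + 12.8 mm gap

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries.data must be (mb, n_contrasts, nx, ny)")

    @property
    def mb(self) -> int:
        return self.data.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class CoilMaps:
    """Complex coil sensitivities, shape (n_coils, mb, nx, ny)."""

    sens: np.ndarray

    def __post_init__(self) -> None:
        self.sens = np.asarray(self.sens)
        if self.sens.ndim != 4:
            raise ValueError("CoilMaps.sens must be (n_coils, mb, nx, ny)")

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]

    @property
    def mb(self) -> int:
        return self.sens.shape[1]


@dataclass
class KSpaceData:
    """Sampled multicoil Cartesian k-space.

    ``samples`` has shape (n_coils, n_contrasts, nx, ny, nz) with zeros at
    unsampled locations; ``pattern`` records which (contrast, ky, kz) entries
    were acquired.
    """

    samples: np.ndarray
    pattern: SamplingPattern
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 5:
            raise ValueError(
                "KSpaceData.samples must be (n_coils, n_contrasts, nx, ny, nz)"
            )


# ---------------------------------------------------------------------------
# centered orthonormal FFT helpers


def fft_centered(a: np.ndarray, axes) -> np.ndarray:
    a = np.fft.ifftshift(a, axes=axes)
    a = spfft.fftn(a, axes=axes, norm="ortho")
    return np.fft.fftshift(a, axes=axes)


def ifft_centered(a: np.ndarray, axes) -> np.ndarray:
    a = np.fft.ifftshift(a, axes=axes)
    a = spfft.ifftn(a, axes=axes, norm="ortho")
    return np.fft.fftshift(a, axes=axes)


def _check_shapes(x: ImageSeries, coils: CoilMaps, pattern: SamplingPattern) -> None:
    mb, n_contrasts, nx, ny = x.shape
    if coils.sens.shape[1:] != (mb, nx, ny):
        raise ValueError(
            f"coil maps {coils.sens.shape} inconsistent with images {x.shape}"
        )
    if pattern.mask.shape != (n_contrasts, ny, mb):
        raise ValueError(
            f"sampling mask {pattern.mask.shape} inconsistent with images {x.shape}"
        )


def forward(x: ImageSeries, coils: CoilMaps, pattern: SamplingPattern) -> KSpaceData:
    """Apply ``D F E`` to an image series (noise is added elsewhere)."""
    _check_shapes(x, coils, pattern)
    # (nc, mb, T, nx, ny) -> (nc, T, nx, ny, nz=mb)
    img = coils.sens[:, :, None, :, :] * x.data[None]
    arr = np.transpose(img, (0, 2, 3, 4, 1))
    k = fft_centered(arr, axes=(-3, -2, -1))
    k *= pattern.mask[None, :, None, :, :]
    return KSpaceData(samples=k, pattern=pattern)


def adjoint(y: KSpaceData, coils: CoilMaps) -> ImageSeries:
    """Apply ``E^H F^H D^H`` to k-space data (the zero-filled reconstruction)."""
    k = y.samples * y.pattern.mask[None, :, None, :, :]
    img = ifft_centered(k, axes=(-3, -2, -1))
    # (nc, T, nx, ny, mb) -> (nc, mb, T, nx, ny)
    img = np.transpose(img, (0, 4, 1, 2, 3))
    out = np.sum(np.conj(coils.sens)[:, :, None, :, :] * img, axis=0)
    return ImageSeries(data=out)


# ---------------------------------------------------------------------------
# block (Casorati) extraction


def _block_offsets(block: int) -> list[tuple[int, int]]:
    h = block // 2
    return [(dx, dy) for dx in range(-h, h + 1) for dy in range(-h, h + 1)]


def extract_blocks(
    x_slice: np.ndarray,
    block: int,
    mode: str = "overlap",
    shift: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Casorati matrices of spatial blocks of one slice.

    Parameters
    ----------
    x_slice
        Complex array (n_contrasts, nx, ny): the contrast series of one slice.
    block
        Odd block edge length.
    mode
        ``"overlap"``: one block centered at every voxel with periodic
        boundary wrap (n_blocks = nx*ny, and the normal operator equals
        ``block**2 * I``). ``"shifted_nonoverlap"``: disjoint tiling after a
        cyclic shift of the image (normal operator = identity); requires the
        block to divide both spatial dimensions.
    shift
        Cyclic (dx, dy) shift used by the tiled mode; drawn per ADMM call by
        the solver.

    Returns
    -------
    ndarray
        (n_blocks, block**2, n_contrasts): rows index voxels of the block,
        columns index contrasts.
    """
    if block % 2 == 0:
        raise ValueError("block edge length must be odd")
    T, nx, ny = x_slice.shape
    if block > min(nx, ny):
        raise ValueError("block larger than image")
    if mode == "overlap":
        h = block // 2
        padded = np.pad(x_slice, ((0, 0), (h, h), (h, h)), mode="wrap")
        view = np.lib.stride_tricks.sliding_window_view(
            padded, (block, block), axis=(1, 2)
        )  # (T, nx, ny, b, b)
        return np.ascontiguousarray(
            view.transpose(1, 2, 3, 4, 0).reshape(nx * ny, block * block, T)
        )
    if mode == "shifted_nonoverlap":
        if nx % block or ny % block:
            raise ValueError("tiled mode requires block to divide nx and ny")
        rolled = np.roll(x_slice, shift, axis=(1, 2))
        b = block
        tiles = rolled.reshape(T, nx // b, b, ny // b, b)
        # (nx/b, ny/b, b, b, T) -> (n_blocks, b*b, T)
        tiles = tiles.transpose(1, 3, 2, 4, 0).reshape(-1, b * b, T)
        return np.ascontiguousarray(tiles)
    raise ValueError(f"unknown block mode {mode!r}")


def assemble_blocks(
    blocks: np.ndarray,
    block: int,
    shape: tuple[int, int, int],
    mode: str = "overlap",
    shift: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Exact adjoint of :func:`extract_blocks` (scatter-add of block entries)."""
    if block % 2 == 0:
        raise ValueError("block edge length must be odd")
    T, nx, ny = shape
    if mode == "overlap":
        stacked = blocks.transpose(1, 2, 0).reshape(block * block, T, nx, ny)
        out = np.zeros((T, nx, ny), dtype=blocks.dtype)
        for j, (dx, dy) in enumerate(_block_offsets(block)):
            out += np.roll(stacked[j], (dx, dy), axis=(1, 2))
        return out
    if mode == "shifted_nonoverlap":
        b = block
        tiles = blocks.reshape(nx // b, ny // b, b, b, T).transpose(4, 0, 2, 1, 3)
        rolled = tiles.reshape(T, nx, ny)
        return np.roll(rolled, (-shift[0], -shift[1]), axis=(1, 2))
    raise ValueError(f"unknown block mode {mode!r}")


# ---------------------------------------------------------------------------
# orthonormal wavelet transform


def _check_wavelet_size(nx: int, ny: int, levels: int) -> None:
    f = 2**levels
    if nx % f or ny % f:
        raise ValueError(
            f"image size ({nx}, {ny}) not divisible by 2^{levels}; pad the "
            "image to a multiple before transforming"
        )


def wavelet_forward(image: np.ndarray, levels: int = WAVELET_LEVELS) -> np.ndarray:
    """Orthonormal 2D wavelet transform (Daubechies-4, periodic boundary).

    Acts on the last two axes, so a full (mb, n_contrasts, nx, ny) volume can
    be transformed in one call. The coefficient array has the same shape as
    the input and the transform is an isometry: ``W^H W = W W^H = I``.
    """
    nx, ny = image.shape[-2:]
    _check_wavelet_size(nx, ny, levels)
    with warnings.catch_warnings():
        # deep levels on tiny test images trigger a pywt boundary note; the
        # periodized transform stays exactly orthonormal regardless
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(
            image, WAVELET, mode=_WAVELET_MODE, level=levels, axes=(-2, -1)
        )
    arr, _ = pywt.coeffs_to_array(coeffs, axes=(-2, -1))
    return arr


_slices_cache: dict = {}


def _coeff_slices(shape: tuple, levels: int):
    key = (shape, levels)
    if key not in _slices_cache:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            template = pywt.wavedec2(
                np.zeros(shape), WAVELET, mode=_WAVELET_MODE, level=levels,
                axes=(-2, -1),
            )
        _, slices = pywt.coeffs_to_array(template, axes=(-2, -1))
        _slices_cache[key] = slices
    return _slices_cache[key]


def wavelet_adjoint(coeffs: np.ndarray, levels: int = WAVELET_LEVELS) -> np.ndarray:
    """Inverse (= adjoint) of :func:`wavelet_forward`."""
    nx, ny = coeffs.shape[-2:]
    _check_wavelet_size(nx, ny, levels)
    slices = _coeff_slices(coeffs.shape, levels)
    structured = pywt.array_to_coeffs(coeffs, slices, output_format="wavedec2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.waverec2(structured, WAVELET, mode=_WAVELET_MODE, axes=(-2, -1))
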