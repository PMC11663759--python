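"""Dictionary-based T1/T2 estimation from reconstructed contrast images.

The mapping chain restores the signed polarity of the inversion-recovery
signals (phase-sensitive correction), estimates a single transmit-field (B1)
scale from a reference region with a coarse three-parameter dictionary, and
then matches every voxel against a fine T1/T2 dictionary simulated at that B1.
Matching maximizes the normalized real inner product between the voxel series
and the l2-normalized atoms, which is equivalent to least squares over a free
non-negative scale; the scale itself is retained as the M0 estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from smsmap.sequence import Dictionary

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterMaps",
    "RoiMask",
    "phase_sensitive_correct",
    "estimate_b1",
    "match_dictionary",
]

#: coarse three-parameter grids used for the first (B1) matching stage
COARSE_T1_GRID = (500.0, 100.0, 1500.0)
COARSE_T2_GRID = (40.0, 30.0, 140.0)
COARSE_B1_GRID = (0.5, 0.05, 1.0)
#: fine grids of the second stage (phantom protocol)
FINE_T1_GRID_PHANTOM = (1.0, 10.0, 2500.0)
FINE_T2_GRID_PHANTOM = (1.0, 4.0, 400.0)
#: fine grids of the second stage (in vivo protocol)
FINE_T1_GRID_INVIVO = (200.0, 1.0, 2500.0)
FINE_T2_GRID_INVIVO = (1.0, 1.0, 150.0)


@dataclass
class RoiMask:
    """Boolean region-of-interest mask, one plane per slice (mb, nx, ny)."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ParameterMaps:
    """Estimated relaxation maps, shape (mb, nx, ny) each.

    ``residual`` is ``1 - r`` with ``r`` the normalized match correlation;
    voxels with an all-zero series carry NaN in ``t1_ms``/``t2_ms`` and are
    flagged false in ``valid``.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    residual: np.ndarray
    valid: np.ndarray
    b1_used: float = 1.0


def phase_sensitive_correct(series: np.ndarray) -> np.ndarray:
    """Restore signed polarity from complex contrast images.

    Each voxel's contrast vector is rotated by the conjugate phase of its last
    contrast (assumed predominantly recovered, hence of positive polarity) and
    the real part is kept. Voxels whose reference magnitude is zero fall back
    to magnitude images; their count is logged.

    Accepts any array whose first-from-last-third axis is contrast, i.e.
    (..., n_contrasts, nx, ny), and returns a real array of the same shape.
    """
    series = np.asarray(series)
    if series.ndim < 3:
        raise ValueError("series must be (..., n_contrasts, nx, ny)")
    ref = series[..., -1:, :, :]
    mag = np.abs(ref)
    zero_ref = mag[..., 0, :, :] == 0
    n_zero = int(zero_ref.sum())
    if n_zero:
        logger.warning(
            "phase-sensitive correction: %d voxels with zero reference; "
            "falling back to magnitude there",
            n_zero,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        phase = np.where(mag > 0, np.conj(ref) / mag, 1.0)
    out = np.real(series * phase)
    if n_zero:
        out = np.where(zero_ref[..., None, :, :], np.abs(series), out)
    return out


def _match(series_flat: np.ndarray, dictionary: Dictionary, chunk: int = 4096):
    """Best-atom index, correlation and M0 per voxel series.

    ``series_flat`` is (n_voxels, n_contrasts) real. Returns (idx, corr, m0,
    valid). Atoms are matched over the signed correlation (polarity already
    restored), with first-occurrence argmax realizing the smaller-T1-then-T2
    tie-break through the dictionary's lexicographic atom order.
    """
    atoms = dictionary.atoms  # (n_atoms, T), rows unit-norm
    n_vox = series_flat.shape[0]
    idx = np.zeros(n_vox, dtype=np.int64)
    corr = np.zeros(n_vox)
    m0 = np.zeros(n_vox)
    norms = np.linalg.norm(series_flat, axis=1)
    valid = norms > 0
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        scores = series_flat[lo:hi] @ atoms.T  # (chunk, n_atoms)
        best = np.argmax(scores, axis=1)
        idx[lo:hi] = best
        picked = scores[np.arange(hi - lo), best]
        m0[lo:hi] = picked
        with np.errstate(divide="ignore", invalid="ignore"):
            corr[lo:hi] = np.where(norms[lo:hi] > 0, picked / norms[lo:hi], 0.0)
    return idx, corr, m0, valid


def estimate_b1(
    series: np.ndarray, coarse_dict: Dictionary, roi: RoiMask
) -> float:
    """Mean matched B1 over a reference region (stage one of the mapping).

    ``series`` is the polarity-restored real series (mb, n_contrasts, nx, ny)
    or (n_contrasts, nx, ny); ``roi`` selects the reference voxels (the septum
    in vivo, a vial region in phantoms).
    """
    if np.unique(coarse_dict.b1).size < 2:
        raise ValueError("coarse dictionary must span several B1 levels")
    series = np.asarray(series)
    if series.ndim == 3:
        series = series[None]
    mask = roi.mask if roi.mask.ndim == 3 else roi.mask[None]
    if mask.sum() == 0:
        raise ValueError("empty ROI")
    T = series.shape[1]
    vox = np.moveaxis(series, 1, -1)[mask]  # (n_roi, T)
    if vox.shape[1] != T:
        raise AssertionError
    idx, _, _, valid = _match(vox, coarse_dict)
    if not valid.any():
        raise ValueError("ROI contains only zero signals")
    matched = coarse_dict.b1[idx[valid]]
    if np.all(matched == matched[0]):  # unanimous ROI: exact, no mean rounding
        return float(matched[0])
    return float(np.mean(matched))


def match_dictionary(series: np.ndarray, fine_dict: Dictionary) -> ParameterMaps:
    """Voxelwise T1/T2 by exhaustive correlation matching (stage two).

    ``series`` is the polarity-restored real series (mb, n_contrasts, nx, ny).
    Per voxel the atom maximizing ``<s, d> / (||s|| ||d||)`` is selected; the
    inner product with the unit-norm atom is kept as the M0 (least-squares
    scale) and ``1 - correlation`` as the match residual.
    """
    series = np.asarray(series)
    if series.ndim == 3:
        series = series[None]
    mb, T, nx, ny = series.shape
    if T != fine_dict.n_contrasts:
        raise ValueError(
            f"series has {T} contrasts but dictionary {fine_dict.n_contrasts}"
        )
    flat = np.moveaxis(series, 1, -1).reshape(-1, T)
    idx, corr, m0, valid = _match(flat, fine_dict)
    t1 = np.where(valid, fine_dict.t1_ms[idx], np.nan).reshape(mb, nx, ny)
    t2 = np.where(valid, fine_dict.t2_ms[idx], np.nan).reshape(mb, nx, ny)
    m0_map = np.where(valid, m0, 0.0).reshape(mb, nx, ny)
    residual = np.clip(1.0 - corr, 0.0, 1.0).reshape(mb, nx, ny)
    b1 = float(fine_dict.b1[0]) if np.unique(fine_dict.b1).size == 1 else float("nan")
    return ParameterMaps(
        t1_ms=t1,
        t2_ms=t2,
        m0=m0_map,
        residual=residual,
        valid=valid.reshape(mb, nx, ny),
        b1_used=b1,
    )
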