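"""Quantitative comparison of reconstructions and parameter maps.

PSNR and SSIM score raw-image fidelity against a reference (the fully sampled
or single-band reconstruction); ROI statistics, Bland-Altman bias/limits of
agreement and the linear-fit coefficient of determination quantify agreement
of the estimated relaxation times with the reference values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = ["AgreementReport", "psnr", "ssim", "bland_altman", "roi_stats"]


@dataclass
class AgreementReport:
    """Bland-Altman bias, 95% limits of agreement, and linear-fit R^2."""

    bias: float
    loa_lower: float
    loa_upper: float
    r_squared: float
    n: int


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio ``20 log10(max|ref| / RMSE)`` in dB.

    Identical inputs return ``inf``. The peak is the maximum magnitude of the
    reference image.
    """
    ref = np.asarray(ref)
    test = np.asarray(test)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    peak = float(np.abs(ref).max())
    if peak == 0:
        raise ValueError("all-zero reference image")
    mse = float(np.mean(np.abs(ref - test) ** 2))
    if mse == 0:
        return float("inf")
    return 20.0 * np.log10(peak / np.sqrt(mse))


def ssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity on magnitude images, canonical constants.

    The data range is taken from the reference magnitude. Multi-frame inputs
    (any leading axes before the trailing 2D image axes) are averaged.
    """
    ref = np.abs(np.asarray(ref))
    test = np.abs(np.asarray(test))
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    dr = float(ref.max() - ref.min())
    if dr == 0:
        dr = 1.0
    if ref.ndim == 2:
        return float(structural_similarity(ref, test, data_range=dr))
    flat_r = ref.reshape(-1, *ref.shape[-2:])
    flat_t = test.reshape(-1, *test.shape[-2:])
    vals = [
        structural_similarity(r, t, data_range=dr) for r, t in zip(flat_r, flat_t)
    ]
    return float(np.mean(vals))


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementReport:
    """Agreement of paired measurements ``a`` (test) vs ``b`` (reference).

    Bias is ``mean(a - b)``; the 95% limits of agreement are
    ``bias +/- 1.96 SD(a - b)``; R^2 comes from the least-squares fit of
    ``a`` on ``b``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(b, b[0]):
        r2 = 1.0 if np.allclose(a, a[0]) else 0.0
    else:
        fit = stats.linregress(b, a)
        r2 = float(fit.rvalue**2)
    return AgreementReport(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        r_squared=r2,
        n=a.size,
    )


def roi_stats(map_: np.ndarray, masks: dict[str, np.ndarray]) -> dict[str, tuple]:
    """Arithmetic mean and sample SD of a map over each named ROI."""
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        vals = np.asarray(map_)[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"empty ROI {name!r}")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out
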