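"""Coil-sensitivity estimation from the single-band calibration beat.

A deliberately simple autocalibration method: the fully sampled central ky
lines of each slice are apodized (Hann window over the calibration extent),
zero-filled and inverse-transformed to low-resolution coil images, and each
coil image is divided by the root-sum-of-squares combination. The output is
RSS-normalized inside the object support.
"""

from __future__ import annotations

import numpy as np

from smsmap.operators import CoilMaps, ifft_centered

__all__ = ["estimate_sensitivities"]


def estimate_sensitivities(
    acs: np.ndarray,
    support_threshold: float = 0.1,
) -> tuple[CoilMaps, np.ndarray]:
    """Low-resolution coil maps from single-band ACS k-space.

    Parameters
    ----------
    acs
        (n_coils, mb, nx, ny) k-space with only the central calibration ky
        lines nonzero (per slice, single band). At least four calibration
        lines are required.
    support_threshold
        Fraction of the maximum RSS magnitude below which voxels are treated
        as background (maps there are extrapolated from the regularized
        division but flagged outside the support mask).

    Returns
    -------
    (CoilMaps, support)
        Estimated maps with RSS equal to one inside the support, and the
        boolean support mask (mb, nx, ny).
    """
    acs = np.asarray(acs)
    if acs.ndim != 4:
        raise ValueError("acs must be (n_coils, mb, nx, ny)")
    line_power = np.sum(np.abs(acs), axis=(0, 1, 2))  # per ky line
    sampled = np.nonzero(line_power > 0)[0]
    if sampled.size == 0:
        raise ValueError("all-zero ACS data")
    if sampled.size < 4:
        raise ValueError("need at least four calibration lines")
    nc, mb, nx, ny = acs.shape
    # demodulate each coil's dominant linear phase (recenter its ky energy)
    # before windowing: otherwise the apodization attenuates coils with steep
    # receive-phase ramps and biases their relative amplitude
    power = np.sum(np.abs(acs) ** 2, axis=2)  # (nc, mb, ny)
    ky = np.arange(ny)
    centroid = np.sum(power * ky, axis=-1) / np.maximum(np.sum(power, axis=-1), 1e-30)
    shift = np.rint(centroid - ny // 2).astype(int)  # (nc, mb)
    # Hann apodization over the central band; the window stays fixed on the
    # k-space center while each coil's data is recentered under it
    window = np.zeros(ny)
    window[sampled] = np.hanning(sampled.size + 2)[1:-1]
    apodized = np.empty_like(acs)
    for c in range(nc):
        for q in range(mb):
            apodized[c, q] = np.roll(acs[c, q], -shift[c, q], axis=-1) * window
    low_res = ifft_centered(apodized, axes=(-2, -1))
    # restore the demodulated ramp in image space
    y_idx = np.arange(ny) - ny // 2
    restore = np.exp(
        2j * np.pi * shift[:, :, None, None] * y_idx[None, None, None, :] / ny
    )
    low_res = low_res * restore
    rss = np.sqrt(np.sum(np.abs(low_res) ** 2, axis=0))
    eps = 1e-6 * float(rss.max())
    sens = low_res / (rss[None] + eps)
    support = rss > support_threshold * rss.max()
    # renormalize so RSS is exactly one on the support
    rss_s = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    sens = np.where(support[None], sens / np.maximum(rss_s[None], eps), sens)
    return CoilMaps(sens=sens), support
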