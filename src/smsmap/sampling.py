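"""SUPER-CAIPIRINHA undersampling masks over (contrast, ky, kz).

Simultaneous slices are modeled as kz Fourier partitions; CAIPIRINHA RF phase
cycling is equivalent to a skewed kz assignment on this 3D Fourier grid. The
SUPER component cycles the in-plane undersampling offset across contrasts so
that the union of masks over one shift cycle covers every outer ky line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SamplingPattern", "make_super_caipirinha", "make_acs"]


@dataclass(frozen=True)
class SamplingPattern:
    """Boolean sampling masks for one acquisition.

    ``mask`` has shape (n_contrasts, ny, nz) with nz equal to the multiband
    factor; ``acs_mask`` has shape (nz, ny) and marks the fully sampled
    central calibration lines acquired single-band per slice.
    """

    mask: np.ndarray
    r_inplane: int
    mb: int
    super_shifts: np.ndarray
    center_lines: int
    acs_mask: np.ndarray

    @property
    def n_contrasts(self) -> int:
        return self.mask.shape[0]

    @property
    def ny(self) -> int:
        return self.mask.shape[1]

    @property
    def nominal_acceleration(self) -> int:
        """Nominal combined acceleration: in-plane rate times multiband factor."""
        return self.r_inplane * self.mb

    def sampled_fraction(self, contrast: int | None = None) -> float:
        m = self.mask if contrast is None else self.mask[contrast]
        return float(m.mean())


def _center_band(ny: int, width: int) -> tuple[int, int]:
    """Index range (start, stop) of the central ky band, DC at floor(ny/2)."""
    start = ny // 2 - width // 2
    return start, start + width


def make_super_caipirinha(
    ny: int,
    mb: int,
    r_inplane: int,
    n_contrasts: int,
    center_lines: int = 24,
    dense_center: bool = True,
) -> SamplingPattern:
    """Skewed-grid undersampling with per-contrast shift cycling.

    Outer ky lines are sampled where ``(ky - t mod R) mod R == 0`` (SUPER
    cycling with R = ``r_inplane``) and each sampled line is assigned the
    single partition ``kz = floor(ky / R) mod mb`` (CAIPIRINHA skew). The
    central ``center_lines`` ky band is sampled at reduction 2 with a
    two-contrast parity cycle (so the union of adjacent contrasts covers the
    whole band) plus the DC line at every contrast — the readout acquires the
    k-space-center line every heartbeat, so it must be sampled in every
    contrast — all with the same kz skew; with ``dense_center=False`` the center
    follows the outer pattern, which makes the per-contrast sampled fraction
    exactly ``1 / (R * mb)``.
    """
    if mb not in (1, 2, 3):
        raise ValueError("multiband factor must be 1, 2 or 3")
    if r_inplane < 1:
        raise ValueError("r_inplane must be >= 1")
    if not 0 <= center_lines <= ny:
        raise ValueError("center_lines must lie in [0, ny]")
    ky = np.arange(ny)
    kz_of_ky = (ky // r_inplane) % mb
    shifts = np.arange(n_contrasts) % r_inplane
    mask = np.zeros((n_contrasts, ny, mb), dtype=bool)
    c0, c1 = _center_band(ny, center_lines)
    for t in range(n_contrasts):
        sampled = (ky - shifts[t]) % r_inplane == 0
        if dense_center and center_lines > 0:
            central = (ky >= c0) & (ky < c1)
            # reduction 2 with cycling parity for coverage, plus the DC line
            # at every contrast (the readout acquires it every heartbeat)
            dense = ((ky - ny // 2 - (t % 2)) % 2 == 0) | (ky == ny // 2)
            sampled = np.where(central, dense, sampled)
        mask[t, ky[sampled], kz_of_ky[sampled]] = True
    return SamplingPattern(
        mask=mask,
        r_inplane=r_inplane,
        mb=mb,
        super_shifts=shifts,
        center_lines=center_lines,
        acs_mask=make_acs(ny, mb, min(18, ny)),
    )


def make_acs(ny: int, mb: int, n_acs: int = 18) -> np.ndarray:
    """Fully sampled central-line calibration mask, one row per slice.

    Returns a boolean (mb, ny) array with the central ``n_acs`` ky lines true
    for every slice; the calibration beat is acquired single-band so there is
    no kz dimension.
    """
    if not 0 <= n_acs <= ny:
        raise ValueError("n_acs must lie in [0, ny]")
    acs = np.zeros((mb, ny), dtype=bool)
    c0, c1 = _center_band(ny, n_acs)
    acs[:, c0:c1] = True
    return acs
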