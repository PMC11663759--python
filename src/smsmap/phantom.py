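"""Digital phantoms, synthetic coil maps, and fully simulated acquisitions.

Everything downstream (reconstruction, mapping, evaluation) is testable from
these generators alone: a nine-vial relaxometry phantom with physiological
T1/T2, a three-slice cardiac-like geometry (blood pool, myocardial ring,
septal sector), smooth synthetic coil sensitivities, and the end-to-end
simulation of noisy undersampled multicoil k-space including the single-band
calibration beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smsmap.operators import CoilMaps, ImageSeries, KSpaceData, fft_centered, forward, adjoint
from smsmap.sampling import SamplingPattern
from smsmap.sequence import SequenceSchedule, _simulate_batch

__all__ = [
    "PhantomSpec",
    "make_vial_phantom",
    "make_cardiac_phantom",
    "make_coil_maps",
    "simulate_acquisition",
    "SimulatedAcquisition",
    "DEFAULT_VIAL_T1_MS",
    "DEFAULT_VIAL_T2_MS",
]

#: default vial relaxation times (ms), spanning the physiological range and
#: lying exactly on the fine phantom dictionary lattice (T1 on 1+10k, T2 on
#: 1+4k) so that noiseless identifiability is exact.
DEFAULT_VIAL_T1_MS = (301.0, 491.0, 681.0, 871.0, 1061.0, 1251.0, 1441.0, 1631.0, 1801.0)
DEFAULT_VIAL_T2_MS = (33.0, 61.0, 89.0, 117.0, 145.0, 173.0, 201.0, 229.0, 249.0)


@dataclass
class PhantomSpec:
    """Ground-truth parameter maps and named region masks.

    All maps have shape (mb, nx, ny). ``m0`` is complex; voxels with zero
    ``m0`` are outside the object. ``b1`` defaults to one everywhere so that
    transmit-field estimation experiments are controlled.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    b1: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    labels: tuple[str, ...] = ()

    @property
    def mb(self) -> int:
        return self.t1_ms.shape[0]

    @property
    def shape(self) -> tuple:
        return self.t1_ms.shape

    @property
    def object_mask(self) -> np.ndarray:
        return np.abs(self.m0) > 0


def _disk(nx: int, ny: int, cx: float, cy: float, r: float) -> np.ndarray:
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


def _ellipse(nx: int, ny: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0


def make_vial_phantom(
    nx: int = 96,
    ny: int = 96,
    mb: int = 3,
    t1_list=DEFAULT_VIAL_T1_MS,
    t2_list=DEFAULT_VIAL_T2_MS,
) -> PhantomSpec:
    """Nine vials on a 3x3 grid inside a low-signal gel holder.

    The vial grid is replicated on every simultaneous slice with a one-voxel
    in-plane offset per slice (mimicking imperfect vial alignment). Besides
    the full vial masks, eroded ``roi_*`` masks (for unbiased ROI statistics)
    and a ``b1_ref`` reference region are provided.
    """
    t1_list = tuple(float(v) for v in t1_list)
    t2_list = tuple(float(v) for v in t2_list)
    if len(t1_list) != 9 or len(t2_list) != 9:
        raise ValueError("nine T1 and nine T2 values required")
    if any(t1 < t2 for t1, t2 in zip(t1_list, t2_list)):
        raise ValueError("each vial needs T1 >= T2")
    t1 = np.zeros((mb, nx, ny))
    t2 = np.zeros((mb, nx, ny))
    m0 = np.zeros((mb, nx, ny), dtype=complex)
    b1 = np.ones((mb, nx, ny))
    masks: dict[str, np.ndarray] = {}

    r_vial = 0.068 * min(nx, ny)
    r_roi = max(r_vial - 2.0, 1.0)
    centers = [0.28, 0.50, 0.72]
    spacing = (centers[1] - centers[0]) * min(nx, ny)
    if 2 * r_vial >= spacing:
        raise ValueError("vials overlap; reduce radius or matrix too small")
    # low-signal holder (on-lattice background tissue)
    holder_t1, holder_t2, holder_m0 = 301.0, 29.0, 0.35
    labels = []
    for q in range(mb):
        off = q - (mb - 1) / 2  # one-voxel offset per slice
        holder = _disk(nx, ny, nx / 2 + off, ny / 2, 0.44 * min(nx, ny))
        t1[q][holder] = holder_t1
        t2[q][holder] = holder_t2
        m0[q][holder] = holder_m0
        for k in range(9):
            cx = centers[k // 3] * nx + off
            cy = centers[k % 3] * ny
            vial = _disk(nx, ny, cx, cy, r_vial)
            roi = _disk(nx, ny, cx, cy, r_roi)
            t1[q][vial] = t1_list[k]
            t2[q][vial] = t2_list[k]
            m0[q][vial] = 1.0
            for name, m in ((f"vial_{k}", vial), (f"roi_{k}", roi)):
                if name not in masks:
                    masks[name] = np.zeros((mb, nx, ny), dtype=bool)
                masks[name][q] = m
    labels = [f"vial_{k}" for k in range(9)]
    # reference region for the coarse B1 stage: a vial whose (T1, T2) lies
    # inside the abbreviated dictionary's coverage, like the septum in vivo
    masks["b1_ref"] = masks["roi_3"].copy()
    return PhantomSpec(t1_ms=t1, t2_ms=t2, m0=m0, b1=b1, masks=masks, labels=tuple(labels))


def make_cardiac_phantom(nx: int = 96, ny: int = 96, mb: int = 3) -> PhantomSpec:
    """Three-slice short-axis-like geometry.

    Per slice: a body ellipse (T1 900 / T2 80 ms), a blood-pool disk (T1 1900
    / T2 250 ms), a myocardial annulus (T1 1200 / T2 45 ms) and a septal
    sector of the annulus; the ring shrinks toward the apical slice.
    """
    if mb < 1:
        raise ValueError("mb must be >= 1")
    t1 = np.zeros((mb, nx, ny))
    t2 = np.zeros((mb, nx, ny))
    m0 = np.zeros((mb, nx, ny), dtype=complex)
    b1 = np.ones((mb, nx, ny))
    myo = np.zeros((mb, nx, ny), dtype=bool)
    septum = np.zeros((mb, nx, ny), dtype=bool)
    blood = np.zeros((mb, nx, ny), dtype=bool)
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for q in range(mb):
        shrink = 1.0 - 0.12 * q  # basal -> apical
        body = _ellipse(nx, ny, nx / 2, ny / 2, 0.42 * nx, 0.36 * ny)
        t1[q][body] = 900.0
        t2[q][body] = 80.0
        m0[q][body] = 0.6
        r_bp = 0.13 * min(nx, ny) * shrink
        r_out = r_bp + 0.07 * min(nx, ny)
        cx, cy = nx * 0.45, ny * 0.5
        bp = _disk(nx, ny, cx, cy, r_bp)
        ring = _disk(nx, ny, cx, cy, r_out) & ~bp
        t1[q][bp] = 1900.0
        t2[q][bp] = 250.0
        m0[q][bp] = 1.0
        t1[q][ring] = 1200.0
        t2[q][ring] = 45.0
        m0[q][ring] = 0.8
        ang = np.arctan2(Y - cy, X - cx)
        sect = ring & (np.abs(ang - np.pi / 2) < np.pi / 5)
        myo[q], septum[q], blood[q] = ring, sect, bp
    masks = {"myocardium": myo, "septum": septum, "blood": blood}
    return PhantomSpec(
        t1_ms=t1, t2_ms=t2, m0=m0, b1=b1, masks=masks,
        labels=("myocardium", "septum", "blood"),
    )


def make_coil_maps(
    nx: int, ny: int, mb: int, n_coils: int, seed: int = 0
) -> CoilMaps:
    """Smooth synthetic coil sensitivities, RSS-normalized to one.

    Coils are Gaussian receive profiles centered on the field-of-view
    perimeter at staggered axial positions (so the maps differ across
    simultaneous slices, which is what makes slice separation possible), each
    with a smooth linear phase ramp. Ramp slopes are assigned deterministically
    distinct per element (small per-seed jitter): the phase diversity across
    elements is what conditions in-plane unaliasing, and independently random
    slopes can coincide across elements and leave the array degenerate for
    some seeds. Deterministic per seed. A single coil yields a flat
    unit-sensitivity map for oracle tests.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilMaps(sens=np.ones((1, mb, nx, ny), dtype=complex))
    rng = np.random.default_rng(seed)
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sens = np.zeros((n_coils, mb, nx, ny), dtype=complex)
    radius = 0.6 * min(nx, ny)
    sigma = 0.45 * min(nx, ny)
    z_slices = np.linspace(-1.0, 1.0, mb) if mb > 1 else np.array([0.0])
    # elements staggered across the slice direction like an anterior/posterior
    # array; the axial spread is what conditions the slice separation
    z_positions = np.linspace(-1.2, 1.2, n_coils)
    # distinct phase-ramp slopes per element; the x-order is interleaved so
    # (ax, ay) pairs never repeat along the ring
    ramp = 5.0 * np.pi / max(nx, ny)
    ay_slopes = ramp * np.linspace(-1.0, 1.0, n_coils)
    ax_slopes = ay_slopes[np.argsort((np.arange(n_coils) * 3) % n_coils)]
    for c in range(n_coils):
        angle = 2 * np.pi * c / n_coils + rng.normal(0, 0.1)
        cx = nx / 2 + radius * np.cos(angle)
        cy = ny / 2 + radius * np.sin(angle)
        z_coil = z_positions[c] + rng.normal(0, 0.1)
        ax = ax_slopes[c] + rng.normal(0, 0.05 * ramp)
        ay = ay_slopes[c] + rng.normal(0, 0.05 * ramp)
        phi0 = rng.uniform(0, 2 * np.pi)
        prof = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2))
        phase = np.exp(1j * (ax * X + ay * Y + phi0))
        for q in range(mb):
            axial = np.exp(-((z_slices[q] - z_coil) ** 2) / (2 * 0.8**2))
            sens[c, q] = prof * axial * phase
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    sens /= rss[None]
    return CoilMaps(sens=sens)


@dataclass
class SimulatedAcquisition:
    """Output bundle of :func:`simulate_acquisition`."""

    kspace: KSpaceData
    acs: np.ndarray  # (n_coils, mb, nx, ny) single-band calibration k-space
    truth: ImageSeries
    acs_image: np.ndarray  # (mb, nx, ny) calibration-beat image per slice
    noise_scale: float  # absolute per-component noise SD actually applied


def _truth_series(
    phantom: PhantomSpec, schedule: SequenceSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the Bloch signal per distinct tissue (cached by parameter tuple)."""
    mb, nx, ny = phantom.shape
    T = schedule.n_imaging
    obj = phantom.object_mask
    t1 = phantom.t1_ms[obj]
    t2 = phantom.t2_ms[obj]
    b1 = phantom.b1[obj]
    params = np.stack([t1, t2, b1], axis=1)
    uniq, inv = np.unique(params, axis=0, return_inverse=True)
    signals, acs_sig = _simulate_batch(uniq[:, 0], uniq[:, 1], uniq[:, 2], schedule)
    x = np.zeros((mb, T, nx, ny), dtype=complex)
    acs_img = np.zeros((mb, nx, ny), dtype=complex)
    vox_sig = signals[inv]  # (n_obj, T)
    vox_acs = acs_sig[inv]
    m0_obj = phantom.m0[obj]
    full = np.zeros((mb, nx, ny, T), dtype=complex)
    full[obj] = vox_sig * m0_obj[:, None]
    x = np.moveaxis(full, -1, 1)
    acs_img[obj] = vox_acs * m0_obj
    return x, acs_img


def simulate_acquisition(
    phantom: PhantomSpec,
    schedule: SequenceSchedule,
    pattern: SamplingPattern,
    coils: CoilMaps,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedAcquisition:
    """Simulate the full undersampled multicoil acquisition of a phantom.

    The ground-truth image series is built from the Bloch simulator (signal
    cached per distinct tissue), encoded with ``y = D F E x``, and corrupted
    with i.i.d. complex Gaussian noise of per-component standard deviation
    ``noise_sd`` relative to the normalized image scale (99th-percentile
    magnitude of the zero-filled adjoint equals one). The calibration beat is
    simulated single-band per slice at the final-beat magnetization and
    restricted to the ACS lines.
    """
    if pattern.n_contrasts != schedule.n_imaging:
        raise ValueError(
            f"pattern has {pattern.n_contrasts} contrasts but schedule "
            f"{schedule.n_imaging} imaging beats"
        )
    x, acs_img = _truth_series(phantom, schedule)
    truth = ImageSeries(data=x)
    y = forward(truth, coils, pattern)

    # single-band fully sampled center lines per slice
    coil_imgs = coils.sens * acs_img[None]  # (nc, mb, nx, ny)
    acs_k = fft_centered(coil_imgs, axes=(-2, -1))
    acs_k *= pattern.acs_mask[None, :, None, :]

    rng = np.random.default_rng(seed)
    scale = float(np.percentile(np.abs(adjoint(y, coils).data), 99))
    sd_abs = noise_sd * scale
    if noise_sd > 0:
        noise = rng.normal(0, sd_abs, y.samples.shape + (2,))
        y.samples = y.samples + (noise[..., 0] + 1j * noise[..., 1]) * (
            pattern.mask[None, :, None, :, :]
        )
        noise_acs = rng.normal(0, sd_abs, acs_k.shape + (2,))
        acs_k = acs_k + (noise_acs[..., 0] + 1j * noise_acs[..., 1]) * (
            pattern.acs_mask[None, :, None, :]
        )
    y.noise_sd = noise_sd
    return SimulatedAcquisition(
        kspace=y, acs=acs_k, truth=truth, acs_image=acs_img, noise_scale=sd_abs
    )
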