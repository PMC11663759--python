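"""Acquisition schedule and Bloch signal simulation for SMS multimapping.

The sequence acquires one multicontrast image per imaging heartbeat with a
spoiled FLASH readout train. T1 weighting is produced by inversion pulses and
free recovery across heartbeats; T2 weighting by T2-preparation modules played
immediately before the readout. A final prep-free heartbeat acquires the
single-band autocalibration (ACS) data. The same simulator generates both the
phantom signals and the matching dictionaries, so the dictionary is exact for
the simulated acquisition.

The signal model is a discrete longitudinal-magnetization recursion with
perfect spoiling (no transverse coherence history): each TR tips Mz by the
B1-scaled flip angle, records the transverse signal Mz*sin(theta) at the TR of
the k-space-center line, and relaxes toward equilibrium with T1 over the TR.
Inversion multiplies Mz by -delta (delta = inversion efficiency); T2
preparation multiplies Mz by exp(-TEprep/T2) assuming ideal adiabatic
refocusing.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeartbeatSpec",
    "SequenceSchedule",
    "TissueParams",
    "Dictionary",
    "build_default_schedule",
    "simulate_signal",
    "build_dictionary",
    "grid_values",
]

# prep kinds
PREP_NONE = "none"
PREP_INVERSION = "inversion"
PREP_T2PREP = "t2prep"


@dataclass(frozen=True)
class HeartbeatSpec:
    """Preparation and timing of a single cardiac cycle.

    Parameters
    ----------
    prep
        ``"none"``, ``"inversion"`` or ``"t2prep"``.
    prep_ms
        Inversion time TI (inversion pulse to k-space-center line) or the
        T2-preparation echo time, in milliseconds. Ignored for ``"none"``.
    trigger_delay_ms
        Time from the R-wave to the first readout excitation.
    is_acs
        Marks the prep-free calibration beat (single-band ACS readout).
    """

    prep: str = PREP_NONE
    prep_ms: float = 0.0
    trigger_delay_ms: float = 500.0
    is_acs: bool = False

    def __post_init__(self) -> None:
        if self.prep not in (PREP_NONE, PREP_INVERSION, PREP_T2PREP):
            raise ValueError(f"unknown prep kind {self.prep!r}")
        if self.prep != PREP_NONE and not self.prep_ms > 0:
            raise ValueError("prep_ms must be > 0 when a preparation is used")
        if self.is_acs and self.prep != PREP_NONE:
            raise ValueError("ACS calibration beat must be prep-free")


@dataclass(frozen=True)
class SequenceSchedule:
    """Per-heartbeat timing of the multicontrast FLASH acquisition."""

    heartbeats: tuple[HeartbeatSpec, ...]
    rr_ms: float
    flip_deg: float = 5.0
    tr_ms: float = 4.19
    te_ms: float = 1.73
    lines_per_beat: int = 47
    center_line_index: int = 23
    inv_efficiency: float = 0.94

    def __post_init__(self) -> None:
        if not self.heartbeats:
            raise ValueError("schedule needs at least one heartbeat")
        if not 0.0 <= self.inv_efficiency <= 1.0:
            raise ValueError("inversion efficiency must lie in [0, 1]")
        if self.rr_ms <= 0 or self.tr_ms <= 0:
            raise ValueError("rr_ms and tr_ms must be positive")
        if not 0 <= self.center_line_index < self.lines_per_beat:
            raise ValueError("center_line_index outside readout train")

    @property
    def n_imaging(self) -> int:
        return sum(1 for hb in self.heartbeats if not hb.is_acs)

    @property
    def n_beats(self) -> int:
        return len(self.heartbeats)

    @property
    def readout_ms(self) -> float:
        return self.lines_per_beat * self.tr_ms

    def to_dict(self) -> dict:
        return {
            "rr_ms": self.rr_ms,
            "flip_deg": self.flip_deg,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "lines_per_beat": self.lines_per_beat,
            "center_line_index": self.center_line_index,
            "inv_efficiency": self.inv_efficiency,
            "heartbeats": [
                {
                    "prep": hb.prep,
                    "prep_ms": hb.prep_ms,
                    "trigger_delay_ms": hb.trigger_delay_ms,
                    "is_acs": hb.is_acs,
                }
                for hb in self.heartbeats
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceSchedule":
        beats = tuple(HeartbeatSpec(**hb) for hb in d["heartbeats"])
        kw = {k: v for k, v in d.items() if k != "heartbeats"}
        return cls(heartbeats=beats, **kw)

    @property
    def schedule_hash(self) -> str:
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha1(payload).hexdigest()[:16]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue/voxel."""

    t1_ms: float
    t2_ms: float
    b1_scale: float = 1.0
    m0: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if not self.t2_ms > 0:
            raise ValueError("t2_ms must be positive")
        if self.t1_ms < self.t2_ms:
            raise ValueError("non-physical tissue: requires t1_ms >= t2_ms > 0")
        if not self.b1_scale > 0:
            raise ValueError("b1_scale must be positive")


@dataclass(frozen=True)
class Dictionary:
    """Bloch-simulated signal atoms for voxelwise matching.

    ``atoms`` is (n_atoms, n_contrasts), real signed, each row l2-normalized.
    ``t1_ms``, ``t2_ms``, ``b1`` give the generating grid point per atom; the
    atoms are ordered lexicographically by (T1, T2, B1) so that an argmax with
    first-occurrence tie-breaking prefers smaller T1, then smaller T2.
    """

    atoms: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    b1: np.ndarray
    schedule_hash: str

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.atoms.shape[1]


# ---------------------------------------------------------------------------
# schedule construction

#: default preparation assignment of the 10 imaging beats (see docs/methods.md):
#: beat 1 prep-free baseline, beats 2 and 6 inversions (TI 120/200 ms) each
#: followed by free-recovery sampling beats, beats 8-10 T2prep 30/50/80 ms.
DEFAULT_PREPS: tuple[tuple[str, float], ...] = (
    (PREP_NONE, 0.0),
    (PREP_INVERSION, 120.0),
    (PREP_NONE, 0.0),
    (PREP_NONE, 0.0),
    (PREP_NONE, 0.0),
    (PREP_INVERSION, 200.0),
    (PREP_NONE, 0.0),
    (PREP_T2PREP, 30.0),
    (PREP_T2PREP, 50.0),
    (PREP_T2PREP, 80.0),
)

#: upper bound on the per-beat acquisition window (ms)
MAX_READOUT_WINDOW_MS = 200.0


def build_default_schedule(heart_rate_bpm: float, **config) -> SequenceSchedule:
    """Build the default 11-beat schedule (10 imaging + 1 calibration beat).

    Parameters
    ----------
    heart_rate_bpm
        Cardiac rate; the R-R interval is ``60000 / heart_rate_bpm`` ms for
        every beat. Must lie in [30, 150].
    config
        Overrides for any :class:`SequenceSchedule` field plus ``preps`` (a
        list of ``(kind, prep_ms)`` pairs replacing the default imaging-beat
        preparations) and ``trigger_delay_ms``.

    The readout train length defaults to the largest number of lines that
    keeps the acquisition window within {0} ms at the configured TR. The
    trigger delay defaults to 500 ms, shortened on fast heart rates so the
    readout still fits into the cardiac cycle.
    """
    if not 30.0 <= heart_rate_bpm <= 150.0:
        raise ValueError(
            f"heart rate {heart_rate_bpm} bpm outside supported range [30, 150]"
        )
    rr_ms = 60000.0 / heart_rate_bpm
    tr_ms = float(config.pop("tr_ms", 4.19))
    lines = int(config.pop("lines_per_beat", math.floor(MAX_READOUT_WINDOW_MS / tr_ms)))
    if lines * tr_ms > MAX_READOUT_WINDOW_MS:
        raise ValueError(
            f"lines_per_beat * tr_ms = {lines * tr_ms:.1f} ms exceeds the "
            f"{MAX_READOUT_WINDOW_MS:.0f} ms acquisition window"
        )
    center = int(config.pop("center_line_index", lines // 2))
    preps = config.pop("preps", DEFAULT_PREPS)
    trigger = float(config.pop("trigger_delay_ms", 500.0))
    # keep the readout inside the cardiac cycle on fast rates (diastolic timing)
    trigger = min(trigger, max(0.55 * rr_ms, rr_ms - lines * tr_ms - 20.0))
    beats = [
        HeartbeatSpec(prep=kind, prep_ms=ms, trigger_delay_ms=trigger)
        for kind, ms in preps
    ]
    beats.append(HeartbeatSpec(prep=PREP_NONE, trigger_delay_ms=trigger, is_acs=True))
    return SequenceSchedule(
        heartbeats=tuple(beats),
        rr_ms=rr_ms,
        tr_ms=tr_ms,
        lines_per_beat=lines,
        center_line_index=center,
        **config,
    )


build_default_schedule.__doc__ = build_default_schedule.__doc__.format(
    MAX_READOUT_WINDOW_MS
)


# ---------------------------------------------------------------------------
# Bloch simulation


def _simulate_batch(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    b1: np.ndarray,
    schedule: SequenceSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized longitudinal recursion over a batch of tissues.

    Returns ``(signals, acs_signal)`` with ``signals`` of shape
    (n_tissue, n_imaging) and ``acs_signal`` of shape (n_tissue,) holding the
    center-line signal of the calibration beat (zero when the schedule has
    none). Signals are signed and real, for unit equilibrium magnetization.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=np.float64))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=np.float64))
    b1 = np.atleast_1d(np.asarray(b1, dtype=np.float64))
    t1, t2, b1 = np.broadcast_arrays(t1, t2, b1)
    theta = np.deg2rad(schedule.flip_deg) * b1
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    e1_tr = np.exp(-schedule.tr_ms / t1)

    tr = schedule.tr_ms
    lines = schedule.lines_per_beat
    center = schedule.center_line_index
    delta = schedule.inv_efficiency

    mz = np.ones_like(t1)
    signals = np.zeros((t1.shape[0], schedule.n_imaging))
    acs_signal = np.zeros(t1.shape[0])

    def relax(mz: np.ndarray, dt: float) -> np.ndarray:
        if dt <= 0:
            return mz
        e = np.exp(-dt / t1)
        return 1.0 + (mz - 1.0) * e

    contrast = 0
    for hb in schedule.heartbeats:
        td = hb.trigger_delay_ms
        readout_end = td + lines * tr
        if readout_end > schedule.rr_ms + 1e-9:
            raise ValueError(
                f"readout train ends at {readout_end:.0f} ms, beyond the "
                f"{schedule.rr_ms:.0f} ms cardiac cycle"
            )
        if hb.prep == PREP_INVERSION:
            t_inv = td + center * tr - hb.prep_ms
            if t_inv < -1e-9:
                raise ValueError(
                    f"inversion time {hb.prep_ms} ms too long for trigger delay"
                )
            mz = relax(mz, t_inv)
            mz = -delta * mz
            mz = relax(mz, td - t_inv)
        elif hb.prep == PREP_T2PREP:
            mz = relax(mz, td)
            mz = mz * np.exp(-hb.prep_ms / t2)
        else:
            mz = relax(mz, td)
        # FLASH readout train
        for j in range(lines):
            s = mz * sin_t
            if j == center:
                if hb.is_acs:
                    acs_signal = s.copy()
                else:
                    signals[:, contrast] = s
            mz = mz * cos_t
            mz = 1.0 + (mz - 1.0) * e1_tr
        mz = relax(mz, schedule.rr_ms - readout_end)
        if not hb.is_acs:
            contrast += 1
    return signals, acs_signal


def simulate_signal(tissue: TissueParams, schedule: SequenceSchedule) -> np.ndarray:
    """Center-line signal of every imaging heartbeat for one tissue.

    The returned vector is real and signed (post-inversion contrasts are
    negative until recovery crosses zero) and scales linearly with |m0|.
    """
    if schedule.n_imaging < 1:
        raise ValueError("schedule has no imaging heartbeat")
    signals, _ = _simulate_batch(
        tissue.t1_ms, tissue.t2_ms, tissue.b1_scale, schedule
    )
    return abs(tissue.m0) * signals[0]


def simulate_signal_with_acs(
    tissue: TissueParams, schedule: SequenceSchedule
) -> tuple[np.ndarray, float]:
    """Like :func:`simulate_signal` but also returns the calibration-beat signal."""
    signals, acs = _simulate_batch(tissue.t1_ms, tissue.t2_ms, tissue.b1_scale, schedule)
    return abs(tissue.m0) * signals[0], abs(tissue.m0) * float(acs[0])


# ---------------------------------------------------------------------------
# dictionary generation


def grid_values(grid) -> np.ndarray:
    """Expand ``(start, step, stop)`` to the inclusive arithmetic grid.

    A scalar is returned as a one-element grid. Mirrors colon notation: the
    stop value is included only when it falls on the lattice.
    """
    if np.isscalar(grid):
        return np.asarray([float(grid)])
    start, step, stop = (float(v) for v in grid)
    if step <= 0:
        raise ValueError("grid step must be positive")
    if stop < start:
        raise ValueError("grid stop must be >= start")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def build_dictionary(
    t1_grid,
    t2_grid,
    b1_grid,
    schedule: SequenceSchedule,
) -> Dictionary:
    """Simulate one l2-normalized atom per (T1, T2, B1) grid combination.

    Combinations with T1 < T2 are excluded as non-physical. Grids follow
    ``(start, step, stop)`` colon notation; ``b1_grid`` may be a scalar to fix
    the transmit-field scale (the second matching stage).
    """
    t1v = grid_values(t1_grid)
    t2v = grid_values(t2_grid)
    b1v = grid_values(b1_grid)
    if t1v.size == 0 or t2v.size == 0 or b1v.size == 0:
        raise ValueError("empty parameter grid")
    t1g, t2g, b1g = np.meshgrid(t1v, t2v, b1v, indexing="ij")
    t1g, t2g, b1g = t1g.ravel(), t2g.ravel(), b1g.ravel()
    keep = t1g >= t2g
    if not keep.any():
        raise ValueError("no grid combination satisfies T1 >= T2")
    t1g, t2g, b1g = t1g[keep], t2g[keep], b1g[keep]
    atoms, _ = _simulate_batch(t1g, t2g, b1g, schedule)
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    atoms = atoms / norms
    return Dictionary(
        atoms=atoms,
        t1_ms=t1g,
        t2_ms=t2g,
        b1=b1g,
        schedule_hash=schedule.schedule_hash,
    )
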