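"""HDF5 container, NIfTI map export, and run configuration.

Container layout (complex arrays are stored as paired ``*_re``/``*_im``
float32 datasets for portability)::

    /kspace_re, /kspace_im        coil x contrast x kx x ky x kz
    /acs_re, /acs_im              coil x slice x kx x ky (single band)
    /mask                         contrast x ky x kz (uint8)
    /acs_mask                     slice x ky (uint8)
    /maps/{t1,t2,b1,m0,residual}  estimated parameter maps
    /truth/{t1,t2,b1,m0_re,m0_im} ground-truth maps (synthetic runs)
    /meta                         JSON-encoded provenance (config, seed,
                                  package version, schedule hash)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from smsmap import __version__ as _pkg_version
from smsmap.mapping import ParameterMaps
from smsmap.sampling import SamplingPattern
from smsmap.sequence import Dictionary

logger = logging.getLogger(__name__)

__all__ = [
    "write_container",
    "read_container",
    "save_dictionary",
    "load_dictionary",
    "maps_to_nifti",
    "RunConfig",
]


def _write_complex(f: h5py.File, name: str, arr: np.ndarray) -> None:
    f.create_dataset(f"{name}_re", data=np.real(arr).astype(np.float32))
    f.create_dataset(f"{name}_im", data=np.imag(arr).astype(np.float32))


def _read_complex(f: h5py.File, name: str) -> np.ndarray:
    if f"{name}_re" not in f:
        raise KeyError(f"container is missing dataset '{name}_re'")
    return np.asarray(f[f"{name}_re"]) + 1j * np.asarray(f[f"{name}_im"])


def write_container(
    path,
    *,
    kspace: np.ndarray | None = None,
    acs: np.ndarray | None = None,
    pattern: SamplingPattern | None = None,
    truth: dict | None = None,
    maps: ParameterMaps | None = None,
    recon: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write any subset of the pipeline products to one HDF5 container."""
    with h5py.File(path, "w") as f:
        if kspace is not None:
            _write_complex(f, "kspace", kspace)
        if acs is not None:
            _write_complex(f, "acs", acs)
        if recon is not None:
            _write_complex(f, "recon", recon)
        if pattern is not None:
            f.create_dataset("mask", data=pattern.mask.astype(np.uint8))
            f.create_dataset("acs_mask", data=pattern.acs_mask.astype(np.uint8))
            f.attrs["r_inplane"] = pattern.r_inplane
            f.attrs["mb"] = pattern.mb
            f.attrs["center_lines"] = pattern.center_lines
        if truth is not None:
            g = f.create_group("truth")
            for key, arr in truth.items():
                if np.iscomplexobj(arr):
                    _write_complex(g, key, arr)
                else:
                    g.create_dataset(key, data=np.asarray(arr, dtype=np.float32))
        if maps is not None:
            g = f.create_group("maps")
            g.create_dataset("t1", data=maps.t1_ms.astype(np.float32))
            g.create_dataset("t2", data=maps.t2_ms.astype(np.float32))
            g.create_dataset("m0", data=maps.m0.astype(np.float32))
            g.create_dataset("residual", data=maps.residual.astype(np.float32))
            g.create_dataset("valid", data=maps.valid.astype(np.uint8))
            g.attrs["b1_used"] = maps.b1_used
        meta = dict(meta or {})
        meta.setdefault("package_version", _pkg_version)
        f.create_dataset("meta", data=json.dumps(meta, sort_keys=True))


def read_container(path, require: tuple[str, ...] = ()) -> dict:
    """Read a container back into a dict of arrays/objects.

    ``require`` names logical datasets (``kspace``, ``mask``, ``acs`` ...)
    that must be present; a missing one raises ``KeyError`` naming it.
    """
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name in ("kspace", "acs", "recon"):
            if f"{name}_re" in f:
                out[name] = _read_complex(f, name)
        if "mask" in f:
            mask = np.asarray(f["mask"], dtype=bool)
            acs_mask = (
                np.asarray(f["acs_mask"], dtype=bool)
                if "acs_mask" in f
                else np.zeros((mask.shape[2], mask.shape[1]), dtype=bool)
            )
            out["pattern"] = SamplingPattern(
                mask=mask,
                r_inplane=int(f.attrs.get("r_inplane", 1)),
                mb=int(f.attrs.get("mb", mask.shape[2])),
                super_shifts=np.arange(mask.shape[0])
                % max(int(f.attrs.get("r_inplane", 1)), 1),
                center_lines=int(f.attrs.get("center_lines", 0)),
                acs_mask=acs_mask,
            )
        if "truth" in f:
            g = f["truth"]
            truth = {}
            seen_im = {k[:-3] for k in g if k.endswith("_im")}
            for key in g:
                if key.endswith("_im"):
                    continue
                if key.endswith("_re") and key[:-3] in seen_im:
                    truth[key[:-3]] = _read_complex(g, key[:-3])
                else:
                    truth[key] = np.asarray(g[key])
            out["truth"] = truth
        if "maps" in f:
            g = f["maps"]
            out["maps"] = ParameterMaps(
                t1_ms=np.asarray(g["t1"], dtype=float),
                t2_ms=np.asarray(g["t2"], dtype=float),
                m0=np.asarray(g["m0"], dtype=float),
                residual=np.asarray(g["residual"], dtype=float),
                valid=np.asarray(g["valid"], dtype=bool),
                b1_used=float(g.attrs.get("b1_used", 1.0)),
            )
        if "meta" in f:
            out["meta"] = json.loads(f["meta"][()])
    for name in require:
        if name not in out:
            raise KeyError(f"container is missing dataset '{name}'")
    return out


def save_dictionary(path, dictionary: Dictionary) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=dictionary.atoms)
        f.create_dataset("t1", data=dictionary.t1_ms)
        f.create_dataset("t2", data=dictionary.t2_ms)
        f.create_dataset("b1", data=dictionary.b1)
        f.attrs["schedule_hash"] = dictionary.schedule_hash


def load_dictionary(path, expect_schedule_hash: str | None = None) -> Dictionary:
    with h5py.File(path, "r") as f:
        d = Dictionary(
            atoms=np.asarray(f["atoms"]),
            t1_ms=np.asarray(f["t1"]),
            t2_ms=np.asarray(f["t2"]),
            b1=np.asarray(f["b1"]),
            schedule_hash=str(f.attrs["schedule_hash"]),
        )
    if expect_schedule_hash is not None and d.schedule_hash != expect_schedule_hash:
        logger.warning(
            "dictionary schedule hash %s does not match acquisition %s",
            d.schedule_hash,
            expect_schedule_hash,
        )
    return d


def maps_to_nifti(
    maps: ParameterMaps,
    outdir,
    voxel_size_mm: tuple[float, float] = (1.875, 1.875),
    slice_spacing_mm: float = 20.8,
) -> list[Path]:
    """Write one NIfTI volume per parameter (slices stacked along z)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm[0], voxel_size_mm[1], slice_spacing_mm, 1.0])
    written = []
    for name, arr in (
        ("t1_ms", maps.t1_ms),
        ("t2_ms", maps.t2_ms),
        ("m0", maps.m0),
        ("residual", maps.residual),
    ):
        vol = np.moveaxis(np.asarray(arr, dtype=np.float32), 0, -1)  # (nx, ny, mb)
        img = nib.Nifti1Image(vol, affine)
        p = outdir / f"{name}.nii"
        nib.save(img, p)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# run configuration

_ALLOWED_KEYS = {
    "phantom": {"kind", "nx", "ny", "mb"},
    "schedule": {
        "heart_rate_bpm",
        "flip_deg",
        "tr_ms",
        "te_ms",
        "lines_per_beat",
        "center_line_index",
        "inv_efficiency",
        "trigger_delay_ms",
    },
    "pattern": {"r_inplane", "center_lines", "dense_center", "n_acs"},
    "sim": {"noise_sd", "n_coils"},
    "recon": {
        "method",
        "coils",
        "alpha",
        "beta",
        "mu1",
        "mu2",
        "block",
        "max_iter",
        "cg_tol",
        "cg_max_iter",
        "block_mode",
    },
    "mapping": {"protocol", "b1_roi"},
}


@dataclass
class RunConfig:
    """Validated configuration of the full pipeline; round-trips via YAML."""

    seed: int = 0
    outdir: str = "smsmap_out"
    phantom: dict = field(default_factory=lambda: {"kind": "vials", "nx": 96, "ny": 96, "mb": 3})
    schedule: dict = field(default_factory=lambda: {"heart_rate_bpm": 60.0})
    pattern: dict = field(default_factory=lambda: {"r_inplane": 4, "center_lines": 24})
    sim: dict = field(default_factory=lambda: {"noise_sd": 0.005, "n_coils": 8})
    recon: dict = field(default_factory=lambda: {"method": "llrs", "coils": "truth"})
    mapping: dict = field(default_factory=lambda: {"protocol": "phantom"})

    def __post_init__(self) -> None:
        errors = []
        for group, allowed in _ALLOWED_KEYS.items():
            extra = set(getattr(self, group)) - allowed
            if extra:
                errors.append(f"{group}: unknown keys {sorted(extra)}")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        extra = set(d) - known
        if extra:
            raise ValueError(f"invalid configuration: unknown top-level keys {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
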