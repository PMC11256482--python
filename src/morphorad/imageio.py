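"""NIfTI-1 volume and displacement-field I/O with strict geometry handling.

All internal computation happens in world millimetres through the voxel-to-world
affine; volumes are canonicalised to RAS+ orientation on load. Vector fields are
stored as 4D NIfTI with the vector dimension last.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

VALID_UNITS = ("arbitrary", "%", "s^-1", "um^2/s", "mm^2/s", "log-ratio", "label")


@dataclass
class Volume:
    """A scalar 3D (or 4D multi-channel) image with voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (X, Y, Z, 3)."""
        idx = np.indices(self.shape3, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        return self.voxel_to_world(ijk)

    def same_geometry(self, other: "Volume | DisplacementField", atol: float = 1e-5) -> bool:
        return self.shape3 == other.shape3 and np.allclose(self.affine, other.affine, atol=atol)

    def copy_with(self, data: np.ndarray, units: str | None = None) -> "Volume":
        return Volume(data=data, affine=self.affine.copy(), units=units or self.units)


@dataclass
class DisplacementField:
    """Dense displacement u(x) in world mm; the map is Phi(x) = x + u(x).

    direction tags which way the field points: ``template->subject`` fields are
    used to pull subject images back into template space, so det(grad Phi) > 1
    means the subject region is locally larger than the template's.
    """

    data: np.ndarray  # (X, Y, Z, 3) in mm
    affine: np.ndarray
    direction: str = "template->subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("displacement field must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def as_volume(self) -> Volume:
        return Volume(data=self.data, affine=self.affine, units="arbitrary")


def read_volume(path: str | Path, canonical: bool = True) -> Volume:
    """Read a NIfTI-1 volume, canonicalising to RAS+ orientation by default."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel raises several types
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise IOError(f"{path} is not a NIfTI image")
    if canonical:
        img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: str | Path, allow_nan: bool = False) -> Path:
    """Write a Volume to NIfTI-1; non-finite data is rejected unless allow_nan."""
    path = Path(path)
    if not allow_nan and not np.all(np.isfinite(volume.data)):
        raise ValueError(f"refusing to write non-finite data to {path} (pass allow_nan=True to override)")
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_field(path: str | Path) -> DisplacementField:
    vol = read_volume(path, canonical=False)
    if vol.data.ndim != 4 or vol.data.shape[-1] != 3:
        raise IOError(f"{path} does not hold a 3-vector displacement field")
    return DisplacementField(data=vol.data, affine=vol.affine)


def write_field(fieldobj: DisplacementField, path: str | Path) -> Path:
    return write_volume(fieldobj.as_volume(), path)


def read_labels(path: str | Path) -> Volume:
    """Read an integer label map; values are rounded to the nearest integer."""
    vol = read_volume(path)
    data = np.rint(vol.data).astype(np.int32)
    return Volume(data=data, affine=vol.affine, units="label")


def validate_volume(volume: Volume) -> dict:
    """Report basic integrity statistics (NaN/Inf counts, range) for a volume."""
    data = np.asarray(volume.data)
    finite = np.isfinite(data)
    report = {
        "shape": list(data.shape),
        "n_nan": int(np.isnan(data).sum()),
        "n_inf": int(np.isinf(data).sum()),
        "min": float(data[finite].min()) if finite.any() else None,
        "max": float(data[finite].max()) if finite.any() else None,
        "spacing_mm": [float(s) for s in volume.spacing],
    }
    return report


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Structured provenance log: stage entries with parameters, seeds, checksums."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.entries: list[dict] = []

    def log(self, stage: str, *, parameters: dict | None = None, seed: int | None = None,
            inputs: list[str] | None = None, outputs: list[str] | None = None) -> None:
        entry = {
            "stage": stage,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "parameters": parameters or {},
            "seed": seed,
            "inputs": inputs or [],
            "outputs": [],
        }
        for out in outputs or []:
            p = Path(out)
            entry["outputs"].append({"path": str(out), "sha256": checksum(p) if p.exists() else None})
        self.entries.append(entry)
        if self.path is not None:
            self.flush()

    def flush(self) -> None:
        if self.path is None:
            return
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.entries, fh, indent=2)
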