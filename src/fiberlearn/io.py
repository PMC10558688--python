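"""Image container and on-disk formats.

Arrays are indexed ``(z, y, x)``, 0-based; the fiber main axis is ``y`` once a
volume has been registered to the canonical reference. Physical spacing is in
micrometres per axis, stored in the same ``(z, y, x)`` order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


@dataclass
class FiberImage:
    """A 3D scalar volume with physical spacing and provenance metadata.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities.
    spacing : tuple of float
        Voxel size in µm, ``(z, y, x)`` order; strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in µm.
    meta : dict
        Free-form metadata (``sample_id``, ``study_id``, ...). The key
        ``history`` holds an append-only list of processing-step records.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(s) for s in self.origin)
        self.meta.setdefault("history", [])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Extent of the volume in µm per axis (shape × spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def with_voxels(self, voxels: np.ndarray, step: str | None = None, **params) -> "FiberImage":
        """Return a copy carrying new voxel data and an appended history record."""
        out = FiberImage(
            voxels=voxels,
            spacing=self.spacing,
            origin=self.origin,
            meta={**{k: v for k, v in self.meta.items() if k != "history"},
                  "history": list(self.meta.get("history", []))},
        )
        if step is not None:
            out.record(step, **params)
        return out

    def record(self, step: str, **params) -> None:
        self.meta["history"].append({"step": step, **params})

    @property
    def history(self) -> list[dict]:
        return self.meta["history"]

    def checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.voxels).tobytes()).hexdigest()[:16]


def write_tiff(img: FiberImage, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF (one page per z-slice)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sz, sy, sx = img.spacing
    tifffile.imwrite(
        path,
        np.asarray(img.voxels, dtype=np.float32),
        metadata={"spacing": sz, "axes": "ZYX", "unit": "um"},
        resolution=(1.0 / sx, 1.0 / sy),
    )
    return path


def read_tiff(path: str | Path, spacing: tuple[float, float, float] | None = None) -> FiberImage:
    """Read a multi-page TIFF volume; spacing recovered from metadata if present."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        if spacing is None:
            sz = sy = sx = 1.0
            meta = tf.imagej_metadata or tf.shaped_metadata and tf.shaped_metadata[0] or {}
            if isinstance(meta, dict) and "spacing" in meta:
                sz = float(meta["spacing"])
            page = tf.pages[0]
            if "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                if num:
                    sx = den / num
            if "YResolution" in page.tags:
                num, den = page.tags["YResolution"].value
                if num:
                    sy = den / num
            spacing = (sz, sy, sx)
    return FiberImage(voxels=voxels, spacing=spacing, meta={"path": str(path)})


def write_nifti(img: FiberImage, path: str | Path) -> Path:
    """Write a volume as NIfTI with spacing in the header (axes reordered x,y,z)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sz, sy, sx = img.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    # nibabel expects (x, y, z) axis order
    data = np.ascontiguousarray(np.transpose(img.voxels, (2, 1, 0)).astype(np.float32))
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_nifti(path: str | Path) -> FiberImage:
    nii = nib.load(str(path))
    data = np.transpose(np.asanyarray(nii.dataobj), (2, 1, 0))
    zooms = nii.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return FiberImage(voxels=data, spacing=spacing, meta={"path": str(path)})


def read_image(path: str | Path) -> FiberImage:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        return read_nifti(path)
    return read_tiff(path)


class Labbook:
    """Append-only JSONL log of pipeline steps and trial records.

    Every standardization step and every meta-optimization trial appends one
    line, so a run can be audited or resumed from the log alone.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.entries: list[dict] = []
        if self.path is not None and self.path.exists():
            with open(self.path) as fh:
                self.entries = [json.loads(line) for line in fh if line.strip()]

    def log(self, kind: str, **record) -> dict:
        entry = {"kind": kind, **_jsonable(record)}
        self.entries.append(entry)
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            with open(self.path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        return entry

    def __len__(self) -> int:
        return len(self.entries)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
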