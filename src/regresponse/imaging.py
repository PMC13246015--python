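"""Core imaging types and I/O.

Geometry convention: arrays are indexed ``(i, j, k)`` with the axial plane
spanned by the first two axes and ``k`` the slice (z) axis.  Voxel indices
are 0-based and the physical position of voxel ``(i, j, k)`` is
``origin + (i*sx, j*sy, k*sz)``; all distances are measured between voxel
centers.  Only axis-aligned geometries are supported: oblique affines are
rejected on read, which keeps every geometric contract in the package
exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "VolumeImage",
    "LabelMask",
    "ReaderAnnotation",
    "SurvivalRecord",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_volume",
    "read_annotations",
    "write_annotations",
    "read_survival",
    "write_survival",
]

MIN_SHAPE = (8, 8, 4)

ANNOTATION_COLUMNS = [
    "patient_id",
    "reader_id",
    "experience",
    "timepoint",
    "longest_diameter_mm",
    "perpendicular_diameter_mm",
    "slice_index",
]

SURVIVAL_COLUMNS = ["patient_id", "endpoint", "time_days", "event"]


class GeometryError(ValueError):
    """Raised when image/mask geometries are incompatible or unsupported."""


def _as_tuple3(x: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    voxels :
        3D array of intensities (HU-like, arbitrary units).
    spacing :
        Physical voxel size ``(sx, sy, sz)`` in mm; all components > 0.
    origin :
        Physical position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"non-3D image: got {vox.ndim} dimensions")
        if any(n < m for n, m in zip(vox.shape, MIN_SHAPE)):
            raise ValueError(f"image shape {vox.shape} below minimum {MIN_SHAPE}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("non-finite voxels in image")
        sp = _as_tuple3(self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple3(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "VolumeImage | LabelMask", tol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class LabelMask:
    """A binary region sharing the grid of a :class:`VolumeImage`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"non-3D mask: got {vox.ndim} dimensions")
        vals = np.unique(vox)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be binary, found {vals[:10]}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        sp = _as_tuple3(self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple3(self.origin))

    @classmethod
    def on_grid_of(cls, image: "VolumeImage | LabelMask", voxels: np.ndarray) -> "LabelMask":
        return cls(voxels=voxels, spacing=image.spacing, origin=image.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "VolumeImage | LabelMask", tol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass(frozen=True)
class ReaderAnnotation:
    """One reader's segmentations and diameter annotations at one timepoint."""

    reader_id: str
    experience: str  # "junior" | "senior"
    timepoint: str  # "pre" | "post"
    pancreas_mask: LabelMask
    tumor_mask: LabelMask
    longest_diameter: float  # mm
    perpendicular_diameter: float  # mm
    slice_index: int

    def __post_init__(self) -> None:
        if self.experience not in ("junior", "senior"):
            raise ValueError(f"experience must be junior/senior, got {self.experience!r}")
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be pre/post, got {self.timepoint!r}")
        if self.longest_diameter < 0 or self.perpendicular_diameter < 0:
            raise ValueError("diameters must be >= 0")
        if self.perpendicular_diameter > self.longest_diameter + 1e-9:
            raise ValueError("perpendicular diameter exceeds longest diameter")


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored survival outcome for one patient and endpoint."""

    patient_id: str
    time: float  # days
    event: int  # 1 = event observed, 0 = censored
    endpoint: str  # "OS" | "RFS"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.endpoint not in ("OS", "RFS"):
            raise ValueError(f"endpoint must be OS/RFS, got {self.endpoint!r}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine_from_geometry(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(affine: np.ndarray) -> tuple[tuple[float, ...], tuple[float, ...]]:
    lin = affine[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    # axis-aligned check: each column must be +/- a scaled unit vector
    if np.any(np.abs(lin) - np.diag(np.abs(np.diag(lin))) > 1e-4 * spacing.max()):
        raise GeometryError("oblique affine: only axis-aligned geometries are supported")
    if np.any(np.diag(lin) < 0):
        raise GeometryError("negative axis direction: only positive axis-aligned affines supported")
    return tuple(float(s) for s in spacing), tuple(float(o) for o in affine[:3, 3])


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume; spacing/origin are taken from the affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    spacing, origin = _geometry_from_affine(img.affine)
    return VolumeImage(voxels=data, spacing=spacing, origin=origin)


def write_volume(image: VolumeImage, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(image.voxels, dtype=np.float32), _affine_from_geometry(image.spacing, image.origin))
    nib.save(nii, str(path))


def read_mask(path: str | Path, geometry: VolumeImage | LabelMask) -> LabelMask:
    """Read a binary mask and bind it to ``geometry``.

    Voxel values are rounded at 0.5; more than two distinct values is an
    error, as is any shape/spacing/origin disagreement beyond 1e-3 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"non-3D mask: {path} has {data.ndim} dimensions")
    vals = np.unique(data)
    if len(vals) > 2:
        raise ValueError(f"multi-label mask: found {len(vals)} distinct values in {path}")
    spacing, origin = _geometry_from_affine(img.affine)
    if data.shape != geometry.shape:
        raise GeometryError(f"mask shape {data.shape} does not match geometry {geometry.shape}")
    if not np.allclose(spacing, geometry.spacing, atol=1e-3):
        raise GeometryError(f"mask spacing {spacing} does not match geometry {geometry.spacing}")
    if not np.allclose(origin, geometry.origin, atol=1e-3):
        raise GeometryError(f"mask origin {origin} does not match geometry {geometry.origin}")
    binary = (data >= 0.5).astype(np.uint8)
    return LabelMask(voxels=binary, spacing=geometry.spacing, origin=geometry.origin)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    nii = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from_geometry(mask.spacing, mask.origin))
    nib.save(nii, str(path))


def mask_volume(mask: LabelMask) -> float:
    """Volume of a binary mask in mm³ (voxel count × voxel volume)."""
    return float(mask.voxels.sum()) * mask.voxel_volume


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def annotations_to_frame(rows: Iterable[tuple[str, ReaderAnnotation]]) -> pd.DataFrame:
    """Flatten ``(patient_id, annotation)`` pairs into the annotation table."""
    recs = []
    for patient_id, ann in rows:
        recs.append(
            {
                "patient_id": patient_id,
                "reader_id": ann.reader_id,
                "experience": ann.experience,
                "timepoint": ann.timepoint,
                "longest_diameter_mm": ann.longest_diameter,
                "perpendicular_diameter_mm": ann.perpendicular_diameter,
                "slice_index": ann.slice_index,
            }
        )
    return pd.DataFrame(recs, columns=ANNOTATION_COLUMNS)


def write_annotations(frame: pd.DataFrame, path: str | Path) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    frame[ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return frame


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"patient_id": r.patient_id, "endpoint": r.endpoint, "time_days": r.time, "event": r.event}
            for r in records
        ],
        columns=SURVIVAL_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    frame = pd.read_csv(path)
    missing = set(SURVIVAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return [
        SurvivalRecord(
            patient_id=str(row.patient_id),
            time=float(row.time_days),
            event=int(row.event),
            endpoint=str(row.endpoint),
        )
        for row in frame.itertuples()
    ]
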