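"""Voxel grids with world coordinates and NIfTI I/O.

The whole package works on isotropic 3-D grids. World coordinates are in
millimetres; the world position of voxel ``(i, j, k)`` is
``origin_mm + (i, j, k) * voxel_size_mm`` (voxel-centre convention, 0-based
indices). Activity is carried in kBq/cc, attenuation in cm^-1 at 511 keV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: accepted ``unit`` strings
UNITS = ("kBq/cc", "cm-1", "HU", "arbitrary-MR", "label", "percent")


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with isotropic voxel size and a world origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel. Stored as float64 except for ``unit='label'``
        volumes, which keep an integer dtype.
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    origin_mm : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    unit : str
        One of :data:`UNITS`.
    """

    values: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "kBq/cc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.unit == "label":
            if not np.issubdtype(self.values.dtype, np.integer):
                self.values = self.values.astype(np.int32)
        else:
            self.values = self.values.astype(np.float64, copy=False)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"values must be 3-D with positive shape, got {self.values.shape}")
        if not float(self.voxel_size_mm) > 0:
            raise ValueError("voxel_size_mm must be > 0")
        self.voxel_size_mm = float(self.voxel_size_mm)
        self.origin_mm = tuple(float(c) for c in self.origin_mm)
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.unit == "percent":
            # percent-difference images encode "undefined outside the mask" as NaN
            if np.any(np.isinf(self.values)):
                raise ValueError("values must not be infinite")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (= cm^3)."""
        return (self.voxel_size_mm / 10.0) ** 3

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along ``axis``."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate arrays (mm), each of shape (nx, ny, nz)."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        """World coordinate of the grid centre."""
        return tuple(
            self.origin_mm[a] + self.voxel_size_mm * (self.shape[a] - 1) / 2.0 for a in range(3)
        )

    def world_to_index(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world point (mm)."""
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / self.voxel_size_mm

    def like(self, values: np.ndarray, unit: str | None = None) -> "VoxelVolume":
        """New volume on this grid with different ``values`` (and unit)."""
        return replace(self, values=values, unit=unit or self.unit)

    # -- I/O --------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> Path:
        """Write as NIfTI (.nii or .nii.gz); unit goes in the header descrip."""
        path = Path(path)
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float64), affine)
        img.header["descrip"] = self.unit.encode()
        zooms = (self.voxel_size_mm,) * 3
        img.header.set_zooms(zooms)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, unit: str | None = None) -> "VoxelVolume":
        img = nib.load(str(path))
        affine = img.affine
        vs = float(affine[0, 0])
        if not np.allclose(np.diag(affine)[:3], vs) or vs <= 0:
            raise ValueError("only axis-aligned isotropic NIfTI volumes are supported")
        if unit is None:
            unit = img.header["descrip"].tobytes().rstrip(b"\x00").decode() or "kBq/cc"
        values = np.asarray(img.dataobj, dtype=np.float64)
        if unit == "label":
            values = np.rint(values).astype(np.int32)
        return cls(values=values, voxel_size_mm=vs, origin_mm=tuple(affine[:3, 3]), unit=unit)


#: alias used for attenuation volumes (unit "cm-1")
MuMap = VoxelVolume


def make_grid(
    shape: tuple[int, int, int],
    voxel_size_mm: float,
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    unit: str = "kBq/cc",
) -> VoxelVolume:
    """Zero-filled volume whose grid centre sits at ``center_mm``."""
    shape = tuple(int(n) for n in shape)
    origin = tuple(
        center_mm[a] - voxel_size_mm * (shape[a] - 1) / 2.0 for a in range(3)
    )
    dtype = np.int32 if unit == "label" else np.float64
    return VoxelVolume(np.zeros(shape, dtype=dtype), voxel_size_mm, origin, unit)


def save_label_dictionary(labels: dict[int, str], path: str | Path) -> Path:
    """JSON sidecar mapping integer label ids to names."""
    path = Path(path)
    path.write_text(json.dumps({str(k): v for k, v in labels.items()}, indent=2))
    return path


def load_label_dictionary(path: str | Path) -> dict[int, str]:
    return {int(k): v for k, v in json.loads(Path(path).read_text()).items()}
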