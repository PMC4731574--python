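"""Volume and table IO, voxel/mm coordinate handling.

All volumes in one analysis session share a single :class:`VolumeGeometry`
(dims + affine). Voxel indices are 0-based everywhere inside the package;
user-facing coordinates are millimetres obtained through the affine, so
reports are unambiguous about indexing conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and voxel→mm affine of a 3D volume.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along x, y, z.
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices (homogeneous) to mm coordinates.
        Must be invertible.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is singular")
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be a positive integer triple, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    def matches(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)

    def require_match(self, other: "VolumeGeometry") -> None:
        if not self.matches(other):
            raise ValueError(
                f"geometry mismatch: dims {self.dims} vs {other.dims} "
                f"or affines differ"
            )


def voxel_to_mm(voxel: tuple[int, int, int], geometry: VolumeGeometry) -> np.ndarray:
    """Map a 0-based voxel index triple to mm coordinates via the affine."""
    ijk = np.asarray(voxel, dtype=float)
    if ijk.shape != (3,):
        raise ValueError("voxel must be a triple")
    if np.any(ijk < 0) or np.any(ijk >= np.asarray(geometry.dims)):
        raise ValueError(f"voxel {voxel} out of bounds for dims {geometry.dims}")
    return (geometry.affine @ np.append(ijk, 1.0))[:3]


def mm_to_voxel(mm: tuple[float, float, float], geometry: VolumeGeometry) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm` (continuous, not rounded)."""
    xyz = np.append(np.asarray(mm, dtype=float), 1.0)
    return (np.linalg.inv(geometry.affine) @ xyz)[:3]


def write_volume(volume: np.ndarray, geometry: VolumeGeometry, path: str | Path) -> Path:
    """Write a 3D volume or 4D series as NIfTI-1 (float64)."""
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D array, got ndim={volume.ndim}")
    if tuple(volume.shape[:3]) != geometry.dims:
        raise ValueError(
            f"volume shape {volume.shape[:3]} does not match geometry dims {geometry.dims}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.astype(np.float64), geometry.affine)
    nib.save(img, str(path))
    return path


def read_volume(
    path: str | Path, reference: VolumeGeometry | None = None
) -> tuple[np.ndarray, VolumeGeometry]:
    """Read a NIfTI-1 volume; optionally check it against a session reference.

    Returns
    -------
    (data, geometry)
        ``data`` is float64, 3D or 4D; ``geometry`` describes the first
        three axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    geometry = VolumeGeometry(tuple(int(d) for d in data.shape[:3]), np.asarray(img.affine))
    if reference is not None:
        reference.require_match(geometry)
    return data, geometry


SCHEDULE_COLUMNS = [
    "subject",
    "run",
    "onset_s",
    "modality",
    "stim_type",
    "role",
    "identity",
    "color",
    "is_oddball",
    "has_button_press",
    "has_error",
]

CLUSTER_COLUMNS = [
    "size_voxels",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
    "peak_t",
    "peak_z_equiv",
    "com_x_mm",
    "com_y_mm",
    "com_z_mm",
]


def write_schedule_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a block-schedule table with the frozen column set."""
    missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"schedule table missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame[SCHEDULE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_schedule_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEDULE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"schedule table missing columns: {missing}")
    for col in ("is_oddball", "has_button_press", "has_error"):
        frame[col] = frame[col].astype(bool)
    return frame


def write_cluster_table(clusters, stat_map, path: str | Path) -> pd.DataFrame:
    """Write a TSV inventory of clusters (peak/center-of-mass in mm).

    ``peak_z_equiv`` is the standard-normal deviate with the same upper-tail
    probability as the peak t value (NaN when the map carries no df).
    """
    from fairmirror.univariate import t_to_z

    rows = []
    for cl in clusters:
        peak_mm = voxel_to_mm(cl.peak_voxel, stat_map.geometry)
        z_equiv = (
            t_to_z(cl.peak_value, stat_map.df)
            if (stat_map.kind == "t" and stat_map.df is not None)
            else np.nan
        )
        rows.append(
            {
                "size_voxels": cl.size_voxels,
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
                "peak_t": cl.peak_value,
                "peak_z_equiv": z_equiv,
                "com_x_mm": cl.center_of_mass_mm[0],
                "com_y_mm": cl.center_of_mass_mm[1],
                "com_z_mm": cl.center_of_mass_mm[2],
            }
        )
    frame = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return frame
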