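"""Volume and cohort-table I/O.

All voxel-wise math in this package assumes every volume of an analysis lives
on one sampling grid (same shape, same affine): subject R1 maps, tissue
probability maps and atlas coefficient maps are compared voxel by voxel, so
spatial registration must have happened upstream. :func:`assert_shared_grid`
enforces that contract at every entry point.

Conventions: voxel indexing is 0-based, world coordinates follow the NIfTI
affine, and volume data are promoted to float64 on read regardless of the
on-disk dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import CohortTableError, FormatError, GridMismatchError

__all__ = [
    "VolumeGrid",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "assert_shared_grid",
    "read_cohort_table",
    "write_cohort_table",
]

#: groups understood by the cohort table reader
GROUPS = ("control", "welder")


@dataclass
class VolumeGrid:
    """A 3D scalar field plus its voxel-to-world transform.

    Parameters
    ----------
    data:
        3D array (any numeric dtype; label volumes stay integer, scalar maps
        are usually float64).
    affine:
        4x4 voxel-to-world transform as in NIfTI.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be a 4x4 matrix")
        if np.any(self.voxel_size <= 0):
            raise FormatError("voxel sizes derived from the affine must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New volume carrying ``data`` on this grid."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise GridMismatchError(
                f"data shape {data.shape} does not match grid {self.data.shape}"
            )
        return VolumeGrid(data, self.affine.copy())


@dataclass
class SubjectRecord:
    """Demographics and exposure indices for one subject.

    Exposure indices (``cei_3m``, ``cei_life`` in mg/m^3*yr, ``air_mn`` in
    mg/m^3) may be absent for controls.
    """

    subject_id: str
    age: int
    group: str
    cei_3m: float | None = None
    cei_life: float | None = None
    air_mn: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise CohortTableError(f"{self.subject_id}: age must be >= 0, got {self.age}")
        if self.group not in GROUPS:
            raise CohortTableError(
                f"{self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        for name in ("cei_3m", "cei_life", "air_mn"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CohortTableError(
                    f"{self.subject_id}: exposure index {name} must be >= 0, got {value}"
                )


def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI-1/NIfTI-2 volume as a float64 :class:`VolumeGrid`.

    4D files with a singleton last axis are squeezed to 3D; any other
    dimensionality is a :class:`FormatError`.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, got shape {data.shape}")
    return VolumeGrid(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(volume: VolumeGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI; scalar data are stored as float32 by default."""
    path = Path(path)
    data = volume.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))
    return path


def assert_shared_grid(volumes: Sequence[VolumeGrid], tol: float = 1e-6) -> None:
    """Check that all volumes share one grid (equal shapes, affines within tol).

    Raises :class:`GridMismatchError` naming the first offending volume.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        return
    ref = volumes[0]
    for i, vol in enumerate(volumes[1:], start=1):
        if vol.shape != ref.shape:
            raise GridMismatchError(
                f"volume {i} has shape {vol.shape}, expected {ref.shape}"
            )
        if not np.allclose(vol.affine, ref.affine, rtol=tol, atol=tol):
            raise GridMismatchError(f"volume {i} affine differs beyond tol={tol}")


_TABLE_COLUMNS = ("subject_id", "age", "group", "cei_3m", "cei_life", "air_mn")


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV (subject_id, age, group, cei_3m, cei_life, air_mn).

    Missing exposure cells are allowed (typically for controls); missing id or
    age is a :class:`CohortTableError`. An empty file yields an empty list.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    for required in ("subject_id", "age", "group"):
        if required not in table.columns:
            raise CohortTableError(f"{path}: missing required column {required!r}")
    records = []
    for _, row in table.iterrows():
        if pd.isna(row["subject_id"]) or pd.isna(row["age"]):
            raise CohortTableError(f"{path}: row with missing subject_id or age")
        age = float(row["age"])
        if age != int(age):
            raise CohortTableError(f"{path}: age must be a whole number, got {age}")
        kwargs = {}
        for name in ("cei_3m", "cei_life", "air_mn"):
            value = row.get(name)
            kwargs[name] = None if value is None or pd.isna(value) else float(value)
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=int(age),
                group=str(row["group"]).strip().lower(),
                **kwargs,
            )
        )
    return records


def write_cohort_table(records: Iterable[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": r.subject_id,
            "age": r.age,
            "group": r.group,
            "cei_3m": r.cei_3m,
            "cei_life": r.cei_life,
            "air_mn": r.air_mn,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_TABLE_COLUMNS)).to_csv(path, index=False)
    return path
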