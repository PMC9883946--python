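"""NIfTI and tabular I/O with validated in-memory containers.

The pipeline operates on 4D dynamic contrast-enhanced series that are assumed
to be co-registered to a common space already; masks and label volumes must
share the series grid exactly (no resampling is performed here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageSeries4D",
    "LabelVolume",
    "CohortTable",
    "read_series",
    "write_series",
    "read_labels",
    "write_labels",
    "write_table",
]

#: Default DCE acquisition schedule: one frame every 5 min from 30 to 150 min
#: after the start of intracisternal contrast infusion (t = 0).
DEFAULT_FRAME_TIMES_MIN: tuple[float, ...] = tuple(float(t) for t in range(30, 151, 5))


@dataclass
class ImageSeries4D:
    """A subject's spatiotemporal signal with an explicit time axis.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, n_frames)``, finite intensities.
    frame_times_min
        Strictly increasing frame acquisition times in minutes since the
        start of contrast injection.
    voxel_size_mm
        Physical voxel dimensions.
    """

    data: np.ndarray
    frame_times_min: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.188, 0.156, 0.188)
    subject_id: str = ""
    group_label: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_min = np.asarray(self.frame_times_min, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] != self.frame_times_min.size:
            raise ValueError(
                f"frame count mismatch: data has {self.data.shape[3]} frames "
                f"but {self.frame_times_min.size} frame times were supplied"
            )
        if self.frame_times_min.size and self.frame_times_min[0] < 0:
            raise ValueError("frame times must be >= 0 minutes post-injection")
        if np.any(np.diff(self.frame_times_min) <= 0):
            raise ValueError("frame_times_min must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series contains non-finite voxel intensities")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelVolume:
    """Integer label volume on the same grid as a companion series (0 = background)."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must hold integer values")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int | Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask of one label, several labels, or everything non-zero."""
        if label is None:
            return self.labels > 0
        if np.isscalar(label):
            return self.labels == label
        return np.isin(self.labels, np.asarray(label))

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass
class CohortTable:
    """Subject → group assignment plus per-subject series paths."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "group_label", "series_path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("subject_id values must be unique")

    @classmethod
    def from_csv(cls, path: str | Path, check_paths: bool = True) -> "CohortTable":
        frame = pd.read_csv(path)
        table = cls(frame)
        if check_paths:
            root = Path(path).parent
            for p in frame["series_path"]:
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = root / candidate
                if not candidate.exists():
                    raise FileNotFoundError(f"series file not found: {p}")
        return table

    def groups(self) -> list[str]:
        return sorted(self.frame["group_label"].unique())

    def subjects_in(self, group: str) -> list[str]:
        sel = self.frame["group_label"] == group
        return list(self.frame.loc[sel, "subject_id"])


def read_series(
    path: str | Path,
    frame_times_min: Sequence[float] = DEFAULT_FRAME_TIMES_MIN,
    subject_id: str = "",
    group_label: str = "",
) -> ImageSeries4D:
    """Load a 4D NIfTI series; frame times are supplied explicitly.

    Header timing metadata is deliberately ignored (TR semantics are unreliable
    for interleaved DCE protocols); the caller states the acquisition schedule.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D NIfTI, got {data.ndim}D: {path}")
    n_times = len(frame_times_min)
    if data.shape[3] != n_times:
        raise ValueError(
            f"file has {data.shape[3]} frames but {n_times} frame times were supplied"
        )
    zooms = img.header.get_zooms()[:3]
    return ImageSeries4D(
        data=data.astype(float),
        frame_times_min=np.asarray(frame_times_min, dtype=float),
        voxel_size_mm=tuple(float(z) for z in zooms),
        subject_id=subject_id,
        group_label=group_label,
        affine=np.asarray(img.affine),
    )


def write_series(series: ImageSeries4D, path: str | Path) -> None:
    """Write a series as float32 NIfTI, voxel size in the header zooms."""
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(series.voxel_size_mm) + (1.0,))
    nib.save(img, str(path))


def read_labels(path: str | Path, name_map: Mapping[int, str] | None = None) -> LabelVolume:
    """Load a 3D integer NIfTI label volume.

    Float-valued files are rejected unless every voxel is an exact integer.
    Labels present in the file but absent from ``name_map`` are kept and a
    warning is emitted.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D label NIfTI, got {data.ndim}D: {path}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"label volume contains non-integer values: {path}")
        data = rounded.astype(np.int32)
    names = dict(name_map) if name_map else {}
    vol = LabelVolume(labels=data.astype(np.int32), names=names, affine=np.asarray(img.affine))
    if names:
        unnamed = [v for v in vol.present_labels() if v not in names]
        if unnamed:
            warnings.warn(f"labels present but unnamed: {unnamed}", stacklevel=2)
    return vol


def write_labels(vol: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.affine)
    nib.save(img, str(path))


def write_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write tabular results as CSV, round-tripping at 12 significant digits."""
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if frame.empty:
        raise ValueError("refusing to write an empty results table")
    frame.to_csv(path, index=False, float_format="%.12g")
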