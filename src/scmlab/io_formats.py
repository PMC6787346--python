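"""Readers, writers and validated domain containers for the pipeline's file formats.

Volumes and label maps are NIfTI-1 (via nibabel); activity tables and all
result tables are tidy CSV; electrophysiology traces are two-column CSV
(time_s, value) with the sampling rate inferred from the time stamps.

No reorientation is attempted: volumes, masks and atlases must already share
a common voxel index space (co-registration is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import nibabel as nib

__all__ = [
    "IntensityVolume",
    "LabelAtlas",
    "ActivityTable",
    "EphysTrace",
    "read_volume",
    "write_volume",
    "read_label_atlas",
    "write_label_atlas",
    "read_activity_csv",
    "write_activity_csv",
    "read_trace",
    "write_trace",
]

VALID_BIN_WIDTHS_MIN = (5, 15, 60)

ACTIVITY_COLUMNS = ["animal_id", "genotype", "bin_start", "bin_width_min", "value"]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class IntensityVolume:
    """A 3D T1-weighted intensity grid with voxel-size metadata.

    ``data`` is in arbitrary scanner units and must be finite and
    non-negative; ``voxel_size_mm`` is the physical voxel edge length.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite voxels")
        if np.any(self.data < 0):
            raise FormatError("volume contains negative intensities")
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise FormatError("voxel_size_mm must be a 3-vector of positive reals")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelAtlas:
    """An integer ROI label map plus label → ROI-name lookup.

    Label 0 is background; every nonzero label present in ``labels`` must be
    named in ``names``.
    """

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise FormatError("label map must be integer-valued")
            self.labels = as_int
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative (0 = background)")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise FormatError(f"unnamed labels in atlas: {sorted(missing)}")
        self.names = {int(k): str(v) for k, v in self.names.items()}

    @property
    def roi_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


@dataclass
class ActivityTable:
    """Long-format binned activity: one row per (animal, time bin).

    ``value`` is distance in cm (open field) or wheel revolutions (counts).
    Bins for one animal must be uniform in width, non-overlapping, and one of
    5, 15 or 60 minutes wide.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"activity table missing columns: {missing}")
        df = df.copy()
        df["bin_start"] = pd.to_datetime(df["bin_start"])
        df["bin_width_min"] = df["bin_width_min"].astype(int)
        df["value"] = df["value"].astype(float)
        if df["value"].isna().any() or (df["value"] < 0).any():
            raise FormatError("activity values must be non-negative and finite")
        bad_widths = set(df["bin_width_min"].unique()) - set(VALID_BIN_WIDTHS_MIN)
        if bad_widths:
            raise FormatError(
                f"unknown bin widths {sorted(bad_widths)}; allowed: {VALID_BIN_WIDTHS_MIN}"
            )
        for animal, sub in df.groupby("animal_id", sort=False):
            if sub["bin_width_min"].nunique() > 1:
                raise FormatError(f"animal {animal!r} mixes bin widths")
            if sub["bin_start"].duplicated().any():
                raise FormatError(f"animal {animal!r} has duplicated/overlapping bins")
            starts = sub["bin_start"].sort_values()
            width = pd.Timedelta(minutes=int(sub["bin_width_min"].iloc[0]))
            gaps = starts.diff().dropna()
            if (gaps < width).any():
                raise FormatError(f"animal {animal!r} has overlapping bins")
        df = df.sort_values(["animal_id", "bin_start"], kind="stable").reset_index(drop=True)
        self.frame = df

    @property
    def bin_width_min(self) -> int:
        widths = self.frame["bin_width_min"].unique()
        if len(widths) != 1:
            raise FormatError("table mixes bin widths across animals")
        return int(widths[0])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class EphysTrace:
    """A uniformly sampled electrophysiology trace.

    ``samples`` are pA in voltage clamp and mV in current clamp.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    mode: str  # "voltage_clamp" | "current_clamp"
    cell_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise FormatError(f"unknown recording mode {self.mode!r}")
        if self.sampling_rate_hz < 1000:
            raise FormatError("sampling_rate_hz must be >= 1000")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path: str | Path, subject_id: str = "", group_label: str = "") -> IntensityVolume:
    """Load a 3D NIfTI volume. Fails loudly on 4D images and NaN voxels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise FormatError(f"expected 3D volume, got shape {data.shape}")
    voxsize = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return IntensityVolume(
        data=data,
        voxel_size_mm=voxsize,
        subject_id=subject_id or path.stem.split(".")[0],
        group_label=group_label,
    )


def write_volume(volume: IntensityVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(tuple(volume.voxel_size_mm))
    nib.save(img, str(path))
    return path


def read_label_atlas(labels_path: str | Path, names_path: str | Path) -> LabelAtlas:
    """Load an integer label NIfTI and a two-column (label,name) CSV."""
    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise FileNotFoundError(labels_path)
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise FormatError(f"expected 3D label map, got shape {labels.shape}")
    names_df = pd.read_csv(names_path)
    if not {"label", "name"}.issubset(names_df.columns):
        raise FormatError("ROI names file needs columns: label, name")
    names = dict(zip(names_df["label"].astype(int), names_df["name"].astype(str)))
    return LabelAtlas(labels=np.rint(labels).astype(np.int64), names=names)


def write_label_atlas(atlas: LabelAtlas, labels_path: str | Path, names_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(labels_path))
    pd.DataFrame(
        {"label": sorted(atlas.names), "name": [atlas.names[k] for k in sorted(atlas.names)]}
    ).to_csv(names_path, index=False)


# ---------------------------------------------------------------------------
# activity table I/O


def read_activity_csv(path: str | Path) -> ActivityTable:
    """Read and validate a long-format activity CSV (see :class:`ActivityTable`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return ActivityTable(df)


def write_activity_csv(table: ActivityTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.frame.copy()
    out["bin_start"] = out["bin_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# trace I/O

_TIME_TOL_S = 1e-6


def read_trace(
    path: str | Path,
    mode: str = "voltage_clamp",
    cell_id: str = "",
    animal_id: str = "",
) -> EphysTrace:
    """Read a (time_s, value) CSV trace; sampling rate is inferred.

    Raises if the sampling grid is non-uniform beyond 1 µs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise FormatError("trace file needs columns: time_s, value")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("trace needs at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > _TIME_TOL_S):
        raise FormatError("non-uniform sampling beyond 1e-6 s tolerance")
    return EphysTrace(
        samples=df["value"].to_numpy(dtype=float),
        sampling_rate_hz=1.0 / dt[0],
        mode=mode,
        cell_id=cell_id or path.stem,
        animal_id=animal_id,
    )


def write_trace(trace: EphysTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "value": trace.samples}).to_csv(path, index=False)
    return path
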