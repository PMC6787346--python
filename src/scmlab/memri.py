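"""Manganese-enhanced MRI (MEMRI) activity mapping.

Mn2+ entering active neurons brightens T1-weighted images, but raw signal is
non-quantitative and varies scan to scan, so each scan is normalized to a
voxel-wise z-map using its own in-brain mean and dispersion. "Active" voxels
are those with z >= 1 (boundary included); per-ROI counts of suprathreshold
voxels are the activity statistic, compared between groups with a pooled
-variance two-sample t-test.

The field's shorthand for the dispersion is ambiguous (sigma can denote SD or
variance); both divisor conventions are implemented and recorded in the
normalization record, with SD the default. Because the count statistic is
threshold-relative, the convention only rescales the effective threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntensityVolume, LabelAtlas

__all__ = [
    "ZMap",
    "normalize_zmap",
    "threshold_zmap",
    "count_suprathreshold",
    "count_cohort",
    "compare_roi_counts",
    "compare_all_rois",
]

DEFAULT_Z_THRESHOLD = 1.0


class DegenerateScanError(ValueError):
    """In-mask dispersion is zero: the scan cannot be z-normalized."""


@dataclass(frozen=True)
class NormalizationRecord:
    mean_in_mask: float
    dispersion_in_mask: float
    divisor_convention: str  # "sd" | "variance"
    ddof: int = 1  # sample (n-1) dispersion


@dataclass
class ZMap:
    """A z-normalized volume. Out-of-mask voxels are exactly 0."""

    data: np.ndarray
    mask: np.ndarray
    normalization: NormalizationRecord
    subject_id: str = ""
    group_label: str = ""
    threshold_applied: float | None = None


def normalize_zmap(
    volume: IntensityVolume,
    mask: np.ndarray,
    divisor_convention: str = "sd",
) -> ZMap:
    """Convert a scan to a z-map: z_i = (x_i - mean) / D over the brain mask.

    mean and D are computed over in-mask voxels only (the extracted brain
    volume); D is the sample SD (``divisor_convention="sd"``, default) or the
    sample variance (``"variance"``). Out-of-mask voxels are set to 0.
    """
    if divisor_convention not in ("sd", "variance"):
        raise ValueError(f"divisor_convention must be 'sd' or 'variance', got {divisor_convention!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.data.shape}")
    vals = volume.data[mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    mean = float(np.mean(vals))
    var = float(np.var(vals, ddof=1))
    if var <= 0.0:
        raise DegenerateScanError("degenerate scan: zero in-mask dispersion")
    divisor = np.sqrt(var) if divisor_convention == "sd" else var
    z = np.zeros_like(volume.data, dtype=float)
    z[mask] = (vals - mean) / divisor
    record = NormalizationRecord(
        mean_in_mask=mean,
        dispersion_in_mask=divisor,
        divisor_convention=divisor_convention,
    )
    return ZMap(
        data=z,
        mask=mask,
        normalization=record,
        subject_id=volume.subject_id,
        group_label=volume.group_label,
    )


def threshold_zmap(zmap: ZMap, z_threshold: float = DEFAULT_Z_THRESHOLD) -> ZMap:
    """Zero all voxels with z below the threshold; z >= threshold survive."""
    data = np.where(zmap.data >= z_threshold, zmap.data, 0.0)
    data[~zmap.mask] = 0.0
    return replace(zmap, data=data, threshold_applied=z_threshold)


def count_suprathreshold(
    zmap: ZMap,
    atlas: LabelAtlas,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Count in-mask voxels with z >= threshold in each named ROI.

    Counting is threshold-relative on the stored z-values, so it commutes
    with :func:`threshold_zmap` for the same threshold (thresholding only
    zeroes voxels that would not be counted anyway).

    Returns a tidy frame: subject_id, group_label, roi_name,
    n_suprathreshold, n_total_roi_voxels.
    """
    if atlas.labels.shape != zmap.data.shape:
        raise ValueError("atlas shape does not match z-map shape")
    supra = zmap.mask & (zmap.data >= z_threshold)
    rows = []
    for label in sorted(atlas.names):
        roi = atlas.labels == label
        n_total = int(np.count_nonzero(roi & zmap.mask))
        n_above = int(np.count_nonzero(roi & supra))
        if n_total == 0:
            warnings.warn(
                f"ROI {atlas.names[label]!r} has zero voxels in mask", stacklevel=2
            )
        rows.append(
            {
                "subject_id": zmap.subject_id,
                "group_label": zmap.group_label,
                "roi_name": atlas.names[label],
                "n_suprathreshold": n_above,
                "n_total_roi_voxels": n_total,
            }
        )
    return pd.DataFrame(rows)


def count_cohort(
    zmaps: list[ZMap],
    atlas: LabelAtlas,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Stack per-subject suprathreshold counts into one ROICountTable."""
    return pd.concat(
        [count_suprathreshold(z, atlas, z_threshold) for z in zmaps],
        ignore_index=True,
    )


@dataclass(frozen=True)
class GroupComparison:
    roi_name: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    t_statistic: float
    df: int
    p_value: float
    n_a: int
    n_b: int


def compare_roi_counts(
    table: pd.DataFrame,
    roi_name: str,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Unpaired two-tailed t-test (homoscedastic) on per-subject ROI counts."""
    sub = table[table["roi_name"] == roi_name]
    xa = sub.loc[sub["group_label"] == group_a, "n_suprathreshold"].to_numpy(dtype=float)
    xb = sub.loc[sub["group_label"] == group_b, "n_suprathreshold"].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(
            f"need >= 2 subjects per group for {roi_name!r}; got {len(xa)} and {len(xb)}"
        )
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0:
        # degenerate but well-defined: identical constants are "no
        # difference", different constants are a certain difference
        t, p = (0.0, 1.0) if np.mean(xa) == np.mean(xb) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return GroupComparison(
        roi_name=roi_name,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(np.mean(xa)),
        mean_b=float(np.mean(xb)),
        se_a=float(stats.sem(xa)),
        se_b=float(stats.sem(xb)),
        t_statistic=float(t),
        df=len(xa) + len(xb) - 2,
        p_value=float(p),
        n_a=len(xa),
        n_b=len(xb),
    )


def compare_all_rois(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-ROI two-group comparisons as a tidy frame.

    ``fdr=True`` appends Benjamini–Yekutieli adjusted p-values (off by
    default; the ROI-wise tests are reported unadjusted at alpha <= 0.05).
    """
    rows = []
    for roi in table["roi_name"].unique():
        c = compare_roi_counts(table, roi, group_a, group_b)
        rows.append(
            {
                "roi_name": c.roi_name,
                f"mean_{group_a}": c.mean_a,
                f"mean_{group_b}": c.mean_b,
                f"se_{group_a}": c.se_a,
                f"se_{group_b}": c.se_b,
                "t_statistic": c.t_statistic,
                "df": c.df,
                "p_value": c.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        from .actimetry import adjust_fdr_by

        out["p_adjusted_by"] = adjust_fdr_by(out["p_value"].to_numpy())
    return out
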