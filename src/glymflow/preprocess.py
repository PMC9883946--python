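"""Reference-region percent-signal-change normalization and 3D smoothing.

Raw T1-weighted intensities are converted to percent signal change relative to
a quiet reference region: a window of consecutive frames with the least change
in the reference-ROI mean trace defines the baseline mean m, and every voxel
value x becomes 100*(x - m)/m. Smoothing is purely spatial (never across time)
and uses mask-renormalized Gaussian weights so no signal bleeds across the
brain-mask boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageSeries4D, LabelVolume

__all__ = [
    "ReferenceWindow",
    "NormalizedSeries",
    "select_stable_window",
    "percent_signal_change",
    "gaussian_smooth",
    "normalize_series",
]


@dataclass
class ReferenceWindow:
    """A run of consecutive frames over which the reference ROI is stable."""

    start_frame: int
    length: int
    reference_mean: float
    variability_score: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")
        if self.reference_mean <= 0:
            raise ValueError("reference mean must be positive")


@dataclass
class NormalizedSeries:
    """Percent-signal-change series, same grid and time axis as its source."""

    data: np.ndarray  # (nx, ny, nz, n_frames), percent units
    frame_times_min: np.ndarray
    reference_window: ReferenceWindow | None = None
    smooth_radius_voxels: float | None = None
    subject_id: str = ""
    group_label: str = ""
    voxel_size_mm: tuple[float, float, float] = (0.188, 0.156, 0.188)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


def _roi_mean_trace(series: ImageSeries4D, roi_mask: np.ndarray) -> np.ndarray:
    if roi_mask.shape != series.grid_shape:
        raise ValueError("reference ROI grid does not match series grid")
    if not roi_mask.any():
        raise ValueError("reference ROI is empty")
    return series.data[roi_mask].mean(axis=0)


def select_stable_window(
    series: ImageSeries4D,
    ref_roi: LabelVolume | np.ndarray,
    label: int | None = None,
    length: int = 6,
) -> ReferenceWindow:
    """Pick the window of ``length`` consecutive frames with the flattest
    reference-ROI mean trace.

    Variability score is the standard deviation of the ROI-mean trace within
    the window; ties break toward the earliest window.
    """
    mask = ref_roi.mask(label) if isinstance(ref_roi, LabelVolume) else np.asarray(ref_roi, bool)
    trace = _roi_mean_trace(series, mask)
    n = trace.size
    if length > n:
        raise ValueError(f"window length {length} exceeds {n} frames")
    scores = np.array([trace[s : s + length].std() for s in range(n - length + 1)])
    start = int(np.argmin(scores))  # argmin returns the earliest minimum
    m = float(trace[start : start + length].mean())
    if m <= 0:
        raise ValueError("reference mean is non-positive (non-physical intensities)")
    return ReferenceWindow(
        start_frame=start, length=length, reference_mean=m, variability_score=float(scores[start])
    )


def percent_signal_change(
    series: ImageSeries4D,
    ref_roi: LabelVolume | np.ndarray,
    window: ReferenceWindow,
    label: int | None = None,
    per_voxel_baseline: bool = False,
) -> NormalizedSeries:
    """Convert every voxel to percent signal change, 100*(x - m)/m.

    By default m is a single scalar per subject: the mean over (reference ROI
    voxels x window frames). With ``per_voxel_baseline`` each voxel uses its
    own window-mean baseline instead.
    """
    mask = ref_roi.mask(label) if isinstance(ref_roi, LabelVolume) else np.asarray(ref_roi, bool)
    if window.start_frame + window.length > series.n_frames:
        raise ValueError("reference window does not fit the series")
    frames = slice(window.start_frame, window.start_frame + window.length)
    if per_voxel_baseline:
        m = series.data[..., frames].mean(axis=3, keepdims=True)
        if np.any(m <= 0):
            raise ValueError("per-voxel baseline contains non-positive values")
    else:
        m = series.data[mask][:, frames].mean()
        if m <= 0:
            raise ValueError("reference mean is non-positive (non-physical intensities)")
    data = 100.0 * (series.data - m) / m
    return NormalizedSeries(
        data=data,
        frame_times_min=series.frame_times_min.copy(),
        reference_window=window,
        subject_id=series.subject_id,
        group_label=series.group_label,
        voxel_size_mm=series.voxel_size_mm,
        affine=series.affine,
    )


def _masked_gaussian_3d(
    volume: np.ndarray, mask: np.ndarray | None, sigma: float, truncate: float
) -> np.ndarray:
    """Gaussian smoothing with weights renormalized over the mask support."""
    if mask is None:
        return ndimage.gaussian_filter(volume, sigma=sigma, truncate=truncate)
    m = mask.astype(float)
    num = ndimage.gaussian_filter(volume * m, sigma=sigma, truncate=truncate)
    den = ndimage.gaussian_filter(m, sigma=sigma, truncate=truncate)
    out = np.zeros_like(volume)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    out[~mask] = volume[~mask]
    return out


def gaussian_smooth(
    series: NormalizedSeries,
    radius_voxels: float = 2.0,
    mask: np.ndarray | None = None,
    sigma_voxels: float | None = None,
) -> NormalizedSeries:
    """Smooth each frame with a truncated isotropic 3D Gaussian.

    The kernel support half-width equals ``radius_voxels`` per axis; unless
    given explicitly, sigma = radius/2 so the stated support holds with the
    default radius of two voxels. Masked-out voxels are excluded from the
    convolution support (renormalized weights) and returned unchanged.
    """
    if radius_voxels <= 0:
        raise ValueError("radius must be positive")
    sigma = radius_voxels / 2.0 if sigma_voxels is None else sigma_voxels
    if sigma < np.finfo(float).eps:
        return series
    truncate = radius_voxels / sigma
    out = np.empty_like(series.data)
    for f in range(series.n_frames):
        out[..., f] = _masked_gaussian_3d(series.data[..., f], mask, sigma, truncate)
    return NormalizedSeries(
        data=out,
        frame_times_min=series.frame_times_min.copy(),
        reference_window=series.reference_window,
        smooth_radius_voxels=radius_voxels,
        subject_id=series.subject_id,
        group_label=series.group_label,
        voxel_size_mm=series.voxel_size_mm,
        affine=series.affine,
    )


def normalize_series(
    series: ImageSeries4D,
    ref_roi: LabelVolume | np.ndarray,
    label: int | None = None,
    window_length: int = 6,
    smooth_radius_voxels: float | None = 2.0,
    brain_mask: np.ndarray | None = None,
    per_voxel_baseline: bool = False,
) -> NormalizedSeries:
    """Full preprocessing: stable-window selection, percent change, smoothing.

    Order of operations: normalize, smooth within the brain mask, then the
    caller may restrict attention to the mask (values outside are untouched
    by smoothing).
    """
    window = select_stable_window(series, ref_roi, label=label, length=window_length)
    normalized = percent_signal_change(
        series, ref_roi, window, label=label, per_voxel_baseline=per_voxel_baseline
    )
    if smooth_radius_voxels is not None and smooth_radius_voxels > 0:
        normalized = gaussian_smooth(normalized, smooth_radius_voxels, mask=brain_mask)
    return normalized
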