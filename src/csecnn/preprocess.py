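"""Time-series cleaning for resting-state ROI signals.

Covers the steps that follow spatial preprocessing: frame censoring from
motion parameters, averaging voxel series within atlas regions, linear
detrending, ideal band-pass filtering to the low-frequency resting-state
band, and nuisance regression.  The canonical pipeline order is

    censor -> extract -> detrend -> bandpass -> regress

and the detrending and regression stages are idempotent projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

__all__ = [
    "ROITimeSeries",
    "motion_censor",
    "extract_roi_timeseries",
    "detrend",
    "bandpass",
    "regress_nuisance",
    "clean_pipeline",
]


@dataclass
class ROITimeSeries:
    """Per-subject matrix of mean ROI signals (rows = ROIs, columns = time)."""

    subject_id: str
    values: np.ndarray
    roi_labels: list[int] = field(default_factory=list)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if not self.roi_labels:
            self.roi_labels = list(range(1, self.values.shape[0] + 1))
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length must equal the number of rows")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "ROITimeSeries":
        return replace(self, values=values)


def motion_censor(
    motion: np.ndarray,
    translation_threshold_mm: float = 2.0,
    rotation_threshold_deg: float = 2.0,
    axial_only: bool = False,
) -> np.ndarray:
    """Boolean keep-mask over frames from a 6 x T motion-parameter trace.

    Rows 0-2 are translations in mm, rows 3-5 rotations in degrees.  A frame
    is dropped when any translation magnitude exceeds the translation
    threshold or any rotation magnitude exceeds the rotation threshold
    (default 2 mm / 2 degrees).  ``axial_only`` restricts the translation
    criterion to the third (z) axis.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError(f"motion trace must be 6 x T, got shape {motion.shape}")
    translations = motion[2:3] if axial_only else motion[0:3]
    bad = np.any(np.abs(translations) > translation_threshold_mm, axis=0)
    bad |= np.any(np.abs(motion[3:6]) > rotation_threshold_deg, axis=0)
    return ~bad


def extract_roi_timeseries(volume4d: np.ndarray, atlas) -> ROITimeSeries:
    """Average the voxel series of each atlas region.

    Row k of the output is the mean over all voxels carrying label k at each
    timepoint, rows ordered by ascending label 1..max(label).
    """
    volume4d = np.asarray(volume4d, dtype=float)
    labels_grid = np.asarray(getattr(atlas, "data", atlas))
    if volume4d.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got {volume4d.ndim}-D")
    if volume4d.shape[:3] != labels_grid.shape:
        raise ValueError(
            f"spatial extents {volume4d.shape[:3]} do not match atlas {labels_grid.shape}"
        )
    max_label = int(labels_grid.max())
    if max_label < 1:
        raise ValueError("atlas contains no nonzero labels")
    flat = volume4d.reshape(-1, volume4d.shape[3])
    flat_labels = labels_grid.reshape(-1)
    rows = []
    for label in range(1, max_label + 1):
        sel = flat_labels == label
        if not sel.any():
            raise ValueError(f"atlas label {label} has zero voxels")
        rows.append(flat[sel].mean(axis=0))
    return ROITimeSeries(
        subject_id="", values=np.stack(rows), roi_labels=list(range(1, max_label + 1))
    )


def detrend(ts: ROITimeSeries) -> ROITimeSeries:
    """Remove the least-squares linear trend (intercept + slope) per ROI."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    return ts.with_values(scipy.signal.detrend(ts.values, axis=1, type="linear"))


def bandpass(ts: ROITimeSeries, f_low: float = 0.01, f_high: float = 0.08) -> ROITimeSeries:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Retains Fourier components with ``f_low <= f <= f_high`` (inclusive
    edges) and zeroes everything else, including the DC term when f_low > 0.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 <= f_low < f_high):
        raise ValueError(f"need 0 <= f_low < f_high, got {f_low}, {f_high}")
    if f_high >= nyquist:
        raise ValueError(f"f_high={f_high} must be below the Nyquist frequency {nyquist}")
    n_t = ts.n_timepoints
    freqs = np.fft.rfftfreq(n_t, d=ts.tr_seconds)
    keep = (freqs >= f_low) & (freqs <= f_high)
    spectrum = np.fft.rfft(ts.values, axis=1)
    spectrum[:, ~keep] = 0
    return ts.with_values(np.fft.irfft(spectrum, n=n_t, axis=1))


def regress_nuisance(ts: ROITimeSeries, confounds: np.ndarray | None = None) -> ROITimeSeries:
    """Residualize each ROI series against confound regressors plus intercept.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution.  With no confounds this reduces to per-row mean removal.
    """
    n_t = ts.n_timepoints
    if confounds is None or np.size(confounds) == 0:
        design = np.ones((n_t, 1))
    else:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[1] != n_t:
            raise ValueError(
                f"confound rows have length {confounds.shape[1]}, expected {n_t}"
            )
        design = np.column_stack([confounds.T, np.ones(n_t)])
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    return ts.with_values(ts.values - (design @ beta).T)


def clean_pipeline(
    ts: ROITimeSeries,
    motion: np.ndarray | None = None,
    confounds: np.ndarray | None = None,
    f_low: float = 0.01,
    f_high: float = 0.08,
) -> ROITimeSeries:
    """Censor -> detrend -> bandpass -> regress, in the fixed order.

    Censored frames are dropped outright (no interpolation); the confound
    matrix, if given, is censored with the same mask so the design stays
    aligned with the data.
    """
    if motion is not None:
        keep = motion_censor(motion)
        ts = ts.with_values(ts.values[:, keep])
        if confounds is not None and np.size(confounds) > 0:
            confounds = np.atleast_2d(np.asarray(confounds, dtype=float))[:, keep]
    ts = detrend(ts)
    ts = bandpass(ts, f_low=f_low, f_high=f_high)
    return regress_nuisance(ts, confounds)
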