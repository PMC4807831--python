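"""Image-to-TAC protocol: 50% ROI, mask propagation, decay correction, FWHM.

The region of interest is defined once on the first dynamic frame as all
voxels strictly above a fraction (default 50%) of that frame's maximum,
then propagated unchanged to every later frame.  The ROI-summed signal,
converted to activity and optionally corrected for physical decay,
yields the time-activity curve (TAC) the washout fits consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import IsotopeSpec, frame_averaged_exp
from .synthetic import DynamicImageSeries, GAUSS_FWHM_PER_SIGMA

__all__ = ["ROIMask", "TimeActivityCurve", "select_roi", "extract_tac", "measure_fwhm"]


@dataclass
class ROIMask:
    """Boolean voxel mask aligned to a series grid."""

    mask: np.ndarray  # 3D bool
    threshold_fraction: float = 0.5
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.voxel_count < 1:
            raise ValueError("mask must contain at least one voxel")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class TimeActivityCurve:
    """ROI-summed activity per frame with timing and correction provenance.

    ``values`` are in Bq (activity mode) or Bq-equivalent after counts
    are divided by sensitivity and frame duration.  ``provenance``
    records the ROI size, the summary statistic, the physical decay
    constant present in / divided out of the data, and the correction
    method, which the fitters use to build a correction-consistent
    model.
    """

    times: np.ndarray  # frame mid-times, s
    values: np.ndarray
    frame_starts: np.ndarray | None = None
    frame_durations: np.ndarray | None = None
    decay_corrected: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")
        for name in ("frame_starts", "frame_durations"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} length must match times")
                setattr(self, name, v)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def select_roi(
    series: DynamicImageSeries,
    threshold_fraction: float = 0.5,
    reference_frame: int = 0,
) -> ROIMask:
    """Select voxels strictly above ``threshold_fraction`` of the reference-frame max.

    The deterministic counterpart of the manual ROI drawing used on real
    scans: every qualifying voxel of the reference frame (default: the
    first) is taken, and the maximum voxel always qualifies since the
    comparison is strict and the fraction is below 1.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if not (0 <= reference_frame < series.n_frames):
        raise IndexError(
            f"reference_frame {reference_frame} out of range for "
            f"{series.n_frames} frames"
        )
    ref = series.values[reference_frame]
    peak = float(ref.max())
    if peak <= 0:
        raise ValueError("reference frame is all zero: no source to delineate")
    mask = ref > threshold_fraction * peak
    return ROIMask(mask, threshold_fraction, reference_frame)


def extract_tac(
    series: DynamicImageSeries,
    roi: ROIMask,
    isotope: IsotopeSpec | None = None,
    decay_correct: bool = False,
) -> TimeActivityCurve:
    """Apply the ROI to every frame and return the time-activity curve.

    Counts-mode series are converted to frame-averaged activity by
    dividing by the scanner sensitivity (from series metadata) and the
    frame duration.  With ``decay_correct=True`` (and a series that still
    contains physical decay) each frame is additionally divided by the
    frame-averaged physical decay factor referenced to t = 0 =
    injection/acquisition start, which is exact for histogrammed counts.
    The ROI statistic is the voxel SUM; half-lives are invariant to the
    sum-vs-mean choice.
    """
    if roi.mask.shape != series.grid_shape:
        raise ValueError(
            f"ROI grid {roi.mask.shape} does not match series grid "
            f"{series.grid_shape}"
        )
    sums = series.values[:, roi.mask].sum(axis=1)

    if series.units == "counts":
        sensitivity = series.meta.get("sensitivity")
        if sensitivity is None:
            raise ValueError(
                "counts-mode series without 'sensitivity' in meta cannot be "
                "converted to activity"
            )
        values = sums / (sensitivity * series.frame_durations)
    else:
        values = sums.astype(float)

    provenance = {
        "roi_voxels": roi.voxel_count,
        "roi_threshold_fraction": roi.threshold_fraction,
        "statistic": "sum",
        "units": series.units,
        "correction": "none",
        "physical_lambda": None,
        "physical_decay_in_data": not series.decay_corrected,
    }
    corrected = series.decay_corrected

    if decay_correct and not series.decay_corrected:
        if isotope is None:
            raise ValueError("decay correction requires an isotope")
        factors = frame_averaged_exp(
            isotope.lambda_phys, series.frame_starts, series.frame_durations
        )
        values = values / factors
        corrected = True
        provenance.update(
            {
                "correction": "frame_average",
                "physical_lambda": isotope.lambda_phys,
                "physical_decay_in_data": False,
            }
        )
    elif not series.decay_corrected and isotope is not None:
        provenance["physical_lambda"] = isotope.lambda_phys

    return TimeActivityCurve(
        times=series.mid_times,
        values=values,
        frame_starts=series.frame_starts,
        frame_durations=series.frame_durations,
        decay_corrected=corrected,
        provenance=provenance,
    )


def _axis_fwhm(profile: np.ndarray, peak_idx: int, step: float) -> float:
    """FWHM of a 1D profile by linear interpolation at half maximum."""
    half = profile[peak_idx] / 2.0

    def crossing(direction: int) -> float:
        i = peak_idx
        while 0 <= i + direction < len(profile) and profile[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(profile):
            raise ValueError(
                "profile does not fall below half maximum inside the grid; "
                "peak too close to the boundary"
            )
        # linear interpolation between bracketing samples
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return (i + direction * frac) * step

    left = crossing(-1)
    right = crossing(+1)
    return right - left


def measure_fwhm(series: DynamicImageSeries, frame: int = 0) -> float:
    """FWHM (mm) of the point source in one frame, averaged over the 3 axes.

    Takes the 1D profile through the peak voxel along each axis,
    interpolates the half-maximum crossings linearly, and averages the
    three widths.  For a Gaussian blob this returns sigma *
    2*sqrt(2 ln 2) up to voxel-integration broadening.
    """
    if not (0 <= frame < series.n_frames):
        raise IndexError(f"frame {frame} out of range")
    vol = series.values[frame]
    if vol.max() <= 0:
        raise ValueError("frame has no positive peak")
    peak = np.unravel_index(int(np.argmax(vol)), vol.shape)
    for a in range(3):
        if peak[a] in (0, vol.shape[a] - 1):
            raise ValueError("peak lies on the grid boundary; FWHM undefined")

    widths = []
    for a in range(3):
        idx = list(peak)
        idx[a] = slice(None)
        profile = vol[tuple(idx)].astype(float)
        widths.append(_axis_fwhm(profile, peak[a], series.voxel_size[a]))
    return float(np.mean(widths))
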