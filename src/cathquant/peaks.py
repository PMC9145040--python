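"""Chromatographic peak detection, integration and signal-to-noise.

Each MRM channel yields one time/intensity trace per injection.  Peaks are
located as the intensity maximum inside a retention-time window, bounded at
the nearest local minima of a lightly smoothed trace (capped at apex
+/- 4 sigma-hat), baseline-corrected with a straight line between the
boundaries, and integrated by the trapezoid rule.  Background noise is the
standard deviation of the median-detrended trace outside the signal window;
S/N is baseline-corrected peak height over that noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class Chromatogram:
    """A single MRM channel trace for one injection.

    Times must be strictly increasing and (near-)uniformly spaced; at least
    20 points are required so a baseline region always exists.
    """

    sample_id: str
    analyte: str
    product_mz: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise PeakError("times and intensities must be 1-D and equally long")
        if t.size < 20:
            raise PeakError("chromatogram needs at least 20 points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise PeakError("time vector must be strictly increasing")
        if (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise PeakError("sampling must be uniform within 1%")

    @property
    def sampling_interval(self) -> float:
        return float(np.mean(np.diff(self.times)))


@dataclass(frozen=True)
class Peak:
    """An integrated peak; ``found`` is False for noise-only candidates."""

    apex_time: float
    height: float
    area: float
    baseline_noise_sd: float
    sn: float
    found: bool


def estimate_noise(chrom: Chromatogram, exclusion: tuple[float, float]) -> float:
    """Background-noise SD outside ``exclusion`` after median detrending.

    A 9-point rolling median removes slow baseline drift; the SD of the
    residuals over all points outside the excluded (signal) interval is the
    noise estimate.
    """
    lo, hi = exclusion
    mask = (chrom.times < lo) | (chrom.times > hi)
    if int(mask.sum()) < 20:
        raise PeakError("too few baseline points outside the exclusion interval")
    trend = median_filter(chrom.intensities, size=9, mode="nearest")
    resid = (chrom.intensities - trend)[mask]
    return float(np.std(resid))


def signal_to_noise(height: float, noise_sd: float) -> float:
    """Peak height over background-noise SD; +inf when the noise is zero."""
    if height < 0 or noise_sd < 0:
        raise PeakError("height and noise must be non-negative")
    if noise_sd == 0:
        return math.inf if height > 0 else 0.0
    return height / noise_sd


def _sigma_from_half_height(
    t: np.ndarray, y: np.ndarray, apex: int, floor: float, fallback: float
) -> float:
    """Estimate the Gaussian width from the full width at half maximum."""
    half = floor + (y[apex] - floor) / 2.0
    left = right = None
    for i in range(apex, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.5
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    for i in range(apex, t.size - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.5
            right = t[i] + frac * (t[i + 1] - t[i])
            break
    if left is None or right is None or right <= left:
        return fallback
    return (right - left) / 2.3548200450309493  # FWHM -> sigma


def detect_peak(chrom: Chromatogram, expected_rt: float, window: float) -> Peak:
    """Locate and integrate the peak inside ``expected_rt +/- window``.

    The apex is the maximum raw intensity in the window (earliest point on
    ties).  Integration boundaries are the nearest local minima of a 5-point
    moving average, capped at apex +/- 4 sigma-hat; a linear baseline drawn
    between the boundaries is subtracted before trapezoid integration.  The
    peak counts as found only when its baseline-corrected height exceeds
    three times the background noise.
    """
    if window <= 0:
        raise PeakError("window must be positive")
    t, y = chrom.times, chrom.intensities
    lo_t, hi_t = expected_rt - window, expected_rt + window
    if hi_t < t[0] or lo_t > t[-1]:
        raise PeakError("window outside chromatogram time span")
    noise_sd = estimate_noise(chrom, (lo_t, hi_t))

    in_win = np.nonzero((t >= lo_t) & (t <= hi_t))[0]
    if in_win.size == 0:
        raise PeakError("window contains no samples")
    apex = int(in_win[np.argmax(y[in_win])])  # argmax -> earliest tie wins

    smooth = uniform_filter1d(y, size=5, mode="nearest")
    out_mask = (t < lo_t) | (t > hi_t)
    floor = float(np.median(y[out_mask])) if out_mask.any() else float(np.min(y))
    sigma_hat = _sigma_from_half_height(t, y, apex, floor, fallback=window / 2.0)

    cap = 4.0 * sigma_hat
    left = apex
    while left > 0 and (t[apex] - t[left - 1]) <= cap:
        left -= 1
        if 0 < left < t.size - 1 and smooth[left] <= smooth[left - 1] and smooth[left] <= smooth[left + 1]:
            break
    right = apex
    while right < t.size - 1 and (t[right + 1] - t[apex]) <= cap:
        right += 1
        if 0 < right < t.size - 1 and smooth[right] <= smooth[right - 1] and smooth[right] <= smooth[right + 1]:
            break

    baseline = np.interp(
        t[left : right + 1], [t[left], t[right]], [smooth[left], smooth[right]]
    )
    corrected = y[left : right + 1] - baseline
    area = float(np.trapezoid(corrected, t[left : right + 1]))
    height = float(y[apex] - np.interp(t[apex], [t[left], t[right]], [smooth[left], smooth[right]]))

    found = height > 3.0 * noise_sd and height > 0 and area > 0
    sn = signal_to_noise(max(height, 0.0), noise_sd)
    return Peak(
        apex_time=float(t[apex]),
        height=height,
        area=area,
        baseline_noise_sd=noise_sd,
        sn=sn,
        found=found,
    )
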