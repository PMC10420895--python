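"""Threshold-value freshness rule from synchronous-spectrum peaks.

A sample is called fresh when the intensities of its per-sample
synchronous map at three fixed locations — the autocorrelation peaks at
(1450, 1450) and (1940, 1940) nm and the cross peak at (1450, 1940) nm —
all stay at or below thresholds learned from fresh calibration milk.
Fresh-milk peak values scatter tightly around zero (the study reports
standard deviations below 3e-5), so each threshold is set to the fresh
mean plus k standard deviations (k = 3 by default).

Also provided: ordinary least-squares regression of a peak intensity on
storage time, since the 1940 nm and (1450, 1940) peaks track storage time
roughly linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corr2d import peak_value, synchronous_single
from .dataio import SpectralDataset, Spectrum
from .exceptions import GridError, Lacto2dError

DEFAULT_PEAK_LOCATIONS: tuple[tuple[float, float], ...] = (
    (1450.0, 1450.0),
    (1940.0, 1940.0),
    (1450.0, 1940.0),
)

FRESH = "fresh"
NON_FRESH = "non_fresh"


@dataclass
class ThresholdModel:
    """Fitted peak thresholds plus the rule 'all at/below -> fresh'."""

    peak_locations: tuple[tuple[float, float], ...]
    thresholds: np.ndarray
    k_sd: float
    fresh_means: np.ndarray = field(default=None)
    fresh_sds: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "peak_locations": [list(p) for p in self.peak_locations],
            "thresholds": self.thresholds.tolist(),
            "k_sd": self.k_sd,
            "fresh_means": self.fresh_means.tolist(),
            "fresh_sds": self.fresh_sds.tolist(),
            "rule": "all_below_is_fresh",
        }


def sample_peak_values(
    s: Spectrum,
    ref: Spectrum,
    locations: tuple[tuple[float, float], ...] = DEFAULT_PEAK_LOCATIONS,
) -> np.ndarray:
    """Synchronous-map intensities of one sample at the given peak locations."""
    mat = synchronous_single(s, ref)
    return np.array([peak_value(mat, nu1, nu2) for nu1, nu2 in locations])


def fit_thresholds(
    fresh_cal: SpectralDataset,
    ref: Spectrum,
    k_sd: float = 3.0,
    locations: tuple[tuple[float, float], ...] = DEFAULT_PEAK_LOCATIONS,
) -> ThresholdModel:
    """Set each threshold to mean + k_sd * SD of the fresh calibration peaks."""
    if len(fresh_cal) < 2:
        raise Lacto2dError("threshold fitting needs >= 2 fresh calibration samples")
    peaks = np.vstack(
        [sample_peak_values(s, ref, locations) for s in fresh_cal]
    )
    means = peaks.mean(axis=0)
    sds = peaks.std(axis=0, ddof=1)
    return ThresholdModel(
        peak_locations=tuple(locations),
        thresholds=means + k_sd * sds,
        k_sd=k_sd,
        fresh_means=means,
        fresh_sds=sds,
    )


def classify_threshold(s: Spectrum, ref: Spectrum, model: ThresholdModel) -> str:
    """fresh iff every monitored peak is at or below its threshold."""
    if s.wavelengths.shape != ref.wavelengths.shape or not np.allclose(
        s.wavelengths, ref.wavelengths
    ):
        raise GridError("sample grid does not match the reference grid")
    peaks = sample_peak_values(s, ref, model.peak_locations)
    return FRESH if np.all(peaks <= model.thresholds) else NON_FRESH


def peak_time_regression(
    peaks: np.ndarray | list[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS fit of peak intensity on storage time.

    Parameters
    ----------
    peaks
        Sequence of (storage_time_hours, intensity) pairs.

    Returns
    -------
    (slope, intercept, r_squared) with R^2 = 1 - SS_res / SS_tot.
    """
    arr = np.asarray(peaks, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise Lacto2dError("regression needs >= 3 (time, intensity) pairs")
    t, y = arr[:, 0], arr[:, 1]
    if np.unique(t).size < 2:
        raise Lacto2dError("regression needs >= 2 distinct storage times")
    res = stats.linregress(t, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 0.0  # constant response: the fit explains nothing beyond the mean
    else:
        pred = res.slope * t + res.intercept
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return float(res.slope), float(res.intercept), r2
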