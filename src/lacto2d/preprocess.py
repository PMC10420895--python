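"""Spectral pretreatments: SNV, MSC and Savitzky-Golay first derivative.

These are the scatter/baseline corrections routinely compared in Vis/NIR
chemometrics.  SNV standardizes each spectrum to zero mean and unit sample
standard deviation across wavelengths; MSC regresses each spectrum on a
reference (by default the calibration-set mean, frozen so validation
samples never influence the fit) and removes the fitted slope and offset;
the first derivative is a Savitzky-Golay filter in absorbance per nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataio import SpectralDataset, Spectrum
from .exceptions import ConfigError, DegenerateInputError, GridError

METHODS = ("raw", "snv", "msc", "deriv1")


@dataclass
class PreprocessConfig:
    """Which pretreatment to apply and its parameters.

    deriv_window must be odd and at least deriv_polyorder + 2 (Savitzky-
    Golay needs one more point than the polynomial order to estimate a
    first derivative stably).
    """

    method: str = "raw"
    deriv_window: int = 11
    deriv_polyorder: int = 2
    msc_reference: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.method == "deriv1":
            _check_sg(self.deriv_window, self.deriv_polyorder)


def _check_sg(window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < polyorder + 2:
        raise ConfigError(
            f"derivative window must be odd and >= polyorder + 2 "
            f"(window={window}, polyorder={polyorder})"
        )


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: (x - mean(x)) / sd(x) across wavelengths."""
    x = s.absorbance
    if x.size < 2:
        raise DegenerateInputError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("SNV undefined for a constant spectrum")
    return s.replace_absorbance((x - x.mean()) / sd)


def msc(ds: SpectralDataset, reference: Spectrum) -> SpectralDataset:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r by least squares,
    x = a*r + b, and replaced by (x - b) / a.
    """
    r = reference.absorbance
    if reference.wavelengths.shape != ds.wavelengths.shape or not np.allclose(
        reference.wavelengths, ds.wavelengths
    ):
        raise GridError("MSC reference must share the dataset grid")
    if np.ptp(r) == 0:
        raise DegenerateInputError("MSC reference must not be constant")
    rc = r - r.mean()
    denom = rc @ rc
    corrected = np.empty_like(ds.values)
    for i, x in enumerate(ds.values):
        a = (rc @ (x - x.mean())) / denom
        if a == 0:
            raise DegenerateInputError(
                f"MSC fit degenerate (slope 0) for sample {ds.metadata['sample_id'][i]}"
            )
        b = x.mean() - a * r.mean()
        corrected[i] = (x - b) / a
    return SpectralDataset(
        wavelengths=ds.wavelengths.copy(),
        values=corrected,
        metadata=ds.metadata.copy(),
    )


def msc_coefficients(x: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept) of x regressed on reference r."""
    rc = r - r.mean()
    a = (rc @ (x - x.mean())) / (rc @ rc)
    b = x.mean() - a * r.mean()
    return float(a), float(b)


def first_derivative(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay first derivative in absorbance per nm, same-length output.

    Boundary points come from the filter's polynomial edge fits so the
    wavelength grid stays aligned with the other pretreatments.
    """
    _check_sg(window, polyorder)
    if window > s.n_points:
        raise ConfigError(
            f"derivative window {window} exceeds spectrum length {s.n_points}"
        )
    step = float(np.diff(s.wavelengths).mean())
    d = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=1,
        delta=step, mode="interp",
    )
    return s.replace_absorbance(d)


def apply_preprocessing(
    ds: SpectralDataset, cfg: PreprocessConfig
) -> SpectralDataset:
    """Apply the configured pretreatment to every spectrum of a dataset."""
    if cfg.method == "raw":
        return ds
    if cfg.method == "snv":
        values = np.vstack([snv(s).absorbance for s in ds])
    elif cfg.method == "deriv1":
        values = np.vstack(
            [first_derivative(s, cfg.deriv_window, cfg.deriv_polyorder).absorbance
             for s in ds]
        )
    else:  # msc
        ref = cfg.msc_reference if cfg.msc_reference is not None else ds.mean_spectrum()
        return msc(ds, ref)
    return SpectralDataset(
        wavelengths=ds.wavelengths.copy(), values=values, metadata=ds.metadata.copy()
    )
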