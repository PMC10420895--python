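"""Generalized two-dimensional correlation spectroscopy (Noda formalism).

The perturbation here is milk storage: each sample spectrum minus the mean
fresh-milk spectrum is a *dynamic spectrum*.  The synchronous correlation
map Phi(v1, v2) measures in-phase co-variation of absorbance at two
wavelengths; its diagonal is the autocorrelation spectrum (total intensity
fluctuation per wavelength, always nonnegative) and off-diagonal entries
are cross peaks.  Two estimators are provided:

* per-sample (``synchronous_single``): the outer product of one dynamic
  spectrum with itself — one feature map per sample, the default feature
  source for classification;
* ensemble (``synchronous_ensemble``): the classical 1/(m-1)-normalized
  average over a group of dynamic spectra, used for per-storage-day maps.

The asynchronous map (Hilbert-Noda transform) is included for
completeness; it is antisymmetric and not used by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import SpectralDataset, Spectrum
from .exceptions import GridError, Lacto2dError


@dataclass
class SyncCorrMatrix:
    """A wavelength x wavelength synchronous correlation matrix.

    values are in absorbance squared; the matrix is symmetric and its
    diagonal is nonnegative.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        p = self.wavelengths.size
        if self.values.shape != (p, p):
            raise GridError(
                f"matrix shape {self.values.shape} does not match grid size {p}"
            )


@dataclass
class AutocorrSpectrum:
    """Diagonal of a synchronous map: total fluctuation per wavelength."""

    wavelengths: np.ndarray
    values: np.ndarray


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b):
        raise GridError("wavelength grids do not match")


def reference_spectrum(fresh: SpectralDataset) -> Spectrum:
    """Pointwise mean of the fresh-milk spectra (the 2D-correlation reference)."""
    if len(fresh) == 0:
        raise Lacto2dError("reference requires at least one fresh spectrum")
    return Spectrum(
        wavelengths=fresh.wavelengths.copy(),
        absorbance=fresh.values.mean(axis=0),
        sample_id="reference",
    )


def dynamic_spectrum(s: Spectrum, ref: Spectrum) -> Spectrum:
    """Sample spectrum minus the reference spectrum, pointwise."""
    _check_same_grid(s.wavelengths, ref.wavelengths)
    return s.replace_absorbance(s.absorbance - ref.absorbance)


def synchronous_single(s: Spectrum, ref: Spectrum) -> SyncCorrMatrix:
    """Synchronous map of one sample: outer product of its dynamic spectrum.

    Phi(v1, v2) = y~(v1) * y~(v2) with y~ = s - ref.  Exactly symmetric,
    rank one, diagonal = y~**2 >= 0; zero when the sample equals the
    reference.
    """
    d = dynamic_spectrum(s, ref).absorbance
    return SyncCorrMatrix(wavelengths=s.wavelengths.copy(), values=np.outer(d, d))


def synchronous_ensemble(group: SpectralDataset, ref: Spectrum) -> SyncCorrMatrix:
    """Noda synchronous map of a group of m >= 2 spectra.

    Phi(v1, v2) = 1/(m-1) * sum_j y~_j(v1) y~_j(v2); symmetric positive
    semidefinite.
    """
    m = len(group)
    if m < 2:
        raise Lacto2dError(f"ensemble estimator needs m >= 2 spectra, got {m}")
    _check_same_grid(group.wavelengths, ref.wavelengths)
    d = group.values - ref.absorbance  # m x p dynamic spectra
    phi = d.T @ d / (m - 1)
    return SyncCorrMatrix(wavelengths=group.wavelengths.copy(), values=phi)


def hilbert_noda_matrix(m: int) -> np.ndarray:
    """The m x m Hilbert-Noda transform matrix: N_jk = 0 if j=k else 1/(pi(k-j))."""
    j = np.arange(m)
    diff = j[None, :] - j[:, None]
    with np.errstate(divide="ignore"):
        n = np.where(diff == 0, 0.0, 1.0 / (np.pi * diff))
    return n


def asynchronous_ensemble(group: SpectralDataset, ref: Spectrum) -> SyncCorrMatrix:
    """Noda asynchronous map Psi = 1/(m-1) * Y~^T N Y~ (antisymmetric, zero diagonal)."""
    m = len(group)
    if m < 3:
        raise Lacto2dError(f"asynchronous estimator needs m >= 3 spectra, got {m}")
    _check_same_grid(group.wavelengths, ref.wavelengths)
    d = group.values - ref.absorbance
    psi = d.T @ hilbert_noda_matrix(m) @ d / (m - 1)
    return SyncCorrMatrix(wavelengths=group.wavelengths.copy(), values=psi)


def autocorrelation(mat: SyncCorrMatrix) -> AutocorrSpectrum:
    """Extract the autocorrelation spectrum (matrix diagonal)."""
    return AutocorrSpectrum(
        wavelengths=mat.wavelengths.copy(), values=np.diag(mat.values).copy()
    )


def nearest_index(grid: np.ndarray, nu: float) -> int:
    """Index of the grid point nearest nu; ties resolve toward the lower wavelength."""
    if nu < grid[0] or nu > grid[-1]:
        raise Lacto2dError(
            f"wavelength {nu} nm outside grid range [{grid[0]}, {grid[-1]}]"
        )
    return int(np.argmin(np.abs(grid - nu)))


def peak_value(mat: SyncCorrMatrix, nu1: float, nu2: float) -> float:
    """Matrix intensity at the grid points nearest (nu1, nu2); symmetric in its args."""
    i = nearest_index(mat.wavelengths, nu1)
    j = nearest_index(mat.wavelengths, nu2)
    return float(mat.values[i, j])


def autocorrelation_features(ds: SpectralDataset, ref: Spectrum) -> np.ndarray:
    """Per-sample autocorrelation spectra as a feature matrix.

    Row i is the diagonal of the per-sample synchronous map of spectrum i,
    i.e. the squared dynamic spectrum — the 2D-correlation feature vector
    fed to the classifiers.
    """
    _check_same_grid(ds.wavelengths, ref.wavelengths)
    d = ds.values - ref.absorbance
    return d * d
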