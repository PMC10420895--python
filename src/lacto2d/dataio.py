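"""Spectral dataset containers and wide-CSV input/output.

A dataset is a samples x wavelengths absorbance matrix on one shared,
strictly increasing nanometre grid, with per-sample metadata (storage time
in hours, titratable acidity in Thorner degrees, freshness label A/B/C, and
an optional calibration/validation split tag).

File dialect: wide CSV, UTF-8, '.' decimal separator; metadata columns
first (``sample_id``, ``storage_time``, ``acidity``, ``label``, optionally
``split``), then one column per wavelength named by its nm value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    GridError,
    StratificationError,
    UniquenessError,
)

#: default acquisition grid: 400..2500 nm at 2 nm resolution (1051 points)
DEFAULT_GRID = np.arange(400.0, 2502.0, 2.0)

METADATA_COLUMNS = ("sample_id", "storage_time", "acidity", "label")
SPLIT_CALIBRATION = "calibration"
SPLIT_VALIDATION = "validation"


@dataclass
class Spectrum:
    """One absorbance spectrum with optional sample metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing nm grid.
    absorbance
        One unitless absorbance value per wavelength.
    sample_id
        Unique sample identifier.
    storage_time
        Storage time in hours (>= 0), or None when unknown.
    acidity
        Titratable acidity in Thorner degrees (> 0), or None.
    label
        Freshness class in {"A", "B", "C"}, or None.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    storage_time: float | None = None
    acidity: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.absorbance.ndim != 1:
            raise GridError("wavelengths and absorbance must be 1-D")
        if self.wavelengths.shape != self.absorbance.shape:
            raise GridError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.absorbance.size} absorbance values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise GridError("wavelength grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.wavelengths.size

    def replace_absorbance(self, values: np.ndarray) -> "Spectrum":
        """Return a copy with the same grid/metadata but new absorbance."""
        return Spectrum(
            wavelengths=self.wavelengths.copy(),
            absorbance=np.asarray(values, dtype=float),
            sample_id=self.sample_id,
            storage_time=self.storage_time,
            acidity=self.acidity,
            label=self.label,
        )


@dataclass
class SpectralDataset:
    """An ordered collection of spectra sharing one wavelength grid.

    Stored column-major-free as a dense ``values`` matrix (samples x
    wavelengths) plus a metadata DataFrame indexed like ``values`` rows.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if self.values.shape[1] != self.wavelengths.size:
            raise GridError(
                f"values have {self.values.shape[1]} columns but grid has "
                f"{self.wavelengths.size} points"
            )
        n = self.values.shape[0]
        if self.metadata.empty and n:
            self.metadata = pd.DataFrame(
                {"sample_id": [f"S{i:03d}" for i in range(n)]}
            )
        if len(self.metadata) != n:
            raise FormatError("metadata rows do not match number of spectra")
        self.metadata = self.metadata.reset_index(drop=True)
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                self.metadata[col] = None if col in ("sample_id", "label") else np.nan
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise UniquenessError(f"duplicate sample_id values: {dupes}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectralDataset":
        if not spectra:
            raise FormatError("cannot build a dataset from zero spectra")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.allclose(
                s.wavelengths, grid
            ):
                raise GridError("all spectra must share one wavelength grid")
        values = np.vstack([s.absorbance for s in spectra])
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "storage_time": [s.storage_time for s in spectra],
                "acidity": [s.acidity for s in spectra],
                "label": [s.label for s in spectra],
            }
        )
        return cls(wavelengths=grid.copy(), values=values, metadata=meta)

    # -- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return self.values.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.metadata.iloc[i]
        st = row.get("storage_time")
        ac = row.get("acidity")
        lab = row.get("label")
        return Spectrum(
            wavelengths=self.wavelengths,
            absorbance=self.values[i],
            sample_id=str(row["sample_id"]),
            storage_time=None if pd.isna(st) else float(st),
            acidity=None if pd.isna(ac) else float(ac),
            label=None if (lab is None or pd.isna(lab)) else str(lab),
        )

    # -- selection -----------------------------------------------------

    def subset(self, mask: np.ndarray | Iterable[bool]) -> "SpectralDataset":
        mask = np.asarray(list(mask) if not isinstance(mask, np.ndarray) else mask)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            values=self.values[mask],
            metadata=self.metadata.loc[mask].reset_index(drop=True),
        )

    def where_label(self, label: str) -> "SpectralDataset":
        return self.subset((self.metadata["label"] == label).to_numpy())

    @property
    def labels(self) -> np.ndarray:
        return self.metadata["label"].to_numpy(dtype=object)

    @property
    def calibration(self) -> "SpectralDataset":
        if "split" not in self.metadata.columns:
            raise FormatError("dataset carries no split tags; call split_dataset")
        return self.subset((self.metadata["split"] == SPLIT_CALIBRATION).to_numpy())

    @property
    def validation(self) -> "SpectralDataset":
        if "split" not in self.metadata.columns:
            raise FormatError("dataset carries no split tags; call split_dataset")
        return self.subset((self.metadata["split"] == SPLIT_VALIDATION).to_numpy())

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(
            wavelengths=self.wavelengths,
            absorbance=self.values.mean(axis=0),
            sample_id="mean",
        )


# ---------------------------------------------------------------------------
# wide-CSV round trip
# ---------------------------------------------------------------------------


def write_spectra(ds: SpectralDataset, path) -> None:
    """Write a dataset in the wide-CSV dialect (metadata first, then nm columns)."""
    meta_cols = [c for c in ("sample_id", "storage_time", "acidity", "label", "split")
                 if c in ds.metadata.columns]
    meta = ds.metadata[meta_cols].copy()
    wl_cols = [_format_wavelength(w) for w in ds.wavelengths]
    spec = pd.DataFrame(ds.values, columns=wl_cols)
    pd.concat([meta, spec], axis=1).to_csv(path, index=False)


def _format_wavelength(w: float) -> str:
    return f"{w:g}"


def read_spectra(path) -> SpectralDataset:
    """Read a wide-CSV spectral dataset.

    Raises
    ------
    FormatError
        Ragged rows or no wavelength columns.
    GridError
        Non-monotonic wavelength header.
    UniquenessError
        Duplicate sample ids.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    meta_cols, wl_cols = [], []
    for col in frame.columns:
        try:
            float(col)
        except ValueError:
            if wl_cols:
                raise FormatError(
                    f"metadata column {col!r} appears after wavelength columns"
                )
            meta_cols.append(col)
        else:
            wl_cols.append(col)
    if not wl_cols:
        raise FormatError("no numeric wavelength columns found in header")
    if "sample_id" not in meta_cols:
        raise FormatError("missing required 'sample_id' column")
    wavelengths = np.array([float(c) for c in wl_cols])
    if np.any(np.diff(wavelengths) <= 0):
        raise GridError("wavelength header is not strictly increasing")
    values = frame[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError("missing or non-numeric absorbance values")
    meta = frame[meta_cols].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    return SpectralDataset(wavelengths=wavelengths, values=values, metadata=meta)


# ---------------------------------------------------------------------------
# calibration / validation split
# ---------------------------------------------------------------------------


def split_dataset(
    ds: SpectralDataset,
    n_calibration: int,
    seed: int,
    stratify: bool = True,
) -> SpectralDataset:
    """Tag each sample ``calibration`` or ``validation``.

    Exactly ``n_calibration`` samples are tagged calibration (the study used
    97 of 130). Under stratification the per-class calibration proportions
    match the global proportion to within one sample (largest-remainder
    allocation). Deterministic for a fixed seed.
    """
    n = len(ds)
    if not 0 < n_calibration < n:
        raise ValueError(
            f"n_calibration must be in (0, {n}); got {n_calibration}"
        )
    rng = np.random.default_rng(seed)
    tags = np.full(n, SPLIT_VALIDATION, dtype=object)
    if stratify:
        labels = ds.metadata["label"].to_numpy(dtype=object)
        if any(lab is None or pd.isna(lab) for lab in labels):
            raise StratificationError("stratified split requires labels on all samples")
        classes, counts = np.unique(labels.astype(str), return_counts=True)
        if np.any(counts < 2):
            small = classes[counts < 2].tolist()
            raise StratificationError(
                f"classes with fewer than 2 members cannot be stratified: {small}"
            )
        frac = n_calibration / n
        quota = counts * frac
        base = np.floor(quota).astype(int)
        remainder = quota - base
        short = n_calibration - base.sum()
        # hand the leftover slots to the largest fractional remainders
        for idx in np.argsort(-remainder)[:short]:
            base[idx] += 1
        for cls, k in zip(classes, base):
            members = np.flatnonzero(labels.astype(str) == cls)
            chosen = rng.choice(members, size=k, replace=False)
            tags[chosen] = SPLIT_CALIBRATION
    else:
        chosen = rng.choice(n, size=n_calibration, replace=False)
        tags[chosen] = SPLIT_CALIBRATION
    out = SpectralDataset(
        wavelengths=ds.wavelengths,
        values=ds.values.copy(),
        metadata=ds.metadata.copy(),
    )
    out.metadata["split"] = tags
    return out
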