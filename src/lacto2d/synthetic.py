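"""Synthetic milk Vis/NIR spectra with storage-dependent structure.

The generator emulates the statistical structure the analysis pipeline
assumes about refrigerated raw milk scanned every 12 h over 6 days:

* absorbance spectra on the 400-2500 nm grid (2 nm steps) built from
  Gaussian absorption bands at the wavelengths assigned to water (1450,
  1940 nm), fat (1210, 1790, 2300 nm), protein (2050, 2180 nm),
  lactose/lactic acid (1194, 1560-1750, 2094 nm) and carotenoids (460 nm),
  on a smooth baseline;
* spoilage-linked bands (water overtones, lactose/lactic acid, fat) grow
  in amplitude with the acidity excess over the fresh baseline — the
  spoilage coordinate — so spectral change is slight during the fresh
  window and accelerates late, and the synchronous autocorrelation and
  cross peaks against a fresh reference grow monotonically with storage;
* multiplicative/additive scatter artifacts a*x + b per sample and white
  instrument noise;
* a titratable-acidity trajectory rising smoothly from 14.1 degT at day 0
  to 21.0 degT at day 6, slowly over the first four days and steeply over
  the last, from which the A/B/C freshness labels are drawn;
* 13 time points x 10 virtual milk types = 130 samples by default, tagged
  with a stratified 97/33 calibration/validation split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import DEFAULT_GRID, SpectralDataset, Spectrum, split_dataset
from .evaluation import label_from_acidity
from .exceptions import ConfigError

ACIDITY_START = 14.1  # degT at day 0
ACIDITY_END = 21.0  # degT at day 6


@dataclass
class BandSpec:
    """One Gaussian absorption band.

    amplitude at storage time t is base_amplitude * (1 + growth_rate * da(t))
    where da(t) is the acidity excess over the fresh baseline in degT (the
    spoilage coordinate, 0 at day 0 rising to 6.9 by day 6); growth_rate is
    the fractional amplitude increase per degT of acidity rise.
    """

    center: float  # nm
    width: float  # Gaussian sigma, nm
    base_amplitude: float  # absorbance
    growth_rate: float = 0.0  # per degT of acidity excess
    role: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0 (center {self.center})")
        if self.base_amplitude < 0:
            raise ConfigError(f"band amplitude must be >= 0 (center {self.center})")


def default_band_library() -> list[BandSpec]:
    """Band assignments with storage growth on the spoilage-linked bands."""
    return [
        BandSpec(460.0, 30.0, 0.15, 0.0, "carotenoids"),
        BandSpec(1194.0, 25.0, 0.25, 0.22, "lactose / lactic acid"),
        BandSpec(1210.0, 25.0, 0.30, 0.02, "fat"),
        BandSpec(1450.0, 40.0, 0.90, 0.30, "water, O-H first overtone"),
        BandSpec(1650.0, 50.0, 0.20, 0.04, "lactose / lactic acid (1560-1750)"),
        BandSpec(1790.0, 30.0, 0.25, 0.17, "fat / fatty acids"),
        BandSpec(1940.0, 45.0, 1.00, 0.35, "water, O-H combination"),
        BandSpec(2050.0, 30.0, 0.35, 0.02, "protein"),
        BandSpec(2094.0, 25.0, 0.30, 0.04, "lactose"),
        BandSpec(2180.0, 30.0, 0.35, 0.02, "protein"),
        BandSpec(2300.0, 35.0, 0.30, 0.02, "fat"),
        BandSpec(2498.0, 40.0, 0.40, 0.26, "water / long-wavelength edge"),
    ]


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions."""

    n_types: int = 10  # virtual milk types (replicates per time point)
    sampling_interval_hours: float = 12.0
    duration_days: float = 6.0
    band_library: list[BandSpec] = field(default_factory=default_band_library)
    baseline_offset: float = 0.10  # absorbance at 400 nm
    baseline_slope: float = 1.5e-4  # absorbance per nm
    scatter_slope_sd: float = 0.02  # sd of multiplicative a ~ N(1, sd^2)
    scatter_offset_sd: float = 0.01  # sd of additive b ~ N(0, sd^2)
    noise_sd: float = 0.002  # additive white noise, absorbance
    acidity_noise_sd: float = 0.12  # degT, per-sample
    # acidity trajectory a(t) = start + alpha*t + beta*(exp(gamma*t) - 1);
    # beta is solved so a(duration) = ACIDITY_END exactly
    acidity_form: str = "linear_plus_exponential"
    acidity_alpha: float = 0.68  # degT per day, slow early phase
    acidity_gamma: float = 1.0  # per day, late acceleration
    n_calibration: int = 97
    stratify_split: bool = True
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def __post_init__(self) -> None:
        if self.n_types <= 0 or self.duration_days <= 0:
            raise ConfigError("n_types and duration_days must be positive")
        if self.sampling_interval_hours <= 0:
            raise ConfigError("sampling_interval_hours must be positive")
        for sd in (self.scatter_slope_sd, self.scatter_offset_sd,
                   self.noise_sd, self.acidity_noise_sd):
            if sd < 0:
                raise ConfigError("noise/scatter standard deviations must be >= 0")

    @property
    def time_points_days(self) -> np.ndarray:
        step = self.sampling_interval_hours / 24.0
        n = int(round(self.duration_days / step)) + 1
        return np.arange(n) * step

    @property
    def n_samples(self) -> int:
        return self.n_types * self.time_points_days.size

    @property
    def acidity_beta(self) -> float:
        num = (ACIDITY_END - ACIDITY_START) - self.acidity_alpha * self.duration_days
        return num / (math.exp(self.acidity_gamma * self.duration_days) - 1.0)


def acidity_trajectory(t: float | np.ndarray, cfg: SynthConfig) -> float | np.ndarray:
    """Mean titratable acidity (degT) after t days of storage.

    Smooth and strictly increasing, anchored at 14.1 degT (t=0) and
    21.0 degT (t=6 d); the exponential term concentrates the rise in the
    final days so the mean slope over days 0-4 is strictly below the
    day 5-6 slope.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > cfg.duration_days):
        raise ValueError(
            f"storage time must lie in [0, {cfg.duration_days}] days"
        )
    a = (
        ACIDITY_START
        + cfg.acidity_alpha * t_arr
        + cfg.acidity_beta * (np.exp(cfg.acidity_gamma * t_arr) - 1.0)
    )
    return float(a) if np.isscalar(t) else a


def clean_spectrum(t: float, cfg: SynthConfig) -> np.ndarray:
    """Noise- and scatter-free band-sum absorbance at storage time t days.

    Band amplitudes grow with the acidity excess over the fresh baseline,
    so the spectrum barely changes during the fresh window and changes
    fastest over the final days, mirroring spoilage kinetics.
    """
    wl = cfg.wavelengths
    da = float(acidity_trajectory(t, cfg)) - ACIDITY_START
    x = cfg.baseline_offset + cfg.baseline_slope * (wl - wl[0])
    for band in cfg.band_library:
        amp = band.base_amplitude * (1.0 + band.growth_rate * da)
        x = x + amp * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
    return x


def spectrum_model(
    t: float, cfg: SynthConfig, rng: np.random.Generator
) -> Spectrum:
    """Draw one spectrum at storage time t days: bands + scatter + noise.

    The scatter artifact is applied as a*x + b with a ~ N(1, slope_sd^2)
    and b ~ N(0, offset_sd^2); white noise is added afterwards.
    """
    x = clean_spectrum(t, cfg)
    a = rng.normal(1.0, cfg.scatter_slope_sd)
    b = rng.normal(0.0, cfg.scatter_offset_sd)
    noise = rng.normal(0.0, cfg.noise_sd, size=x.size)
    return Spectrum(
        wavelengths=cfg.wavelengths.copy(),
        absorbance=a * x + b + noise,
        storage_time=t * 24.0,
    )


def generate_dataset(cfg: SynthConfig | None = None) -> SpectralDataset:
    """Generate the full synthetic study: spectra, metadata and split tags.

    n_types replicates at each 12-h time point over the storage duration
    (130 samples under the defaults); each sample carries its storage time
    (hours), a noisy acidity drawn around the trajectory, the freshness
    label implied by that acidity, and a stratified calibration/validation
    tag (97/33 by default).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    spectra: list[Spectrum] = []
    for k in range(cfg.n_types):
        for t in cfg.time_points_days:
            s = spectrum_model(float(t), cfg, rng)
            acidity = float(
                acidity_trajectory(float(t), cfg)
                + rng.normal(0.0, cfg.acidity_noise_sd)
            )
            acidity = max(acidity, 13.0)  # trajectory floor is 14.1; guard the scheme edge
            hours = int(round(t * 24.0))
            spectra.append(
                Spectrum(
                    wavelengths=s.wavelengths,
                    absorbance=s.absorbance,
                    sample_id=f"T{k:02d}_h{hours:03d}",
                    storage_time=float(hours),
                    acidity=round(acidity, 2),
                    label=label_from_acidity(acidity),
                )
            )
    ds = SpectralDataset.from_spectra(spectra)
    split_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % (2**31))
    return split_dataset(
        ds, cfg.n_calibration, seed=split_seed, stratify=cfg.stratify_split
    )


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """Copy of a config with a different seed (band library shared)."""
    return replace(cfg, seed=seed)
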