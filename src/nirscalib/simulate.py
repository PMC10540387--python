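"""Synthetic NIR spectra + reference traits with the statistical structure
the calibration pipeline assumes.

Reference traits are drawn from a truncated normal matching the field
population (RPR: mean 42.0, SD 7.62 N·mm⁻² on [22.8, 79.7]; breaking force:
mean 20.3, SD 6.08 N on [6.6, 32.8]); a separate measurement-noise layer
(SD 0.94 / 1.15) reproduces the laboratory replicate error, so the
pipeline's irreducible error floor is known exactly.

Spectra are generated directly in absorbance, where Beer–Lambert mixing is
linear: each spectrum is a sum of Gaussian bands whose informative-band
concentrations are affine in the (standardized) latent trait, plus
independent interferent bands, then distorted by a per-sample multiplicative
slope, additive offset and linear tilt — the minimal scatter structure that
makes SNV/MSC/SSL/derivative pretreatments non-trivially useful — plus
white spectral noise. A reflectance export (10^-A) exercises the
log10(1/R) conversion path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .labref import BREAKING_FORCE, N_RPR_POSITIONS, RPR, ReplicateRecord
from .spectra import ABSORBANCE, ReferenceTable, SpectraSet, to_reflectance

_STREAM_REFERENCE = 1
_STREAM_BANDS = 2
_STREAM_SPECTRA = 3
_STREAM_REPLICATES = 4


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic population.

    Trait statistics default to the RPR population (mean 42.0, SD 7.62,
    range 22.8–79.7 N·mm⁻², reference-error SD 0.94 N·mm⁻²); use
    :meth:`breaking_force` for the breaking-force preset (20.3 ± 6.08 N on
    [6.6, 32.8], reference-error SD 1.15 N).
    """

    n_samples: int = 200
    seed: int = 0
    trait: str = RPR
    trait_mean: float = 42.0
    trait_sd: float = 7.62
    trait_min: float = 22.8
    trait_max: float = 79.7
    # wavenumber grid (cm^-1)
    grid_start: float = 4000.0
    grid_stop: float = 12000.0
    n_points: int = 1038
    # band structure
    n_informative_bands: int = 5
    n_interferent_bands: int = 8
    band_width_range: tuple[float, float] = (150.0, 400.0)
    informative_amplitude: float = 0.35
    interferent_amplitude: float = 0.15
    concentration_noise_sd: float = 0.02
    baseline: float = 0.4
    # per-sample scatter distortion
    scatter_multiplicative_sd: float = 0.2
    scatter_offset_sd: float = 0.1
    scatter_tilt_sd: float = 0.05
    # noise layers
    spectral_noise_sd: float = 0.002
    reference_error_sd: float = 0.94
    # replicate structure (laboratory layer)
    n_replicates: int = 6
    replicate_sd: float = 2.2
    position_sd: float = 1.2
    # gross spectral outliers
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 0.5

    def __post_init__(self) -> None:
        if not self.trait_min < self.trait_mean < self.trait_max:
            raise ConfigError("trait bounds must satisfy min < mean < max")
        for name in (
            "trait_sd", "scatter_multiplicative_sd", "scatter_offset_sd", "scatter_tilt_sd",
            "spectral_noise_sd", "reference_error_sd", "replicate_sd", "position_sd",
            "concentration_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_samples < 1 or self.n_points < 8:
            raise ConfigError("n_samples >= 1 and n_points >= 8 required")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigError("outlier_fraction must be in [0, 1]")

    @classmethod
    def rpr(cls, **overrides) -> "GeneratorConfig":
        return cls(**overrides)

    @classmethod
    def breaking_force(cls, **overrides) -> "GeneratorConfig":
        defaults = dict(
            trait=BREAKING_FORCE, trait_mean=20.3, trait_sd=6.08,
            trait_min=6.6, trait_max=32.8, reference_error_sd=1.15,
            replicate_sd=2.8, position_sd=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_stop, self.n_points)

    @property
    def units(self) -> str:
        return "N·mm⁻²" if self.trait == RPR else "N"


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _sample_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def gen_reference(cfg: GeneratorConfig) -> tuple[ReferenceTable, np.ndarray]:
    """Draw latent traits from a truncated normal and add measurement noise.

    Returns (measured ReferenceTable, noiseless latent vector). The latent
    values are exactly within [trait_min, trait_max]; the measured values
    carry reference-error noise on top.
    """
    if cfg.trait_min >= cfg.trait_max:
        raise ConfigError("degenerate truncation: trait_min >= trait_max")
    rng = _rng(cfg, _STREAM_REFERENCE)
    a = (cfg.trait_min - cfg.trait_mean) / cfg.trait_sd
    b = (cfg.trait_max - cfg.trait_mean) / cfg.trait_sd
    latent = stats.truncnorm.rvs(
        a, b, loc=cfg.trait_mean, scale=cfg.trait_sd, size=cfg.n_samples, random_state=rng
    )
    measured = latent + rng.normal(0.0, cfg.reference_error_sd, size=cfg.n_samples)
    return ReferenceTable(_sample_ids(cfg.n_samples), cfg.trait, cfg.units, measured), latent


def _band_profiles(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded band centers/widths and trait sensitivities (informative bands)."""
    rng = _rng(cfg, _STREAM_BANDS)
    grid = cfg.grid
    span = cfg.grid_stop - cfg.grid_start
    k = cfg.n_informative_bands + cfg.n_interferent_bands
    centers = rng.uniform(cfg.grid_start + 0.05 * span, cfg.grid_stop - 0.05 * span, size=k)
    widths = rng.uniform(*cfg.band_width_range, size=k)
    if np.any(centers < grid[0]) or np.any(centers > grid[-1]):
        raise ConfigError("band center outside the wavenumber grid")
    profiles = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    slopes = rng.uniform(0.4, 1.0, size=cfg.n_informative_bands)
    slopes *= rng.choice([-1.0, 1.0], size=cfg.n_informative_bands)
    return profiles[: cfg.n_informative_bands], profiles[cfg.n_informative_bands :], slopes


def gen_spectra(latent: np.ndarray, cfg: GeneratorConfig) -> SpectraSet:
    """Absorbance spectra whose informative-band concentrations are affine in
    the latent trait, with per-sample scatter distortion and white noise."""
    latent = np.asarray(latent, dtype=float).ravel()
    n = latent.size
    rng = _rng(cfg, _STREAM_SPECTRA)
    inf_profiles, int_profiles, slopes = _band_profiles(cfg)
    z = (latent - cfg.trait_mean) / cfg.trait_sd

    conc_inf = 1.0 + 0.5 * np.outer(z, slopes)  # (n, k_inf)
    conc_inf += rng.normal(0.0, cfg.concentration_noise_sd, size=conc_inf.shape)
    spectra = cfg.baseline + cfg.informative_amplitude * conc_inf @ inf_profiles
    if cfg.n_interferent_bands:
        conc_int = rng.normal(1.0, 0.3, size=(n, cfg.n_interferent_bands))
        spectra += cfg.interferent_amplitude * conc_int @ int_profiles

    nu = _normalized_grid(cfg.grid)
    mult = 1.0 + rng.normal(0.0, cfg.scatter_multiplicative_sd, size=n)
    mult = np.clip(mult, 0.2, None)  # keep the scatter slope physical (positive)
    offset = rng.normal(0.0, cfg.scatter_offset_sd, size=n)
    tilt = rng.normal(0.0, cfg.scatter_tilt_sd, size=n)
    spectra = mult[:, None] * spectra + offset[:, None] + np.outer(tilt, nu)
    spectra += rng.normal(0.0, cfg.spectral_noise_sd, size=spectra.shape)
    return SpectraSet(_sample_ids(n), cfg.grid, spectra, ABSORBANCE)


def _normalized_grid(grid: np.ndarray) -> np.ndarray:
    """Wavenumbers rescaled to [-1, 1] (keeps tilt magnitudes interpretable)."""
    mid = 0.5 * (grid[0] + grid[-1])
    half = 0.5 * (grid[-1] - grid[0])
    return (grid - mid) / half


def gen_replicates(latent: np.ndarray, cfg: GeneratorConfig) -> list[ReplicateRecord]:
    """Laboratory replicate layer: per genotype, 6 replicates (5 position
    peaks each for RPR, a single peak for breaking force), with
    between-replicate and within-replicate (position) error calibrated so
    genotype standard errors fall in the observed 0.57–1.19 N·mm⁻² band."""
    latent = np.asarray(latent, dtype=float).ravel()
    rng = _rng(cfg, _STREAM_REPLICATES)
    ids = _sample_ids(latent.size)
    n_peaks = N_RPR_POSITIONS if cfg.trait == RPR else 1
    records = []
    for g, truth in zip(ids, latent):
        for j in range(cfg.n_replicates):
            center = truth + rng.normal(0.0, cfg.replicate_sd)
            peaks = center + rng.normal(0.0, cfg.position_sd, size=n_peaks)
            records.append(
                ReplicateRecord(
                    genotype=g, trait=cfg.trait, internode=12, replicate=j + 1,
                    peaks=tuple(peaks),
                )
            )
    return records


def inject_outliers(
    s: SpectraSet, fraction: float, magnitude: float, seed: int
) -> tuple[SpectraSet, np.ndarray]:
    """Corrupt a seeded subset of spectra with gross baseline/slope/bump
    artifacts of the given absorbance magnitude; returns the corrupted set
    and the ground-truth outlier flags."""
    if not 0.0 <= fraction <= 1.0:
        raise DataError("outlier fraction must be in [0, 1]")
    n = s.n_samples
    n_out = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    values = s.values.copy()
    if n_out:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=n_out, replace=False)
        flags[idx] = True
        nu = _normalized_grid(s.grid)
        span = s.grid[-1] - s.grid[0]
        for i in idx:
            sign = rng.choice([-1.0, 1.0], size=3)
            amp = magnitude * rng.uniform(0.7, 1.3, size=3)
            center = rng.uniform(s.grid[0], s.grid[-1])
            bump = np.exp(-0.5 * ((s.grid - center) / (0.05 * span)) ** 2)
            values[i] += sign[0] * amp[0] + sign[1] * amp[1] * nu + sign[2] * amp[2] * bump
    return replace(s, values=values), flags


def simulate_dataset(cfg: GeneratorConfig) -> dict:
    """Generate the full linked dataset for one configuration.

    Returns a dict with keys: ``spectra`` (absorbance), ``reflectance``,
    ``reference`` (measured values), ``latent`` (noiseless truth),
    ``replicates``, ``outlier_flags``.
    """
    reference, latent = gen_reference(cfg)
    spectra = gen_spectra(latent, cfg)
    spectra, flags = inject_outliers(
        spectra, cfg.outlier_fraction, cfg.outlier_magnitude, seed=cfg.seed + 7919
    )
    return {
        "spectra": spectra,
        "reflectance": to_reflectance(spectra),
        "reference": reference,
        "latent": latent,
        "replicates": gen_replicates(latent, cfg),
        "outlier_flags": flags,
    }
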