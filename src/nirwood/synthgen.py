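"""Synthetic Vis-NIR wood spectra with known ground truth.

The published wood spectra behind this kind of study are rarely deposited,
so every downstream stage (denoising, wavelength selection, calibration) is
exercised here on simulated data with the statistical structure the analysis
assumes:

* Beer-Lambert mixing: clean absorbance is a nonnegative combination of
  Gaussian absorption bands, A(lambda) = sum_b gauss(lambda; center_b,
  width_b) * (loadings_b . c), with unit path length.  The default band
  library places bands at 1157, 1171, 1370, 1597, 1811, 1830, 2200 and
  2353 nm — positions associated with hemicellulose, cellulose and lignin
  absorption in wood.
* Per-sample multiplicative/additive scatter and a random low-order
  polynomial baseline (the physics MSC/SNV are designed to remove).
* Additive white noise per replicate scan; three replicate scans per sample
  share the same clean spectrum.
* Wood density is an affine function of the component concentrations plus an
  optional quadratic term in total concentration; defaults are calibrated so
  simulated densities stay within 0.50-1.20 g/cm3, bracketing the
  0.576-1.124 g/cm3 range typical of temperate hardwood/larch specimens.

The generator returns reflectance R = 10**(-A_observed) clipped into
(1e-6, 1] so that log10(1/R) is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import SpectraDataset, make_wavelength_grid

__all__ = [
    "BandSpec",
    "SynthConfig",
    "GroundTruth",
    "default_band_library",
    "simulate_concentrations",
    "density_from_concentrations",
    "simulate_spectra",
    "generate_dataset",
]

#: the eight canonical wood-chemistry band positions (nm)
BAND_CENTERS = (1157.0, 1171.0, 1370.0, 1597.0, 1811.0, 1830.0, 2200.0, 2353.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    center, width in nm (width = Gaussian standard deviation); ``loadings``
    gives the unitless absorptivity of each chemical component at this band.
    """

    center: float
    width: float
    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not any(l > 0 for l in self.loadings):
            raise ValueError("at least one loading must be positive")
        if any(l < 0 for l in self.loadings):
            raise ValueError("loadings must be nonnegative")


def default_band_library() -> tuple[BandSpec, ...]:
    """Eight bands at the canonical positions, one dominant component each
    (component 0 = hemicellulose, 1 = cellulose, 2 = lignin)."""
    assignment = {  # center -> (component, absorptivity, width nm)
        1157.0: (0, 0.9, 25.0),
        1171.0: (1, 1.1, 20.0),
        1370.0: (1, 1.3, 35.0),
        1597.0: (2, 1.0, 45.0),
        1811.0: (0, 1.2, 30.0),
        1830.0: (1, 0.8, 25.0),
        2200.0: (2, 1.4, 60.0),
        2353.0: (1, 1.0, 40.0),
    }
    bands = []
    for center in BAND_CENTERS:
        comp, eps, width = assignment[center]
        loadings = [0.0, 0.0, 0.0]
        loadings[comp] = eps
        bands.append(BandSpec(center=center, width=width, loadings=tuple(loadings)))
    return tuple(bands)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator."""

    n_samples: int = 120
    wavelength_start: float = 350.0
    wavelength_stop: float = 2397.0
    wavelength_step: float = 1.0
    n_components: int = 3
    concentration_mean: tuple[float, ...] = (0.35, 0.30, 0.25)
    concentration_sd: tuple[float, ...] = (0.06, 0.05, 0.05)
    density_intercept: float = 0.30
    density_slopes: tuple[float, ...] = (0.55, 0.50, 0.60)
    nonlinearity_strength: float = 0.12
    scatter_slope_range: tuple[float, float] = (0.95, 1.05)
    scatter_offset_range: tuple[float, float] = (-0.02, 0.02)
    baseline_amplitude: float = 0.01
    noise_sd: float = 0.005
    replicates_per_sample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_stop <= self.wavelength_start:
            raise ValueError("wavelength_stop must exceed wavelength_start")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("concentration_mean", "concentration_sd", "density_slopes"):
            if len(getattr(self, name)) != self.n_components:
                raise ValueError(f"{name} must have length n_components")
        if any(m <= 0 for m in self.concentration_mean):
            raise ValueError("concentration means must be positive")
        if any(s < 0 for s in self.concentration_sd):
            raise ValueError("concentration spreads must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return make_wavelength_grid(
            self.wavelength_start, self.wavelength_stop, self.wavelength_step
        )


@dataclass
class GroundTruth:
    """Oracle state retained for recovery tests."""

    concentrations: np.ndarray  # samples x components
    clean_spectra: np.ndarray  # samples x wavelengths, noise/scatter-free absorbance
    informative_band_indices: np.ndarray  # grid indices within +-2 width of a band

    def __post_init__(self) -> None:
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(self.clean_spectra < 0):
            raise ValueError("clean spectra must be nonnegative")
        if self.informative_band_indices.size == 0:
            raise ValueError("informative_band_indices must be non-empty")


def simulate_concentrations(config: SynthConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw component concentrations from zero-truncated normals.

    Reproducible from ``config.seed``; with spread 0 every sample sits at the
    component means.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = np.empty((config.n_samples, config.n_components))
    for j in range(config.n_components):
        mu = config.concentration_mean[j]
        sd = config.concentration_sd[j]
        if sd == 0.0:
            out[:, j] = mu
        else:
            a = (0.0 - mu) / sd  # truncate at zero
            out[:, j] = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sd, size=config.n_samples, random_state=rng
            )
    return out


def density_from_concentrations(concentrations: np.ndarray, config: SynthConfig) -> np.ndarray:
    """density = intercept + slopes . c + nonlinearity * (sum c)**2  [g/cm3]"""
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    linear = config.density_intercept + c @ np.asarray(config.density_slopes)
    total = c.sum(axis=1)
    return linear + config.nonlinearity_strength * total**2


def band_design_matrix(bands: tuple[BandSpec, ...], wavelengths: np.ndarray) -> np.ndarray:
    """Band profiles evaluated on the grid (bands x p).

    Profiles are Gaussians truncated at +-2 standard deviations and shifted
    to zero at the cut, g(u) = (exp(-u^2/2) - exp(-2)) / (1 - exp(-2)) for
    |u| <= 2, so each band has compact support exactly on its +-2 width
    window: outside every window the clean signal is identically zero, which
    gives the selection-recovery tests a sharp oracle.
    """
    wl = np.asarray(wavelengths)
    u = (wl[None, :] - np.array([b.center for b in bands])[:, None]) / np.array(
        [b.width for b in bands]
    )[:, None]
    edge = np.exp(-2.0)
    profile = (np.exp(-0.5 * u**2) - edge) / (1.0 - edge)
    return np.where(np.abs(u) <= 2.0, np.maximum(profile, 0.0), 0.0)


def informative_indices(bands: tuple[BandSpec, ...], wavelengths: np.ndarray) -> np.ndarray:
    """Grid indices within +-2 width of any band center."""
    wl = np.asarray(wavelengths)
    mask = np.zeros(wl.size, dtype=bool)
    for b in bands:
        mask |= np.abs(wl - b.center) <= 2.0 * b.width
    return np.flatnonzero(mask)


def simulate_spectra(
    concentrations: np.ndarray,
    bands: tuple[BandSpec, ...],
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate replicate-level reflectance spectra.

    Returns the (n_samples * replicates) x p reflectance matrix and the
    ground truth (clean absorbance is sample-level).  Scatter and baseline
    are drawn per sample; replicates share everything except the additive
    noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    wl = config.wavelengths
    profiles = band_design_matrix(bands, wl)  # bands x p
    loadings = np.array([b.loadings for b in bands])  # bands x components
    clean = (c @ loadings.T) @ profiles  # samples x p
    n, p = clean.shape
    reps = config.replicates_per_sample

    slopes = rng.uniform(*config.scatter_slope_range, size=n)
    offsets = rng.uniform(*config.scatter_offset_range, size=n)
    # degree-2 polynomial baseline, coefficients scaled by baseline_amplitude
    t = np.linspace(-1.0, 1.0, p)
    basis = np.vstack([np.ones(p), t, t**2])  # 3 x p
    base_coef = rng.uniform(-1.0, 1.0, size=(n, 3)) * config.baseline_amplitude
    baseline = base_coef @ basis  # n x p

    observed = slopes[:, None] * clean + offsets[:, None] + baseline
    observed = np.repeat(observed, reps, axis=0)
    if config.noise_sd > 0:
        observed = observed + rng.normal(0.0, config.noise_sd, size=observed.shape)
    reflectance = np.clip(10.0 ** (-observed), 1e-6, 1.0)
    truth = GroundTruth(
        concentrations=c,
        clean_spectra=clean,
        informative_band_indices=informative_indices(bands, wl),
    )
    return reflectance, truth


def generate_dataset(
    config: SynthConfig, bands: tuple[BandSpec, ...] | None = None
) -> tuple[SpectraDataset, GroundTruth]:
    """Full generator: concentrations -> density -> replicate spectra."""
    if bands is None:
        bands = default_band_library()
    rng = np.random.default_rng(config.seed)
    conc = simulate_concentrations(config, rng)
    density = density_from_concentrations(conc, config)
    reflectance, truth = simulate_spectra(conc, bands, config, rng)
    reps = config.replicates_per_sample
    width = len(str(config.n_samples))
    sample_id = np.repeat(
        [f"S{i + 1:0{width}d}" for i in range(config.n_samples)], reps
    ).astype(object)
    dataset = SpectraDataset(
        wavelengths=config.wavelengths,
        spectra=reflectance,
        density=np.repeat(density, reps),
        sample_id=sample_id,
        species=np.array(["synthetic"] * reflectance.shape[0], dtype=object),
        location=np.array(["synthetic"] * reflectance.shape[0], dtype=object),
        replicate=np.tile(np.arange(1, reps + 1), config.n_samples),
        mode="reflectance",
    )
    return dataset, truth
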