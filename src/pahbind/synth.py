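"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters and an explicit seed:
the same call always produces bitwise-identical output, and generated
objects satisfy the invariants of the types they feed.  Defaults emulate
the experiments the analyses were designed for — fluorimeter-like 2%
multiplicative intensity noise on titrations and spectra, and AR(1)
autocorrelated dG/dlambda samples mimicking correlated MD output.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import lfilter

from .cycle import LambdaWindow, TIProfile
from .exceptions import DomainError, ValidationError
from .polarity import BAND1_WINDOW, BAND3_WINDOW, EmissionSpectrum, UptakeTimeCourse
from .titration import TitrationSeries, fraction_bound, solve_free_sites

__all__ = [
    "NoiseModel",
    "GeneratorConfig",
    "gen_titration",
    "gen_uptake_timecourse",
    "gen_ti_profile",
    "gen_pyrene_spectrum",
]


class NoiseModel(str, Enum):
    additive_gaussian = "additive_gaussian"
    multiplicative_gaussian = "multiplicative_gaussian"


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise and replication settings shared by all generators."""

    seed: int = 0
    noise_model: NoiseModel = NoiseModel.multiplicative_gaussian
    noise_level: float = 0.02
    replicate_count: int = 1

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValidationError("noise_level must be non-negative")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(signal: np.ndarray, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_level == 0:
        return signal.copy()
    eps = rng.standard_normal(signal.shape)
    if cfg.noise_model is NoiseModel.multiplicative_gaussian:
        return signal * (1.0 + cfg.noise_level * eps)
    scale = cfg.noise_level * float(np.max(np.abs(signal)))
    return signal + scale * eps


def gen_titration(kd_true: float, f0: float, f_inf: float,
                  protein_concs, ligand_total: float,
                  sites: int = 2, cfg: GeneratorConfig = GeneratorConfig()) -> TitrationSeries:
    """Forward-simulate a fluorescence titration from the binding isotherm.

    Intensities follow F = F0 + (Finf - F0) * y, with the fraction bound
    evaluated at the self-consistent free-site concentration for the true
    Kd, plus configured noise.  The zero-protein point is kept noise-free:
    it defines F0 during fitting, as in the assay.
    """
    if kd_true <= 0:
        raise DomainError("kd_true must be positive")
    p = np.asarray(protein_concs, dtype=float)
    if not np.any(p == 0.0):
        raise DomainError("protein concentrations must include a zero point")
    s_free = solve_free_sites(p, ligand_total, kd_true, sites)
    y = fraction_bound(s_free, kd_true)
    signal = f0 + (f_inf - f0) * y
    noisy = _apply_noise(signal, cfg, cfg.rng())
    noisy[p == 0.0] = f0
    return TitrationSeries(
        ligand_name="synthetic", ligand_total=ligand_total,
        protein_total=p, intensity=noisy,
        emission_wavelength=350.0, excitation_wavelength=275.0,
    )


def gen_uptake_timecourse(k_true: float, f0: float, f_inf: float, times,
                          ligand_total: float = 2e-6, protein_total: float = 70e-6,
                          cfg: GeneratorConfig = GeneratorConfig()) -> UptakeTimeCourse:
    """Single-exponential uptake trace F(t) = Finf - (Finf - F0) exp(-k t) + noise."""
    if k_true <= 0:
        raise DomainError("k_true must be positive")
    t = np.asarray(times, dtype=float)
    signal = f_inf - (f_inf - f0) * np.exp(-k_true * t)
    noisy = _apply_noise(signal, cfg, cfg.rng())
    return UptakeTimeCourse(time=t, intensity=noisy,
                            ligand_total=ligand_total, protein_total=protein_total)


def _ar1_series(rng: np.random.Generator, n: int, marginal_sd: float,
                phi: float) -> np.ndarray:
    """Stationary AR(1) noise with the requested marginal standard deviation."""
    if marginal_sd == 0:
        return np.zeros(n)
    if phi == 0:
        return rng.normal(0.0, marginal_sd, size=n)
    innov_sd = marginal_sd * np.sqrt(1.0 - phi * phi)
    x0 = rng.normal(0.0, marginal_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    tail, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return np.concatenate(([x0], tail))


def gen_ti_profile(shape, lambda_grid, samples_per_window: int = 4000,
                   sigma_target: float = 0.0, autocorr: float = 0.0,
                   cfg: GeneratorConfig = GeneratorConfig(),
                   n_blocks: int = 10,
                   sigma_is_marginal: bool = False) -> TIProfile:
    """Synthetic dG/dlambda profile with AR(1) per-window sampling noise.

    ``shape`` gives polynomial coefficients (constant first) for the mean
    profile over lambda.  ``sigma_target`` sets the intended standard error
    of each window mean; the marginal sample variance is scaled up by the
    AR(1) inflation factor (1 + phi)/(1 - phi) so correlated and
    uncorrelated draws yield comparable mean precision.  With
    ``sigma_is_marginal`` the target is instead the marginal sample
    standard deviation, so increasing the autocorrelation degrades the
    precision of the window means.  Windows are built through block
    averaging, so the profile arrives with honest sigmas.
    """
    if not 0.0 <= autocorr < 1.0:
        raise DomainError("autocorr must lie in [0, 1)")
    lam = np.asarray(lambda_grid, dtype=float)
    coeffs = np.asarray(shape, dtype=float)
    means = np.polynomial.polynomial.polyval(lam, coeffs)
    rng = cfg.rng()
    n = samples_per_window
    # sd of the mean of n AR(1) samples ~ marginal_sd/sqrt(n) * sqrt((1+phi)/(1-phi))
    inflation = np.sqrt((1.0 + autocorr) / (1.0 - autocorr))
    if sigma_is_marginal:
        marginal_sd = sigma_target
    else:
        marginal_sd = sigma_target * np.sqrt(n) / inflation
    windows = []
    for lam_i, mu in zip(lam, means):
        samples = mu + _ar1_series(rng, n, marginal_sd, autocorr)
        windows.append(LambdaWindow.from_samples(float(lam_i), samples, n_blocks=n_blocks))
    return TIProfile(windows=windows)


def gen_pyrene_spectrum(py_true: float, peak1: float = 373.0, peak3: float = 384.0,
                        width: float = 2.0, amplitude3: float = 1e6,
                        cfg: GeneratorConfig = GeneratorConfig(noise_level=0.0)) -> EmissionSpectrum:
    """Two-Gaussian pyrene-like emission spectrum with band ratio ``py_true``.

    Bands I and III are Gaussians at ``peak1`` and ``peak3`` on a 1 nm
    grid (360-400 nm), with amplitude ratio py_true; narrow widths keep
    band overlap negligible so the extracted ratio matches the target.
    """
    if py_true <= 0:
        raise DomainError("py_true must be positive")
    if not (BAND1_WINDOW[0] <= peak1 <= BAND1_WINDOW[1]):
        raise DomainError("peak1 must lie inside the band-I extraction window")
    if not (BAND3_WINDOW[0] <= peak3 <= BAND3_WINDOW[1]):
        raise DomainError("peak3 must lie inside the band-III extraction window")
    wl = np.arange(360.0, 401.0, 1.0)
    # amplitudes corrected for band overlap so the PEAK ratio (what the
    # extractor measures) equals py_true even for the widest bands
    g = float(np.exp(-0.5 * ((peak3 - peak1) / width) ** 2))
    if py_true * g >= 1.0:
        raise DomainError("bands overlap too strongly for the requested ratio")
    a3 = amplitude3
    a1 = a3 * (py_true - g) / (1.0 - py_true * g)
    if a1 <= 0:
        raise DomainError("bands overlap too strongly for the requested ratio")
    band1 = a1 * np.exp(-0.5 * ((wl - peak1) / width) ** 2)
    band3 = a3 * np.exp(-0.5 * ((wl - peak3) / width) ** 2)
    signal = band1 + band3
    noisy = np.clip(_apply_noise(signal, cfg, cfg.rng()), 0.0, None)
    return EmissionSpectrum(wavelength=wl, intensity=noisy, excitation_wavelength=334.0)
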