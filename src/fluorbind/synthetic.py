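"""Synthetic spectra and titrations with known ground truth.

Every analysis stage in the package can be exercised without instrument
data by generating inputs from the same models the analyses invert:

* titrations follow the static-quenching (ground-state 1:n complex)
  isotherm ``F = F0 / (1 + K_b * [Q]^n)``, the inversion of the double-log
  binding relation, with optional multiplicative Gaussian noise emulating
  shot-noise at high photon counts;
* emission and absorbance spectra are sums of Gaussian bands;
* excitation-emission matrices are sums of separable 2-D Gaussian peaks,
  with a bound-state counterpart obtained by per-peak intensity quenching
  and emission-center shifts.

All randomness flows through a seeded ``numpy.random.Generator``, so a
fixed seed reproduces every dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .spectra import (
    AbsorbanceSpectrum,
    EEMatrix,
    EmissionSpectrum,
    QuenchTitration,
)

__all__ = [
    "GroundTruth",
    "PAPER_LIKE_TRUTH",
    "default_concentrations",
    "generate_titration",
    "generate_emission_spectrum",
    "generate_eem",
    "generate_absorbance",
]


@dataclass(frozen=True)
class GroundTruth:
    """Known parameters behind a synthetic quench titration.

    Attributes
    ----------
    K_b : float
        Association constant of the ground-state complex, L/mol.
    n_sites : float
        Apparent binding stoichiometry (Hill-like exponent).
    F0 : float
        Unquenched fluorescence, counts per second.
    emission_band : tuple of (center nm, width nm, amplitude)
        Gaussian emission band of the free protein.
    noise_sd_relative : float
        Standard deviation of the multiplicative Gaussian noise, as a
        fraction of the signal (0 disables noise).
    seed : int
        Seed for the noise generator.
    """

    K_b: float = 38.301e3
    n_sites: float = 1.161
    F0: float = 1.2e4
    emission_band: tuple[float, float, float] = (322.0, 25.0, 1.2e4)
    noise_sd_relative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_b <= 0 or self.n_sites <= 0 or self.F0 <= 0:
            raise ValidationError("K_b, n_sites and F0 must be positive")
        if self.noise_sd_relative < 0:
            raise ValidationError("noise_sd_relative must be >= 0")


#: A titration ground truth matching the 298 K serum-albumin study
#: conditions (K_b ~ 3.8e4 L/mol, n ~ 1.16, emission maximum 322 nm).
PAPER_LIKE_TRUTH = GroundTruth()


def default_concentrations(n: int = 10) -> np.ndarray:
    """Quencher concentrations 5-50 uM, the standard titration series."""
    return np.linspace(5e-6, 50e-6, n)


def generate_titration(
    truth: GroundTruth,
    concentrations: Sequence[float] | None = None,
    temperature: float = 298.0,
) -> QuenchTitration:
    """Simulate a quench titration from the static 1:n complex model.

    ``F = F0 / (1 + K_b * [Q]^n)``, then multiplicative Gaussian noise
    ``F * (1 + N(0, noise_sd_relative))``, seeded; a fixed seed reproduces
    the intensities exactly.
    """
    if concentrations is None:
        concentrations = default_concentrations()
    q = np.asarray(concentrations, dtype=float)
    if np.any(q <= 0) or not np.all(np.diff(q) > 0):
        raise ValidationError("concentrations must be positive and increasing")
    f = truth.F0 / (1.0 + truth.K_b * q**truth.n_sites)
    if truth.noise_sd_relative > 0:
        rng = np.random.default_rng(truth.seed)
        f = f * (1.0 + rng.normal(0.0, truth.noise_sd_relative, size=f.shape))
        f = np.clip(f, np.finfo(float).tiny, None)
    return QuenchTitration(
        quencher_concentrations=q,
        intensities=f,
        F0=truth.F0,
        reference_emission_wavelength=truth.emission_band[0],
        temperature=temperature,
        label=f"synthetic titration (seed={truth.seed})",
    )


def _gaussian(x: np.ndarray, center: float, width: float, amplitude: float):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def _make_grid(grid) -> np.ndarray:
    if isinstance(grid, tuple) and len(grid) == 3:
        start, stop, step = grid
        if step <= 0:
            raise ValidationError("grid step must be > 0")
        return np.arange(start, stop + step / 2, step)
    return np.asarray(grid, dtype=float)


def generate_emission_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid,
    excitation_wavelength: float = 280.0,
    temperature: float | None = None,
    label: str = "synthetic emission",
) -> EmissionSpectrum:
    """Sum-of-Gaussians emission spectrum on a wavelength grid.

    ``bands`` is a list of (center nm, width nm, amplitude) triples;
    ``grid`` is either a (start, stop, step) tuple or an explicit array.
    """
    wl = _make_grid(grid)
    intensity = np.zeros_like(wl)
    for center, width, amplitude in bands:
        intensity += _gaussian(wl, center, width, amplitude)
    return EmissionSpectrum(
        emission_wavelengths=wl,
        intensities=intensity,
        excitation_wavelength=excitation_wavelength,
        temperature=temperature,
        label=label,
    )


def generate_absorbance(
    bands: Sequence[tuple[float, float, float]],
    concentration: float,
    path_length: float,
    grid,
    label: str = "synthetic absorbance",
) -> AbsorbanceSpectrum:
    """Sum-of-Gaussians absorbance spectrum via Beer-Lambert.

    Each band is (center nm, width nm, epsilon_max M^-1 cm^-1); absorbance
    is ``A = sum epsilon_band * c * l``, so ``molar_absorptivity`` recovers
    the band epsilons exactly.
    """
    wl = _make_grid(grid)
    eps = np.zeros_like(wl)
    for center, width, eps_max in bands:
        eps += _gaussian(wl, center, width, eps_max)
    return AbsorbanceSpectrum(
        wavelengths=wl,
        absorbance=eps * concentration * path_length,
        chromophore_concentration=concentration,
        path_length=path_length,
        label=label,
    )


def generate_eem(
    free_peaks: Sequence[tuple[float, float, float, tuple[float, float]]],
    quench_factors: Sequence[float],
    em_shift: float | Sequence[float],
    ex_grid,
    em_grid,
) -> tuple[EEMatrix, EEMatrix]:
    """Free/bound pair of EEMs built from separable 2-D Gaussian peaks.

    ``free_peaks`` is a list of (ex_center, em_center, intensity,
    (ex_width, em_width)); the bound matrix multiplies each peak's
    intensity by the matching ``quench_factors`` entry and shifts its
    emission center by ``em_shift`` (a scalar applied to all peaks, or one
    value per peak).  Returns ``(free, bound)``.
    """
    if len(quench_factors) != len(free_peaks):
        raise ValidationError("need one quench factor per peak")
    shifts = (
        [float(em_shift)] * len(free_peaks)
        if np.isscalar(em_shift)
        else [float(s) for s in em_shift]
    )
    if len(shifts) != len(free_peaks):
        raise ValidationError("need one emission shift per peak")
    ex = _make_grid(ex_grid)
    em = _make_grid(em_grid)

    def build(factors, peak_shifts):
        grid = np.zeros((ex.size, em.size))
        for (ex_c, em_c, amp, (ex_w, em_w)), fac, sh in zip(
            free_peaks, factors, peak_shifts
        ):
            grid += np.outer(
                _gaussian(ex, ex_c, ex_w, 1.0),
                _gaussian(em, em_c + sh, em_w, fac * amp),
            )
        return grid

    free = EEMatrix(ex, em, build([1.0] * len(free_peaks), [0.0] * len(free_peaks)),
                    label="synthetic EEM (free)")
    bound = EEMatrix(ex, em, build(list(quench_factors), shifts),
                     label="synthetic EEM (bound)")
    return free, bound
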