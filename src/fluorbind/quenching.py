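"""Stern-Volmer quenching analysis and mechanism classification.

A quencher Q reduces the fluorescence of a protein either dynamically
(excited-state collisions) or statically (ground-state complex formation).
Both obey the Stern-Volmer relation

    F0 / F = 1 + K_q * tau0 * [Q] = 1 + K_SV * [Q]

where F0 and F are the intensities without and with quencher, K_SV is the
Stern-Volmer constant (slope of F0/F against [Q]) and K_q = K_SV / tau0 is
the bimolecular quenching rate constant, with tau0 the unquenched
fluorescence lifetime (1e-8 s for serum albumin's tryptophan).

The mechanisms are distinguished by two signatures measured across
temperatures: a static (binding-controlled) quencher shows K_q above the
diffusion-controlled ceiling and K_SV decreasing with temperature, while a
dynamic (collision-controlled) quencher shows K_q at or below the ceiling
and K_SV increasing with temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError
from .spectra import QuenchTitration

__all__ = [
    "DEFAULT_TAU0",
    "DEFAULT_DIFFUSION_LIMIT",
    "SternVolmerFit",
    "MechanismVerdict",
    "stern_volmer_fit",
    "quenching_rate_constant",
    "classify_mechanism",
]

#: Unquenched fluorescence lifetime of the protein donor, seconds.
DEFAULT_TAU0 = 1e-8

#: Ceiling of the bimolecular rate constant for diffusion-controlled
#: (dynamic) quenching at 298 K, L mol^-1 s^-1.
DEFAULT_DIFFUSION_LIMIT = 7.4e9


@dataclass(frozen=True)
class SternVolmerFit:
    """Result of a linear Stern-Volmer fit at one temperature.

    Attributes
    ----------
    K_SV : float
        Stern-Volmer constant (slope), L/mol.
    K_SV_stderr : float
        Standard error of the slope, L/mol.
    intercept : float
        Fitted intercept of F0/F (1.0 exactly when constrained).
    K_q : float
        Bimolecular quenching rate constant K_SV / tau0, L mol^-1 s^-1.
    r_squared : float
        Coefficient of determination of the fit, clipped to [0, 1].
    tau0 : float
        Unquenched lifetime used, s.
    temperature : float or None
        Temperature of the titration, K.
    n_points : int
        Number of positive-concentration points used.
    """

    K_SV: float
    K_SV_stderr: float
    intercept: float
    K_q: float
    r_squared: float
    tau0: float
    temperature: float | None
    n_points: int


@dataclass(frozen=True)
class MechanismVerdict:
    """Static-vs-dynamic classification with its supporting evidence."""

    label: Literal["static", "dynamic", "ambiguous"]
    kq_exceeds_diffusion_limit: bool
    ksv_temperature_trend: Literal["decreasing", "increasing", "non-monotone"]
    diffusion_limit_used: float


def quenching_rate_constant(K_SV: float, tau0: float = DEFAULT_TAU0) -> float:
    """Bimolecular quenching rate constant ``K_q = K_SV / tau0``.

    Parameters
    ----------
    K_SV : float
        Stern-Volmer constant, L/mol.
    tau0 : float
        Unquenched fluorescence lifetime, s.
    """
    if tau0 <= 0:
        raise DomainError("tau0 must be > 0")
    return K_SV / tau0


def stern_volmer_fit(
    titration: QuenchTitration,
    tau0: float = DEFAULT_TAU0,
    fix_intercept: bool = False,
) -> SternVolmerFit:
    """Fit the Stern-Volmer relation F0/F = intercept + K_SV * [Q].

    Ordinary least squares of F0/F against quencher concentration over the
    points with [Q] > 0.  With ``fix_intercept`` the intercept is pinned to
    the theoretical value of 1 and only the slope is estimated; the default
    leaves it free because measured data rarely passes exactly through 1.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 positive-concentration points.
    ValidationError
        Any intensity is <= 0.
    """
    if tau0 <= 0:
        raise DomainError("tau0 must be > 0")
    mask = titration.quencher_concentrations > 0
    q = titration.quencher_concentrations[mask]
    f = titration.intensities[mask]
    if q.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points with [Q] > 0, have {q.size}"
        )
    if np.any(f <= 0):
        raise ValidationError("all intensities must be > 0 for F0/F")

    y = titration.F0 / f
    if fix_intercept:
        # regression through (0, 1): minimize ||(y - 1) - slope*q||^2
        yc = y - 1.0
        sxx = float(np.dot(q, q))
        slope = float(np.dot(q, yc)) / sxx
        resid = yc - slope * q
        dof = q.size - 1
        stderr = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
        intercept = 1.0
        fitted = 1.0 + slope * q
    else:
        res = stats.linregress(q, y)
        slope = float(res.slope)
        intercept = float(res.intercept)
        stderr = float(res.stderr)
        fitted = intercept + slope * q

    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # flat data (no quenching): the constant model is exact
        r_squared = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r_squared = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))

    return SternVolmerFit(
        K_SV=slope,
        K_SV_stderr=stderr,
        intercept=intercept,
        K_q=quenching_rate_constant(slope, tau0),
        r_squared=r_squared,
        tau0=tau0,
        temperature=titration.temperature,
        n_points=int(q.size),
    )


def _ksv_trend(temperatures: np.ndarray, ksv: np.ndarray) -> str:
    diffs = np.diff(ksv)
    if np.any(diffs > 0) and np.any(diffs < 0):
        return "non-monotone"
    slope = stats.linregress(temperatures, ksv).slope
    return "decreasing" if slope < 0 else "increasing"


def classify_mechanism(
    fits: Sequence[SternVolmerFit],
    diffusion_limit: float = DEFAULT_DIFFUSION_LIMIT,
) -> MechanismVerdict:
    """Classify quenching as static, dynamic or ambiguous.

    The verdict combines two pieces of evidence: whether every K_q exceeds
    the diffusion-controlled ceiling, and the direction of the K_SV trend
    across temperature (sign of the least-squares slope; reported as
    non-monotone when pointwise differences change sign).  ``static``
    requires K_q above the ceiling *and* a decreasing trend; ``dynamic``
    requires K_q at or below the ceiling and an increasing trend; every
    other combination is ``ambiguous``, with both evidence flags exposed so
    the caller can weigh them.

    Parameters
    ----------
    fits : sequence of SternVolmerFit
        Fits at >= 2 distinct temperatures, sorted by temperature, all
        computed with the same tau0.
    diffusion_limit : float
        Dynamic-quenching ceiling, L mol^-1 s^-1.
    """
    if len(fits) < 2:
        raise InsufficientDataError(
            "mechanism classification needs fits at >= 2 temperatures"
        )
    temps = np.array([f.temperature for f in fits], dtype=float)
    if np.any(np.isnan(temps)):
        raise ValidationError("every fit must carry a temperature")
    if not np.all(np.diff(temps) > 0):
        raise ValidationError("fits must be sorted by strictly increasing temperature")
    tau0s = {f.tau0 for f in fits}
    if len(tau0s) != 1:
        raise ValidationError("all fits must share the same tau0")

    ksv = np.array([f.K_SV for f in fits])
    kq = np.array([f.K_q for f in fits])
    trend = _ksv_trend(temps, ksv)
    exceeds = bool(np.all(kq > diffusion_limit))
    all_below = bool(np.all(kq <= diffusion_limit))

    if exceeds and trend == "decreasing":
        label = "static"
    elif all_below and trend == "increasing":
        label = "dynamic"
    else:
        label = "ambiguous"
    return MechanismVerdict(
        label=label,
        kq_exceeds_diffusion_limit=exceeds,
        ksv_temperature_trend=trend,
        diffusion_limit_used=diffusion_limit,
    )
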