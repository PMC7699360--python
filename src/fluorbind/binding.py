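"""Binding-constant estimation and site-marker displacement analysis.

For static quenching by ground-state 1:n complex formation, the fraction of
quenched fluorophore obeys the double-logarithmic isotherm

    log10((F0 - F) / F) = log10(K_b) + n * log10([Q])

so an ordinary least-squares line through the double-log plot yields the
apparent association constant K_b (from the intercept) and the apparent
number of binding sites n (from the slope).  The free-ligand concentration
is approximated by the total added ligand; no depletion correction is
applied.  The Gibbs free energy of association follows as

    dG = -R * T * ln(K_b),   R = 8.314 J K^-1 mol^-1.

Site-marker displacement compares K_b fitted with a site-specific competitor
present (warfarin for Sudlow site I, flufenamic acid for site II, digitoxin
for site III) against the marker-free baseline: a marker sharing the
ligand's site depresses the apparent K_b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError
from .spectra import QuenchTitration

__all__ = [
    "GAS_CONSTANT",
    "BindingFit",
    "DisplacementEntry",
    "DisplacementReport",
    "double_log_fit",
    "gibbs_free_energy",
    "displacement_analysis",
]

logger = logging.getLogger(__name__)

#: Universal gas constant, J K^-1 mol^-1.
GAS_CONSTANT = 8.314

#: Default fractional K_b drop (in percent) counted as displacement.
DEFAULT_DISPLACEMENT_THRESHOLD = 10.0


@dataclass(frozen=True)
class BindingFit:
    """Double-log isotherm fit: K_b, stoichiometry n and Gibbs energy.

    ``K_b_stderr_log10`` is the standard error of the fitted intercept,
    i.e. of log10(K_b); ``n_excluded`` counts points dropped because
    F >= F0 leaves the left side of the isotherm undefined.
    """

    K_b: float
    n_sites: float
    K_b_stderr_log10: float
    n_stderr: float
    r_squared: float
    temperature: float
    delta_G: float
    n_points: int
    n_excluded: int = 0


@dataclass(frozen=True)
class DisplacementEntry:
    """Displacement outcome for one site marker."""

    marker: str
    fit: BindingFit
    percent_change_Kb: float
    delta_delta_G: float
    displaces: bool


@dataclass(frozen=True)
class DisplacementReport:
    """Baseline fit plus per-marker competitive-displacement entries."""

    baseline: BindingFit
    entries: tuple[DisplacementEntry, ...]
    threshold_percent: float


def gibbs_free_energy(K_b: float, temperature: float) -> float:
    """Gibbs free energy of association, kJ/mol.

    ``dG = -R*T*ln(K_b) / 1000`` with R = 8.314 J K^-1 mol^-1; negative for
    K_b > 1 (spontaneous association).
    """
    if K_b <= 0:
        raise DomainError("K_b must be > 0")
    if temperature <= 0:
        raise DomainError("temperature must be > 0 K")
    return -GAS_CONSTANT * temperature * float(np.log(K_b)) / 1000.0


def double_log_fit(titration: QuenchTitration) -> BindingFit:
    """Fit the double-logarithmic binding isotherm to a quench titration.

    OLS of log10((F0-F)/F) on log10([Q]) over the points with [Q] > 0 and
    0 < F < F0.  Points with F >= F0 (no measurable quenching, so the
    double-log transform is undefined) are excluded with a logged warning
    and counted in the result.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points remain after exclusion.
    ValidationError
        The titration carries no temperature (needed for dG).
    """
    if titration.temperature is None:
        raise ValidationError(
            "titration must carry a temperature to compute delta_G"
        )
    q = titration.quencher_concentrations
    f = titration.intensities
    f0 = titration.F0
    usable = (q > 0) & (f > 0) & (f < f0)
    n_excluded = int(np.count_nonzero((q > 0) & ~usable))
    if n_excluded:
        logger.warning(
            "double_log_fit: excluded %d point(s) with F >= F0 or F <= 0",
            n_excluded,
        )
    q, f = q[usable], f[usable]
    if q.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points with 0 < F < F0, have {q.size}"
        )

    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    res = stats.linregress(x, y)
    K_b = float(10.0 ** res.intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else float(np.clip(res.rvalue**2, 0.0, 1.0))
    return BindingFit(
        K_b=K_b,
        n_sites=float(res.slope),
        K_b_stderr_log10=float(res.intercept_stderr),
        n_stderr=float(res.stderr),
        r_squared=r_squared,
        temperature=titration.temperature,
        delta_G=gibbs_free_energy(K_b, titration.temperature),
        n_points=int(q.size),
        n_excluded=n_excluded,
    )


def displacement_analysis(
    baseline: BindingFit,
    marker_fits: Mapping[str, BindingFit],
    threshold_percent: float = DEFAULT_DISPLACEMENT_THRESHOLD,
) -> DisplacementReport:
    """Compare binding fits with site markers present against a baseline.

    For each marker the relative change of the apparent association
    constant, ``100 * (K_b,marker - K_b,baseline) / K_b,baseline``, and the
    shift of Gibbs energy ``ddG = dG,marker - dG,baseline`` are reported;
    ``displaces`` is set when K_b drops by more than ``threshold_percent``.

    All fits must share the baseline's temperature.
    """
    if threshold_percent <= 0:
        raise DomainError("threshold_percent must be > 0")
    entries = []
    for marker, fit in marker_fits.items():
        if fit.temperature != baseline.temperature:
            raise ValidationError(
                f"marker {marker!r} fitted at {fit.temperature} K but the "
                f"baseline is at {baseline.temperature} K"
            )
        pct = 100.0 * (fit.K_b - baseline.K_b) / baseline.K_b
        entries.append(
            DisplacementEntry(
                marker=marker,
                fit=fit,
                percent_change_Kb=pct,
                delta_delta_G=fit.delta_G - baseline.delta_G,
                displaces=pct < -threshold_percent,
            )
        )
    return DisplacementReport(
        baseline=baseline,
        entries=tuple(entries),
        threshold_percent=threshold_percent,
    )
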