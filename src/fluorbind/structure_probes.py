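"""Conformational probes: synchronous fluorescence, EEM peaks, UV-Vis shifts.

Three complementary readouts of ligand-induced conformational change in a
fluorescent protein:

* synchronous fluorescence -- scanning excitation and emission together at
  a fixed offset delta_lambda isolates tyrosine (15 nm) or tryptophan
  (60 nm) microenvironments; intensity loss and wavelength shifts of the
  scan maximum report on local polarity changes;
* 3D / excitation-emission-matrix peaks -- the Rayleigh line (ex = em) and
  the intrinsic tryptophan peak are summarized by windowed maxima, percent
  intensity change and emission shift relative to the ligand-free protein;
* UV-Vis absorption maxima -- the complex's lambda_max relative to the
  free protein (negative shift = blue) and free ligand (positive = red).

Peak positions are grid argmaxima with ties broken toward shorter
wavelength; instruments report integer-nm positions, so no sub-grid
refinement is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import RangeError, ValidationError
from .spectra import AbsorbanceSpectrum, EEMatrix, SynchronousScan

__all__ = [
    "PeakSummary",
    "UVVisShiftReport",
    "synchronous_scan",
    "compare_scans",
    "eem_peak_table",
    "uvvis_shift",
]


@dataclass(frozen=True)
class PeakSummary:
    """Free-vs-bound comparison of one spectral peak.

    ``percent_change`` is 100*(bound - free)/free rounded to the configured
    number of decimals; ``percent_change_full`` keeps full precision.
    Positions are emission wavelengths in nm (for EEM peaks, an
    (excitation, emission) pair); ``shift`` is bound minus free on the
    emission axis, positive for a red shift.
    """

    free_intensity: float
    bound_intensity: float
    percent_change: float
    free_position: float | tuple[float, float]
    bound_position: float | tuple[float, float]
    shift: float
    percent_change_full: float
    region: str = ""


@dataclass(frozen=True)
class UVVisShiftReport:
    """Absorption maxima of complex vs. free protein and free ligand."""

    complex_lambda_max: float
    protein_lambda_max: float
    ligand_lambda_max: float
    shift_vs_protein: float
    shift_vs_ligand: float


def _percent_change(free: float, bound: float) -> float:
    return 100.0 * (bound - free) / free


def _argmax_first(values: np.ndarray) -> int:
    # np.argmax returns the first occurrence, i.e. the shortest wavelength
    return int(np.argmax(values))


def synchronous_scan(eem: EEMatrix, delta_lambda: float) -> SynchronousScan:
    """Extract the constant-offset scan lambda_em = lambda_ex + delta_lambda.

    For every excitation wavelength whose target emission lies inside the
    emission axis, the intensity is read by linear interpolation along the
    emission axis of that excitation row (bilinear on the grid, degenerate
    in the excitation direction because excitation points are on-grid).
    Excitation points whose target emission falls outside the grid are
    dropped.

    Raises
    ------
    RangeError
        No excitation point admits lambda_ex + delta_lambda on the grid.
    """
    if delta_lambda <= 0:
        raise ValidationError("delta_lambda must be > 0")
    targets = eem.excitation_wavelengths + delta_lambda
    em = eem.emission_wavelengths
    admissible = (targets >= em[0]) & (targets <= em[-1])
    if not np.any(admissible):
        raise RangeError(
            f"delta_lambda={delta_lambda} nm leaves no excitation point whose "
            f"target emission falls inside [{em[0]}, {em[-1]}] nm"
        )
    ex = eem.excitation_wavelengths[admissible]
    intensities = np.array(
        [
            np.interp(t, em, row)
            for t, row in zip(targets[admissible], eem.intensity_grid[admissible])
        ]
    )
    return SynchronousScan(
        delta_lambda=delta_lambda,
        excitation_wavelengths=ex,
        intensities=intensities,
        label=eem.label,
    )


def compare_scans(
    free: SynchronousScan,
    bound: SynchronousScan,
    rounding: int = 1,
) -> PeakSummary:
    """Summarize the free-vs-bound change of the synchronous-scan maximum.

    The peak is the global maximum of each scan; positions are reported on
    the emission axis (lambda_ex + delta_lambda).  Both scans must share
    the same delta_lambda.
    """
    if free.delta_lambda != bound.delta_lambda:
        raise ValidationError(
            f"delta_lambda mismatch: {free.delta_lambda} vs {bound.delta_lambda}"
        )
    i_free = _argmax_first(free.intensities)
    i_bound = _argmax_first(bound.intensities)
    free_int = float(free.intensities[i_free])
    bound_int = float(bound.intensities[i_bound])
    free_pos = float(free.emission_wavelengths[i_free])
    bound_pos = float(bound.emission_wavelengths[i_bound])
    pct = _percent_change(free_int, bound_int)
    return PeakSummary(
        free_intensity=free_int,
        bound_intensity=bound_int,
        percent_change=round(pct, rounding),
        free_position=free_pos,
        bound_position=bound_pos,
        shift=bound_pos - free_pos,
        percent_change_full=pct,
        region=f"delta_lambda={free.delta_lambda:g} nm",
    )


def _windowed_peak(
    eem: EEMatrix, ex_window: tuple[float, float], em_window: tuple[float, float]
):
    ex_mask = (eem.excitation_wavelengths >= ex_window[0]) & (
        eem.excitation_wavelengths <= ex_window[1]
    )
    em_mask = (eem.emission_wavelengths >= em_window[0]) & (
        eem.emission_wavelengths <= em_window[1]
    )
    if not np.any(ex_mask) or not np.any(em_mask):
        raise RangeError(
            f"region ex={ex_window}, em={em_window} nm does not intersect the grid"
        )
    sub = eem.intensity_grid[np.ix_(ex_mask, em_mask)]
    i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
    ex = float(eem.excitation_wavelengths[ex_mask][i])
    em = float(eem.emission_wavelengths[em_mask][j])
    return float(sub[i, j]), (ex, em)


def eem_peak_table(
    free: EEMatrix,
    bound_list: Sequence[EEMatrix],
    regions: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    rounding: int = 1,
) -> list[list[PeakSummary]]:
    """Windowed peak comparison of bound EEMs against the free protein.

    For every bound matrix and every (excitation window, emission window)
    region, the global maximum inside the window is located on both grids
    and summarized as percent intensity change and emission-axis shift.
    The Rayleigh scatter line (ex = em) is treated as an ordinary region.

    Returns one list of :class:`PeakSummary` per bound matrix, ordered as
    ``regions``.
    """
    table: list[list[PeakSummary]] = []
    for bound in bound_list:
        rows: list[PeakSummary] = []
        for k, (ex_win, em_win) in enumerate(regions, start=1):
            free_int, free_pos = _windowed_peak(free, ex_win, em_win)
            bound_int, bound_pos = _windowed_peak(bound, ex_win, em_win)
            pct = _percent_change(free_int, bound_int)
            rows.append(
                PeakSummary(
                    free_intensity=free_int,
                    bound_intensity=bound_int,
                    percent_change=round(pct, rounding),
                    free_position=free_pos,
                    bound_position=bound_pos,
                    shift=bound_pos[1] - free_pos[1],
                    percent_change_full=pct,
                    region=f"peak {k}: ex {ex_win} x em {em_win} nm",
                )
            )
        table.append(rows)
    return table


def _lambda_max(spec: AbsorbanceSpectrum, window: tuple[float, float]) -> float:
    lo, hi = window
    if lo < spec.wavelengths[0] or hi > spec.wavelengths[-1]:
        raise RangeError(
            f"window [{lo}, {hi}] nm exceeds spectrum range "
            f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
        )
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not np.any(mask):
        raise RangeError(f"window [{lo}, {hi}] nm contains no samples")
    sub = spec.absorbance[mask]
    return float(spec.wavelengths[mask][_argmax_first(sub)])


def uvvis_shift(
    free_protein: AbsorbanceSpectrum,
    complex_minus_ligand: AbsorbanceSpectrum,
    free_ligand: AbsorbanceSpectrum,
    window: tuple[float, float],
) -> UVVisShiftReport:
    """Absorption lambda_max shifts of the complex vs. its free components.

    Each lambda_max is the grid argmax inside ``window`` (no sub-grid
    interpolation).  ``complex_minus_ligand`` is the complex spectrum with
    the free-ligand contribution subtracted, so its maximum reflects the
    bound protein.  A negative shift vs. the protein is a blue shift, a
    positive shift vs. the ligand a red shift.
    """
    complex_max = _lambda_max(complex_minus_ligand, window)
    protein_max = _lambda_max(free_protein, window)
    ligand_max = _lambda_max(free_ligand, window)
    return UVVisShiftReport(
        complex_lambda_max=complex_max,
        protein_lambda_max=protein_max,
        ligand_lambda_max=ligand_max,
        shift_vs_protein=complex_max - protein_max,
        shift_vs_ligand=complex_max - ligand_max,
    )
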