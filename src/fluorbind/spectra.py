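"""Core data model and delimited-text I/O for spectra and titrations.

All downstream analyses consume one of five in-memory containers:

``EmissionSpectrum``
    Fluorescence intensity sampled against emission wavelength at a fixed
    excitation wavelength (the donor side of an energy-transfer pair).
``AbsorbanceSpectrum``
    Absorbance against wavelength for a chromophore of known concentration
    and path length (the acceptor side, via Beer-Lambert).
``QuenchTitration``
    Fluorescence intensity at a fixed reference emission wavelength as a
    function of quencher concentration, together with the unquenched
    intensity F0 -- the substrate of Stern-Volmer and double-log fits.
``EEMatrix``
    An excitation x emission intensity grid (a 3D fluorescence landscape).
``SynchronousScan``
    Intensity along the line lambda_em = lambda_ex + delta_lambda through
    an excitation-emission matrix.

File dialect
------------
Plain CSV with ``#``-prefixed metadata lines of the form ``# key=value``
preceding a single header row.  Fluorometer vendors export no common text
format, so the package defines this one and round-trips it losslessly.
Intensities are stored as floating point even though instruments report
integer counts, because normalized and synthetic spectra need fractional
values.  Wavelength grids need not be uniform; operations that require a
uniform grid interpolate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "EmissionSpectrum",
    "AbsorbanceSpectrum",
    "QuenchTitration",
    "EEMatrix",
    "SynchronousScan",
    "read_spectrum",
    "write_spectrum",
]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum at a fixed excitation wavelength.

    Parameters
    ----------
    emission_wavelengths : array-like of float
        Emission wavelengths in nm, strictly increasing.
    intensities : array-like of float
        Fluorescence intensity (counts per second), same length,
        non-negative and finite.
    excitation_wavelength : float
        Excitation wavelength in nm.
    temperature : float, optional
        Sample temperature in K.
    label : str, optional
        Free-text sample description.
    """

    emission_wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float
    temperature: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.emission_wavelengths = _as_float_array(
            self.emission_wavelengths, "emission_wavelengths"
        )
        self.intensities = _as_float_array(self.intensities, "intensities")
        _check_strictly_increasing(self.emission_wavelengths, "emission_wavelengths")
        if self.emission_wavelengths.size != self.intensities.size:
            raise ValidationError(
                "emission_wavelengths and intensities differ in length"
            )
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        self.excitation_wavelength = float(self.excitation_wavelength)
        if self.temperature is not None:
            self.temperature = float(self.temperature)


@dataclass
class AbsorbanceSpectrum:
    """UV-Vis absorbance spectrum of a chromophore solution.

    Absorbance is in AU for a solution of known molar concentration and
    cuvette path length, so the molar absorption coefficient follows from
    Beer-Lambert as ``A / (c * l)``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    chromophore_concentration: float
    path_length: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.absorbance = _as_float_array(self.absorbance, "absorbance")
        _check_strictly_increasing(self.wavelengths, "wavelengths")
        if self.wavelengths.size != self.absorbance.size:
            raise ValidationError("wavelengths and absorbance differ in length")
        self.chromophore_concentration = float(self.chromophore_concentration)
        self.path_length = float(self.path_length)
        if self.chromophore_concentration <= 0:
            raise ValidationError("chromophore_concentration must be > 0")
        if self.path_length <= 0:
            raise ValidationError("path_length must be > 0")


@dataclass
class QuenchTitration:
    """Fluorescence read at a fixed emission wavelength vs. quencher added.

    ``F0`` is the intensity with no quencher present.  Intensities above
    ``1.05 * F0`` are physically suspect (quenching can only lower the
    signal; 5% headroom allows for noise) and trigger a warning, recorded
    in :attr:`suspect_indices`, but are not rejected.
    """

    quencher_concentrations: np.ndarray
    intensities: np.ndarray
    F0: float
    reference_emission_wavelength: float | None = None
    temperature: float | None = None
    label: str = ""
    suspect_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.quencher_concentrations = _as_float_array(
            self.quencher_concentrations, "quencher_concentrations"
        )
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.quencher_concentrations.size != self.intensities.size:
            raise ValidationError(
                "quencher_concentrations and intensities differ in length"
            )
        if np.any(self.quencher_concentrations < 0):
            raise ValidationError("quencher_concentrations must be non-negative")
        _check_strictly_increasing(
            self.quencher_concentrations, "quencher_concentrations"
        )
        self.F0 = float(self.F0)
        if self.F0 <= 0:
            raise ValidationError("F0 must be > 0")
        if self.reference_emission_wavelength is not None:
            self.reference_emission_wavelength = float(
                self.reference_emission_wavelength
            )
        if self.temperature is not None:
            self.temperature = float(self.temperature)
        self.suspect_indices = np.flatnonzero(self.intensities > 1.05 * self.F0)
        if self.suspect_indices.size:
            warnings.warn(
                f"{self.suspect_indices.size} intensity value(s) exceed "
                "1.05*F0; check the titration data",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.quencher_concentrations.size)


@dataclass
class EEMatrix:
    """Excitation-emission matrix: intensity on an excitation x emission grid."""

    excitation_wavelengths: np.ndarray
    emission_wavelengths: np.ndarray
    intensity_grid: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.excitation_wavelengths = _as_float_array(
            self.excitation_wavelengths, "excitation_wavelengths"
        )
        self.emission_wavelengths = _as_float_array(
            self.emission_wavelengths, "emission_wavelengths"
        )
        _check_strictly_increasing(
            self.excitation_wavelengths, "excitation_wavelengths"
        )
        _check_strictly_increasing(self.emission_wavelengths, "emission_wavelengths")
        self.intensity_grid = np.asarray(self.intensity_grid, dtype=float)
        expected = (
            self.excitation_wavelengths.size,
            self.emission_wavelengths.size,
        )
        if self.intensity_grid.shape != expected:
            raise ValidationError(
                f"intensity_grid shape {self.intensity_grid.shape} does not "
                f"match axes {expected}"
            )
        if not np.all(np.isfinite(self.intensity_grid)):
            raise ValidationError("intensity_grid contains non-finite values")
        if np.any(self.intensity_grid < 0):
            raise ValidationError("intensity_grid must be non-negative")


@dataclass
class SynchronousScan:
    """Intensity along lambda_em = lambda_ex + delta_lambda through an EEM.

    A delta_lambda of 15 nm reports on tyrosine microenvironments, 60 nm
    on tryptophan; intensities are indexed by excitation wavelength.
    """

    delta_lambda: float
    excitation_wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.delta_lambda = float(self.delta_lambda)
        if self.delta_lambda <= 0:
            raise ValidationError("delta_lambda must be > 0")
        self.excitation_wavelengths = _as_float_array(
            self.excitation_wavelengths, "excitation_wavelengths"
        )
        self.intensities = _as_float_array(self.intensities, "intensities")
        _check_strictly_increasing(
            self.excitation_wavelengths, "excitation_wavelengths"
        )
        if self.excitation_wavelengths.size != self.intensities.size:
            raise ValidationError(
                "excitation_wavelengths and intensities differ in length"
            )

    @property
    def emission_wavelengths(self) -> np.ndarray:
        """Emission axis of the scan (excitation + delta_lambda)."""
        return self.excitation_wavelengths + self.delta_lambda


_KINDS = ("emission", "absorbance", "titration", "eem")


def _format_float(x: float) -> str:
    return repr(float(x))


def _parse_header(path: Path) -> tuple[dict[str, str], str]:
    """Split a dialect file into metadata dict and the CSV body."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if body_lines:
                    raise FormatError(
                        f"{path}:{lineno}: metadata line after data table"
                    )
                content = line.lstrip("#").strip()
                if not content:
                    continue
                if "=" not in content:
                    raise FormatError(
                        f"{path}:{lineno}: metadata line lacks 'key=value' form: "
                        f"{line!r}"
                    )
                key, _, value = content.partition("=")
                meta[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no data table found")
    return meta, "\n".join(body_lines)


def _meta_float(meta: dict[str, str], key: str, path: Path, required: bool = True):
    if key not in meta:
        if required:
            raise FormatError(f"{path}: missing required metadata '{key}'")
        return None
    try:
        return float(meta[key])
    except ValueError as exc:
        raise FormatError(f"{path}: metadata '{key}' is not numeric") from exc


def read_spectrum(path, kind: str):
    """Read a spectrum file of the given kind from the package CSV dialect.

    Parameters
    ----------
    path : path-like
        File to read.
    kind : {'emission', 'absorbance', 'titration', 'eem'}
        Which container to construct.

    Returns
    -------
    EmissionSpectrum, AbsorbanceSpectrum, QuenchTitration or EEMatrix
        Fully validated object; every invariant is enforced on load and a
        violating file raises rather than being silently repaired.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, body = _parse_header(path)
    declared = meta.get("kind")
    if declared is not None and declared != kind:
        raise FormatError(
            f"{path}: file declares kind={declared!r} but {kind!r} was requested"
        )
    try:
        table = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: cannot parse data table: {exc}") from exc
    if table.isna().any().any():
        raise FormatError(f"{path}: data table contains missing values")
    label = meta.get("label", "")

    if kind == "emission":
        if table.shape[1] != 2:
            raise FormatError(f"{path}: emission table needs exactly 2 columns")
        return EmissionSpectrum(
            emission_wavelengths=table.iloc[:, 0].to_numpy(),
            intensities=table.iloc[:, 1].to_numpy(),
            excitation_wavelength=_meta_float(meta, "excitation", path),
            temperature=_meta_float(meta, "temperature", path, required=False),
            label=label,
        )
    if kind == "absorbance":
        if table.shape[1] != 2:
            raise FormatError(f"{path}: absorbance table needs exactly 2 columns")
        return AbsorbanceSpectrum(
            wavelengths=table.iloc[:, 0].to_numpy(),
            absorbance=table.iloc[:, 1].to_numpy(),
            chromophore_concentration=_meta_float(meta, "concentration", path),
            path_length=_meta_float(meta, "path_length", path),
            label=label,
        )
    if kind == "titration":
        if table.shape[1] != 2:
            raise FormatError(f"{path}: titration table needs exactly 2 columns")
        return QuenchTitration(
            quencher_concentrations=table.iloc[:, 0].to_numpy(),
            intensities=table.iloc[:, 1].to_numpy(),
            F0=_meta_float(meta, "F0", path),
            reference_emission_wavelength=_meta_float(
                meta, "reference_emission", path, required=False
            ),
            temperature=_meta_float(meta, "temperature", path, required=False),
            label=label,
        )
    # EEM: first column is the excitation axis, remaining headers are the
    # emission axis.
    try:
        emission = np.array([float(c) for c in table.columns[1:]])
    except ValueError as exc:
        raise FormatError(
            f"{path}: EEM column headers must be emission wavelengths"
        ) from exc
    return EEMatrix(
        excitation_wavelengths=table.iloc[:, 0].to_numpy(),
        emission_wavelengths=emission,
        intensity_grid=table.iloc[:, 1:].to_numpy(),
        label=label,
    )


def write_spectrum(obj, path) -> Path:
    """Write a spectral object in the package CSV dialect.

    ``read_spectrum(write_spectrum(x), kind)`` reproduces ``x`` at full
    stored precision (floats are written with ``repr``).
    """
    path = Path(path)
    lines: list[str] = []

    def put(key: str, value) -> None:
        if value is not None and value != "":
            lines.append(f"# {key}={value}")

    if isinstance(obj, EmissionSpectrum):
        put("kind", "emission")
        put("excitation", _format_float(obj.excitation_wavelength))
        if obj.temperature is not None:
            put("temperature", _format_float(obj.temperature))
        put("label", obj.label)
        lines.append("wavelength_nm,intensity_cps")
        for w, i in zip(obj.emission_wavelengths, obj.intensities):
            lines.append(f"{_format_float(w)},{_format_float(i)}")
    elif isinstance(obj, AbsorbanceSpectrum):
        put("kind", "absorbance")
        put("concentration", _format_float(obj.chromophore_concentration))
        put("path_length", _format_float(obj.path_length))
        put("label", obj.label)
        lines.append("wavelength_nm,absorbance_AU")
        for w, a in zip(obj.wavelengths, obj.absorbance):
            lines.append(f"{_format_float(w)},{_format_float(a)}")
    elif isinstance(obj, QuenchTitration):
        put("kind", "titration")
        put("F0", _format_float(obj.F0))
        if obj.reference_emission_wavelength is not None:
            put("reference_emission", _format_float(obj.reference_emission_wavelength))
        if obj.temperature is not None:
            put("temperature", _format_float(obj.temperature))
        put("label", obj.label)
        lines.append("concentration_M,intensity_cps")
        for c, i in zip(obj.quencher_concentrations, obj.intensities):
            lines.append(f"{_format_float(c)},{_format_float(i)}")
    elif isinstance(obj, EEMatrix):
        put("kind", "eem")
        put("label", obj.label)
        header = ["excitation_nm"] + [
            _format_float(w) for w in obj.emission_wavelengths
        ]
        lines.append(",".join(header))
        for ex, row in zip(obj.excitation_wavelengths, obj.intensity_grid):
            lines.append(
                ",".join([_format_float(ex)] + [_format_float(v) for v in row])
            )
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")

    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def kind_of(obj) -> str:
    """Return the dialect kind string for a spectral object."""
    for cls, kind in (
        (EmissionSpectrum, "emission"),
        (AbsorbanceSpectrum, "absorbance"),
        (QuenchTitration, "titration"),
        (EEMatrix, "eem"),
    ):
        if isinstance(obj, cls):
            return kind
    raise TypeError(type(obj).__name__)
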