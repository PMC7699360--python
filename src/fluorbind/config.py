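"""Analysis configuration shared by the command-line subcommands."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import ValidationError
from .fret import DEFAULT_GRID_STEP, ForsterParameters
from .quenching import DEFAULT_DIFFUSION_LIMIT, DEFAULT_TAU0

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the pipeline, serializable to YAML.

    Attributes
    ----------
    tau0 : float
        Unquenched donor lifetime, s.
    diffusion_limit : float
        Dynamic-quenching rate ceiling, L mol^-1 s^-1.
    displacement_threshold : float
        Percent drop of K_b counted as site displacement.
    kappa_squared, refractive_index, donor_quantum_yield : float
        Forster-radius constants.
    grid_step : float
        Resampling step for the overlap integral, nm.
    rounding_decimals : int
        Decimals for percent changes in table reports.
    seed : int
        Seed for synthetic-data subcommands.
    """

    tau0: float = DEFAULT_TAU0
    diffusion_limit: float = DEFAULT_DIFFUSION_LIMIT
    displacement_threshold: float = 10.0
    kappa_squared: float = 2.0 / 3.0
    refractive_index: float = 1.336
    donor_quantum_yield: float = 0.15
    grid_step: float = DEFAULT_GRID_STEP
    rounding_decimals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tau0",
            "diffusion_limit",
            "displacement_threshold",
            "refractive_index",
            "donor_quantum_yield",
            "grid_step",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.rounding_decimals < 0:
            raise ValidationError("rounding_decimals must be >= 0")

    @property
    def forster_parameters(self) -> ForsterParameters:
        return ForsterParameters(
            kappa_squared=self.kappa_squared,
            refractive_index=self.refractive_index,
            donor_quantum_yield=self.donor_quantum_yield,
        )

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the non-None keyword values replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True),
                        encoding="utf-8")
        return path

    def digest(self) -> str:
        """Short stable hash of the configuration, for log provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
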