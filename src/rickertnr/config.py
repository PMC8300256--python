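"""Run configuration shared by the assessment pipeline and the CLI.

Every tunable of the pipeline lives here with its default: the
significance level, the outlier-screening threshold, LOWESS settings,
the year a growth rate is indexed by, and the simulation horizon.
Values can be overridden from a YAML file and/or CLI flags (flags win),
and the effective configuration is echoed in every report header so a
result can always be traced to the settings that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .errors import DataValidationError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    alpha: float = 0.05
    outlier_threshold: float = 2.0
    lowess_bandwidth: float = 2.0 / 3.0
    lowess_robust_iters: int = 3
    rate_year_convention: str = "earlier"  # "earlier" | "later"
    simulation_years: int = 20
    percent_rounding: str = "half_away"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataValidationError("alpha must be in (0, 1)")
        if self.outlier_threshold <= 0:
            raise DataValidationError("outlier_threshold must be positive")
        if not 0 < self.lowess_bandwidth <= 1:
            raise DataValidationError("lowess_bandwidth must be in (0, 1]")
        if self.rate_year_convention not in ("earlier", "later"):
            raise DataValidationError(
                f"unknown rate_year_convention {self.rate_year_convention!r}"
            )
        if self.simulation_years < 1:
            raise DataValidationError("simulation_years must be >= 1")
        if self.percent_rounding != "half_away":
            raise DataValidationError("percent_rounding must be 'half_away'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def override(self, **kwargs: Any) -> "RunConfig":
        """A copy with the given fields replaced (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    cfg = RunConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise DataValidationError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise DataValidationError(
                f"unknown config keys: {', '.join(sorted(unknown))}"
            )
        cfg = cfg.override(**data)
    if overrides:
        cfg = cfg.override(**overrides)
    return cfg
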