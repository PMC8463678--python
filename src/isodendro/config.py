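"""Pipeline configuration: one validated object, loadable from YAML.

Every run resolves to a :class:`PipelineConfig`; its SHA-256 hash and the
seed are stamped into the header of every output file so that artifacts are
traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .periods import Period, check_disjoint, validate_period


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline.

    Input paths are optional: when ``tree_csv`` is absent the synthetic
    generator supplies trees (and climate/atm unless those paths are given).
    Windows are inclusive year pairs.  The verification window must be
    disjoint from the calibration window; the boundary year of a shared
    calibration/verification edge belongs to calibration by default
    (1990–2009 vs 1969–1989).
    """

    # inputs (None -> synthesise)
    tree_csv: str | None = None
    climate_csv: str | None = None
    atm_csv: str | None = None
    eruption_csv: str | None = None

    # synthetic scenario
    year_range: Period = (516, 2009)
    n_trees: int = 42
    target_variable: str = "precipitation"
    target_months: tuple[int, ...] = (7,)
    transfer_slope: float = -16.7
    tree_sd: float = 0.15
    noise_sd: float = 0.2
    juvenile_amplitude: float = 0.3
    ar1_coeff: float = 0.3
    innovation_sd: float = 1.0
    volcanic_cooling: float = 1.5

    # chronology
    juvenile_exclude: int = 50
    min_replication: int = 4

    # Suess correction
    suess_ref_year: int = 1850

    # calibration / verification
    calibration_period: Period = (1990, 2009)
    verification_period: Period = (1969, 1989)
    n_bootstrap: int = 1000

    # extremes
    sigma_thresholds: tuple[float, ...] = (2.0, 3.0)
    smooth_window: int = 41
    min_vei: int = 4
    lag_window: tuple[int, int] = (0, 3)

    seed: int = 0

    def __post_init__(self):
        self.year_range = validate_period(self.year_range, "year_range")
        self.calibration_period = validate_period(self.calibration_period, "calibration_period")
        self.verification_period = validate_period(self.verification_period, "verification_period")
        check_disjoint(self.calibration_period, self.verification_period)
        for name in ("juvenile_exclude", "min_replication", "n_trees", "min_vei"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if any(t <= 0 for t in self.sigma_thresholds):
            raise ValidationError("sigma_thresholds must be positive")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be an odd integer ≥ 3")
        self.target_months = tuple(int(m) for m in self.target_months)
        self.sigma_thresholds = tuple(float(t) for t in self.sigma_thresholds)
        self.lag_window = (int(self.lag_window[0]), int(self.lag_window[1]))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("year_range", "calibration_period", "verification_period",
                    "target_months", "sigma_thresholds", "lag_window"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("year_range", "calibration_period", "verification_period",
                    "target_months", "sigma_thresholds", "lag_window"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        """Short SHA-256 of the canonical YAML form."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
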