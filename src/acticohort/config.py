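"""Pipeline configuration.

Every numeric constant of the epoch/wear pipeline lives here so that the
processing chain is auditable end to end: epoch length, the non-wear
detector's window geometry and stationarity thresholds, valid-day /
valid-subject rules, the ENMO->VO2 power law, the MET denominator and the
MET intensity cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the accelerometry -> activity-metric pipeline.

    Attributes
    ----------
    epoch_length_s:
        Aggregation epoch, seconds. Epoch ENMO is the arithmetic mean of
        sample ENMO over the epoch.
    nonwear_window_min, nonwear_step_min:
        Sliding-window geometry of the non-wear detector (window length and
        step, minutes). The window must be a multiple of the step.
    nonwear_sd_threshold_mg, nonwear_range_threshold_mg:
        Per-axis stationarity thresholds (milli-g): an axis is stationary in
        a window when its sample SD is below the first OR its range is below
        the second; a window is non-wear when >= 2 of 3 axes are stationary.
    min_wear_min_per_day:
        Minimum wear minutes for a valid calendar day (600 = 10 h, inclusive).
    min_valid_days:
        Minimum valid days for a valid subject (inclusive).
    vo2_coef, vo2_exp, vo2_floor:
        VO2 = max(vo2_floor, vo2_coef * ENMO_mg ** vo2_exp), ml.kg-1.min-1.
    met_denominator:
        MET = VO2 / met_denominator (3.5 ml.kg-1.min-1 per MET).
    cutpoints:
        MET intensity cut-points (sedentary/light, light/moderate,
        moderate/vigorous). Boundary handling: MET <= 1.5 sedentary,
        1.5 < MET < 3 light, 3 <= MET < 6 moderate, MET >= 6 vigorous.
    autocalibrate:
        Gravity auto-calibration hook; only ``"none"`` is implemented (the
        synthetic signals are calibrated by construction) and the value is
        recorded for auditability.
    """

    epoch_length_s: int = 60
    nonwear_window_min: int = 60
    nonwear_step_min: int = 15
    nonwear_sd_threshold_mg: float = 13.0
    nonwear_range_threshold_mg: float = 50.0
    min_wear_min_per_day: float = 600.0
    min_valid_days: int = 4
    vo2_coef: float = 0.901
    vo2_exp: float = 0.534
    vo2_floor: float = 3.0
    met_denominator: float = 3.5
    cutpoints: tuple[float, float, float] = (1.5, 3.0, 6.0)
    autocalibrate: str = "none"

    def __post_init__(self) -> None:
        numeric = (
            self.epoch_length_s, self.nonwear_window_min, self.nonwear_step_min,
            self.nonwear_sd_threshold_mg, self.nonwear_range_threshold_mg,
            self.min_wear_min_per_day, self.min_valid_days,
            self.vo2_coef, self.vo2_exp, self.vo2_floor, self.met_denominator,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all pipeline constants must be positive")
        if list(self.cutpoints) != sorted(self.cutpoints) or len(set(self.cutpoints)) != 3:
            raise ValueError("cutpoints must be strictly increasing")
        if self.nonwear_window_min % self.nonwear_step_min != 0:
            raise ValueError("nonwear_window_min must be a multiple of nonwear_step_min")
        if self.autocalibrate != "none":
            raise ValueError("only autocalibrate='none' is implemented")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cutpoints"] = list(self.cutpoints)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "cutpoints" in d:
            d["cutpoints"] = tuple(d["cutpoints"])
        return cls(**d)


DEFAULT_CONFIG = PipelineConfig()

CATEGORIES = ("sedentary", "light", "moderate", "vigorous")
"""Intensity categories in increasing order of energy expenditure."""
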