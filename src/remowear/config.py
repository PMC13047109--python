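"""Run configuration: every tunable of every stage, with documented defaults.

Defaults equal the values used throughout the library; the config
round-trips losslessly through YAML and hashes stably for run
manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class CalibrationConfig(BaseModel):
    stationary_sd_threshold_g: float = 0.013
    stationary_window_s: int = 10
    stationary_min_duration_s: float = 60.0
    default_bias_g: float = 0.0
    default_noise_floor_g: float = 0.013
    default_sigma_bar_sq: float = 0.013**2


class WearConfig(BaseModel):
    sd_threshold_g: float = 0.013
    min_window_min: int = 90
    min_axes: int = 2
    pad_min: int = 15
    subblock_min: int = 30


class StepConfig(BaseModel):
    window_len_s: float = 5.0
    moving_sd_threshold_g: float = 0.030
    band_low_hz: float = 0.6
    band_high_hz: float = 2.5
    band_frac: float = 0.5
    amp_floor_g: float = 0.050
    amp_rms_factor: float = 0.6
    min_run: int = 4
    interval_min_s: float = 0.33
    interval_max_s: float = 1.67
    max_interval_spread_s: float = 0.35
    resample: bool = False


class MetricsConfig(BaseModel):
    lwb_gap_s: float = 3.0
    lwb_cap_s: float = 7200.0
    max_nonwear_h: float = 1.5
    min_steps: int = 300
    day_start_hour: int = 7
    day_end_hour: int = 19
    aind_min_coverage: float = 0.5


class PromptConfig(BaseModel):
    p_random_watch: float = 0.5
    srh_gap_min_days: int = 5
    srh_gap_max_days: int = 9
    followup_days: int = 3
    expiry_h: int = 48
    reminder_h: int = 24
    scale_period_days: int = 7
    scale_reminders: bool = True
    horizon_days: int = 84


class ReportConfig(BaseModel):
    block_days: int = 28
    engagement_threshold: float = 0.5
    min_participants: int = 6
    rounding: str = "half_up"


class RunConfig(BaseModel):
    seed: int = 0
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    wear: WearConfig = Field(default_factory=WearConfig)
    steps: StepConfig = Field(default_factory=StepConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    prompts: PromptConfig = Field(default_factory=PromptConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
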