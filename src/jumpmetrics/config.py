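"""Analysis configuration: every detection threshold in one serializable place.

The defaults are the study conventions: 0.5 s body-weight window, onset at
5 resting SD with a 30 ms back-off, 20 N take-off/landing threshold, 0.5 N
resting-sd floor, g = 9.81 m/s^2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .analysis import JumpAnalyzer
from .errors import SpecificationError


@dataclass
class AnalysisConfig:
    bw_window_s: float = 0.5
    onset_sd_mult: float = 5.0
    onset_backoff_s: float = 0.030
    takeoff_threshold_n: float = 20.0
    sd_floor_n: float = 0.5
    lowpass_hz: float | None = None
    g: float = 9.81
    icc_form: str = "single"          # "single" (ICC(2,1)) or "average" (ICC(2,k))
    bonferroni_m: int = 10            # 5 metrics x 2 jump types
    entry_alpha: float = 0.05         # stepwise entry
    removal_alpha: float = 0.10       # stepwise removal
    collinearity_r_max: float = 0.9

    def __post_init__(self) -> None:
        positive = (
            "bw_window_s", "onset_sd_mult", "onset_backoff_s",
            "takeoff_threshold_n", "sd_floor_n", "g",
            "bonferroni_m", "entry_alpha", "removal_alpha", "collinearity_r_max",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise SpecificationError(f"config field {name} must be positive")
        if self.icc_form not in ("single", "average"):
            raise SpecificationError("icc_form must be 'single' or 'average'")

    def analyzer(self) -> JumpAnalyzer:
        return JumpAnalyzer(
            bw_window_s=self.bw_window_s,
            onset_sd_mult=self.onset_sd_mult,
            onset_backoff_s=self.onset_backoff_s,
            takeoff_threshold_n=self.takeoff_threshold_n,
            sd_floor_n=self.sd_floor_n,
            lowpass_hz=self.lowpass_hz,
            g=self.g,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def read(cls, path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
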