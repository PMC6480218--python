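"""Algorithm configuration.

Every tunable of the segmentation pipeline lives in :class:`AlgorithmConfig`.
Defaults reproduce the published method: an order-5 moving-average smoother,
a 0.05 normalized slope-stop threshold stepped in 0.1-s strides for the
stand/sit search, and a 10-sample sliding window with 0.02 / 0.9 mean levels
for the turn search, all defined at a 100-Hz sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from .errors import ConfigError


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the TUG segmentation pipeline.

    Parameters
    ----------
    smooth_order_n:
        Order ``N`` of the causal-forward moving-average smoother (samples).
    slope_stop_threshold:
        Normalized-amplitude difference below which the outward walk from a
        posture peak stops; defines the stand/sit start and end.
    slope_stride:
        Stride of that walk, in seconds (0.1 s = 10 samples at 100 Hz).
    turn_window:
        Length of the sliding window used by the turn-bound search, samples.
    turn_low_level, turn_high_level:
        Window-mean levels (on the normalized yaw) at which the turn-bound
        search stops: the turn starts where the signal leaves the low plateau
        (mean <= ``turn_low_level``) and ends where it reaches the high
        plateau (mean >= ``turn_high_level``).
    baseline_window:
        Seconds of initial quiet stance whose median is subtracted when
        zero-referencing an angle channel.
    peak_min_separation:
        Minimum separation between the stand and sit pitch peaks, seconds.
    step_min_prominence:
        Minimum prominence (m/s^2) of a vertical-acceleration peak counted
        as a step.
    step_min_distance:
        Minimum separation between counted steps, seconds.
    risk_thresholds:
        ``(no/low, low/high)`` boundaries on total test time, seconds.
    target_fs:
        Sampling rate every recording is resampled to before processing, Hz.
    invert_pitch, invert_yaw:
        Sign flips for upside-down sensor mounting.
    robust_turns:
        Use the plateau-adaptive turn search instead of the literal fixed
        0.02/0.9 levels (handles both turns rotating the same direction).
    """

    smooth_order_n: int = 5
    slope_stop_threshold: float = 0.05
    slope_stride: float = 0.1
    turn_window: int = 10
    turn_low_level: float = 0.02
    turn_high_level: float = 0.9
    baseline_window: float = 0.5
    peak_min_separation: float = 3.0
    step_min_prominence: float = 1.0
    step_min_distance: float = 0.3
    risk_thresholds: tuple[float, float] = (10.0, 20.0)
    target_fs: float = 100.0
    invert_pitch: bool = False
    invert_yaw: bool = False
    robust_turns: bool = False

    def __post_init__(self) -> None:
        if self.smooth_order_n < 1:
            raise ConfigError("smooth_order_n must be >= 1")
        if not (0.0 < self.turn_low_level < self.turn_high_level < 1.0):
            raise ConfigError("require 0 < turn_low_level < turn_high_level < 1")
        if self.slope_stride <= 0:
            raise ConfigError("slope_stride must be positive")
        if self.turn_window < 1:
            raise ConfigError("turn_window must be >= 1")
        if self.target_fs <= 0:
            raise ConfigError("target_fs must be positive")
        if len(self.risk_thresholds) != 2 or not (
            self.risk_thresholds[0] < self.risk_thresholds[1]
        ):
            raise ConfigError("risk_thresholds must be two strictly increasing values")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["risk_thresholds"] = list(self.risk_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AlgorithmConfig":
        d = dict(d)
        if "risk_thresholds" in d:
            d["risk_thresholds"] = tuple(d["risk_thresholds"])
        return cls(**d)


DEFAULT_CONFIG = AlgorithmConfig()
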