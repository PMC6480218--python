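"""Turn detection from the conditioned heading (yaw) signal.

Both TUG turns rotate the subject by roughly 180 degrees, so the oriented,
normalized yaw is a staircase: low plateau, rising transition at the 3-m
turn, high plateau, falling transition at the pre-sitting turn, low plateau.
The transition midpoints are located as the extrema of the yaw rate (the
rising turn at the rate maximum, the falling turn at the minimum); the turn
bounds are then found by sliding a 10-sample window outward from each
extremum one sample at a time until its mean reaches the flanking plateau
criterion: 0.02 (low side) or 0.9 (high side) in normalized units.

The literal method assumes the two turns rotate in opposite directions
(rate extrema of opposite sign).  Subjects who turn the same way twice
(heading 0 -> 180 -> 360) break that assumption; ``robust_turns`` instead
takes the two largest disjoint rate excursions and rescales the 2% / 90%
levels to the span between each turn's own flanking plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .errors import ConsistencyError, DetectionError
from .preprocessing import ConditionedSignal

__all__ = ["TurnEvent", "yaw_rate", "locate_turn_extrema",
           "window_search_turn_bounds", "detect_turns"]


@dataclass
class TurnEvent:
    """One turning action: bounds, rate-extremum time, rotation span."""

    which: str  # "turn1_3m" | "turn2_presit"
    t_start: float
    t_end: float
    t_extremum: float
    rotation_span: float  # degrees, on the unwrapped un-normalized heading
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_extremum < self.t_end):
            raise ConsistencyError(
                f"{self.which} bounds not ordered around extremum: "
                f"{self.t_start} < {self.t_extremum} < {self.t_end} fails")
        if not (90.0 < self.rotation_span < 270.0):
            self.flags.append("rotation-span-outside-90-270")


def yaw_rate(yaw_norm: ConditionedSignal) -> np.ndarray:
    """First derivative of the normalized yaw, in normalized units per second.

    Central differences in the interior, one-sided at the edges; same length
    as the input.
    """
    return np.gradient(yaw_norm.values, 1.0 / yaw_norm.fs)


def locate_turn_extrema(rate: np.ndarray, fs: float, t0: float = 0.0
                        ) -> tuple[float, float]:
    """Times of the rate maximum (first turn) and minimum (second turn).

    The rising 3-m turn must precede the falling pre-sitting turn; if the
    minimum comes first the opposite-direction assumption is violated.
    """
    i_max = int(np.argmax(rate))
    i_min = int(np.argmin(rate))
    if i_max >= i_min:
        raise DetectionError("turn order violated: rate maximum does not "
                             "precede rate minimum", stage="turn_detector")
    return t0 + i_max / fs, t0 + i_min / fs


def _window_bounds(x: np.ndarray, t: np.ndarray, center: int, w: int,
                   rising: bool, lo_level: float, hi_level: float
                   ) -> tuple[float, float, list[str]]:
    """Slide ``w``-sample windows outward from ``center`` until the mean
    criteria fire.  ``rising`` selects the transition polarity: for a rising
    transition the left side seeks the low plateau and the right side the
    high plateau; mirrored for a falling one.
    """
    n = x.size
    flags: list[str] = []

    def left_stop(mean: float) -> bool:
        return mean <= lo_level if rising else mean >= hi_level

    def right_stop(mean: float) -> bool:
        return mean >= hi_level if rising else mean <= lo_level

    lo_idx = 0
    found = False
    for i in range(center - w + 1):
        a, b = center - w - i, center - i
        if a < 0:
            break
        if left_stop(float(np.mean(x[a:b + 1]))):
            lo_idx, found = a, True
            break
    if not found:
        flags.append("start-clamped-to-edge")

    hi_idx = n - 1
    found = False
    for i in range(n - center - w):
        a, b = center + i, center + w + i
        if b > n - 1:
            break
        if right_stop(float(np.mean(x[a:b + 1]))):
            hi_idx, found = b, True
            break
    if not found:
        flags.append("end-clamped-to-edge")
    return float(t[lo_idx]), float(t[hi_idx]), flags


def window_search_turn_bounds(yaw_norm: ConditionedSignal, t_extremum: float,
                              which: str,
                              config: AlgorithmConfig = DEFAULT_CONFIG
                              ) -> tuple[float, float, list[str]]:
    """Literal turn-bound search at the fixed 0.02 / 0.9 window-mean levels.

    ``which`` selects the polarity: ``"turn1_3m"`` is the rising transition,
    ``"turn2_presit"`` the falling one.
    """
    rising = which == "turn1_3m"
    return _window_bounds(yaw_norm.values, yaw_norm.t,
                          yaw_norm.index_at(t_extremum), config.turn_window,
                          rising, config.turn_low_level, config.turn_high_level)


def _robust_extrema(rate: np.ndarray, fs: float, t0: float
                    ) -> list[tuple[int, bool]]:
    """Two largest disjoint |rate| excursions, as (index, rising) in time order."""
    a = np.abs(rate)
    i1 = int(np.argmax(a))
    # Mask the contiguous excursion around i1 (down to 10% of its peak).
    thr = 0.1 * a[i1]
    lo = i1
    while lo > 0 and a[lo - 1] > thr:
        lo -= 1
    hi = i1
    while hi < a.size - 1 and a[hi + 1] > thr:
        hi += 1
    masked = a.copy()
    masked[lo:hi + 1] = 0.0
    if not np.any(masked > 0):
        raise DetectionError("only one rate excursion found",
                             stage="turn_detector")
    i2 = int(np.argmax(masked))
    pair = sorted([(i1, rate[i1] > 0), (i2, rate[i2] > 0)])
    return pair


def _local_plateaus(x: np.ndarray, rate: np.ndarray, center: int, fs: float
                    ) -> tuple[float, float]:
    """Median signal level on the quiet flanks of one rate excursion."""
    thr = 0.05 * abs(rate[center])
    k = center
    while k > 0 and abs(rate[k]) > thr:
        k -= 1
    left = float(np.median(x[max(0, k - int(0.5 * fs)):k + 1]))
    k = center
    while k < x.size - 1 and abs(rate[k]) > thr:
        k += 1
    right = float(np.median(x[k:k + int(0.5 * fs) + 1]))
    return left, right


def _rotation_span(yaw_norm: ConditionedSignal, t_start: float, t_end: float
                   ) -> float:
    src = yaw_norm.source
    if src is None:
        src = yaw_norm.values * (yaw_norm.scale if yaw_norm.scale else 1.0)
    return float(abs(src[yaw_norm.index_at(t_end)] -
                     src[yaw_norm.index_at(t_start)]))


def detect_turns(yaw_norm: ConditionedSignal,
                 config: AlgorithmConfig = DEFAULT_CONFIG
                 ) -> tuple[TurnEvent, TurnEvent]:
    """Detect the 3-m turn and the pre-sitting turn."""
    rate = yaw_rate(yaw_norm)
    events: list[TurnEvent] = []
    if not config.robust_turns:
        t_max, t_min = locate_turn_extrema(rate, yaw_norm.fs, float(yaw_norm.t[0]))
        for which, t_ext in (("turn1_3m", t_max), ("turn2_presit", t_min)):
            lo, hi, flags = window_search_turn_bounds(yaw_norm, t_ext, which, config)
            events.append(TurnEvent(
                which=which, t_start=lo, t_end=hi, t_extremum=t_ext,
                rotation_span=_rotation_span(yaw_norm, lo, hi), flags=flags))
    else:
        pair = _robust_extrema(rate, yaw_norm.fs, float(yaw_norm.t[0]))
        for (center, rising), which in zip(pair, ("turn1_3m", "turn2_presit")):
            pl, pr = _local_plateaus(yaw_norm.values, rate, center, yaw_norm.fs)
            low, high = min(pl, pr), max(pl, pr)
            span = high - low
            if span <= 0:
                raise DetectionError("flat plateaus around rate excursion",
                                     stage="turn_detector")
            lo, hi, flags = _window_bounds(
                yaw_norm.values, yaw_norm.t, center, config.turn_window,
                rising, low + config.turn_low_level * span,
                low + config.turn_high_level * span)
            flags.append("robust-mode")
            events.append(TurnEvent(
                which=which, t_start=lo, t_end=hi,
                t_extremum=float(yaw_norm.t[center]),
                rotation_span=_rotation_span(yaw_norm, lo, hi), flags=flags))
    turn1, turn2 = events
    if turn1.t_end > turn2.t_start:
        raise ConsistencyError(
            f"3-m turn ends at {turn1.t_end:.2f}s after pre-sitting turn "
            f"starts at {turn2.t_start:.2f}s")
    return turn1, turn2
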