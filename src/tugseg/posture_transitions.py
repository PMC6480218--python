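"""Stand-up and sit-down detection from the conditioned pitch signal.

Rising from or lowering into a chair produces a forward trunk-lean bump in
the sagittal inclination: the normalized pitch therefore shows two dominant
local maxima, one at the stand-up and one at the sit-down.  From each peak
the start and end of the transition are found by walking outward in fixed
strides until the local slope flattens: the walk stops at the first stride
where the absolute difference between samples one stride apart falls below
the slope-stop threshold (0.05 in normalized units over 0.1 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .errors import ConsistencyError, DetectionError
from .preprocessing import ConditionedSignal

__all__ = ["TransitionEvent", "find_posture_peaks", "slope_search_bounds",
           "detect_stand_sit"]

#: Minimum normalized prominence for a pitch peak to qualify as a posture
#: transition; rejects gait oscillations and noise while accepting the
#: smaller of the two bumps even when the amplitudes differ substantially.
MIN_PEAK_PROMINENCE = 0.1


@dataclass
class TransitionEvent:
    """A stand-up or sit-down: peak time plus start/end bounds, seconds."""

    kind: str  # "standing" | "sitting"
    t_peak: float
    t_start: float
    t_end: float
    peak_value: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_peak < self.t_end):
            raise ConsistencyError(
                f"{self.kind} event bounds not ordered: "
                f"{self.t_start} < {self.t_peak} < {self.t_end} fails")


def find_posture_peaks(pitch_norm: ConditionedSignal,
                       min_separation: float = 3.0) -> tuple[float, float]:
    """Locate the stand and sit peaks of the normalized pitch.

    Returns the times of the two most prominent local maxima at least
    ``min_separation`` seconds apart, ordered in time (stand first).
    """
    x = pitch_norm.values
    if x.size <= 2 * min_separation * pitch_norm.fs:
        raise DetectionError("recording too short for two posture peaks",
                             stage="posture_transitions")
    distance = max(1, int(round(min_separation * pitch_norm.fs)))
    idx, props = find_peaks(x, distance=distance, prominence=MIN_PEAK_PROMINENCE)
    if idx.size < 2:
        raise DetectionError("posture peaks not found", stage="posture_transitions")
    top2 = idx[np.argsort(props["prominences"])[-2:]]
    t1, t2 = sorted(pitch_norm.t[top2])
    return float(t1), float(t2)


def slope_search_bounds(pitch_norm: ConditionedSignal, t_peak: float,
                        threshold: float = 0.05, stride: float = 0.1
                        ) -> tuple[float, float, list[str]]:
    """Walk outward from a posture peak until the slope flattens.

    Leftward: the start is the first position ``t_peak - i`` (``i`` a
    multiple of ``stride``) where ``|x(t - stride) - x(t)| < threshold``;
    rightward symmetrically for the end.  Bounds are clamped to the
    recording edges (with a flag) if the criterion never fires.
    """
    x = pitch_norm.values
    fs = pitch_norm.fs
    n = x.size
    step = max(1, int(round(stride * fs)))
    p = pitch_norm.index_at(t_peak)
    flags: list[str] = []

    k = p
    t_start = pitch_norm.t[0]
    clamped = True
    while k - step >= 0:
        if abs(x[k - step] - x[k]) < threshold:
            t_start = pitch_norm.t[k]
            clamped = False
            break
        k -= step
    if clamped:
        flags.append("start-clamped-to-edge")

    k = p
    t_end = pitch_norm.t[-1]
    clamped = True
    while k + step <= n - 1:
        if abs(x[k + step] - x[k]) < threshold:
            t_end = pitch_norm.t[k]
            clamped = False
            break
        k += step
    if clamped:
        flags.append("end-clamped-to-edge")
    return float(t_start), float(t_end), flags


def detect_stand_sit(pitch_norm: ConditionedSignal,
                     config: AlgorithmConfig = DEFAULT_CONFIG
                     ) -> tuple[TransitionEvent, TransitionEvent]:
    """Detect the standing and sitting events on the conditioned pitch."""
    t1, t2 = find_posture_peaks(pitch_norm, config.peak_min_separation)
    events = []
    for kind, tp in (("standing", t1), ("sitting", t2)):
        lo, hi, flags = slope_search_bounds(
            pitch_norm, tp, config.slope_stop_threshold, config.slope_stride)
        # The stride walk can stop at the peak itself on very shallow bumps;
        # widen by one sample so the event interval is non-degenerate.
        if lo >= tp:
            lo = tp - 1.0 / pitch_norm.fs
            flags.append("start-collapsed-to-peak")
        if hi <= tp:
            hi = tp + 1.0 / pitch_norm.fs
            flags.append("end-collapsed-to-peak")
        peak_val = float(pitch_norm.values[pitch_norm.index_at(tp)])
        events.append(TransitionEvent(kind=kind, t_peak=tp, t_start=lo,
                                      t_end=hi, peak_value=peak_val, flags=flags))
    standing, sitting = events
    if standing.t_end > sitting.t_start:
        raise ConsistencyError(
            f"standing ends at {standing.t_end:.2f}s after sitting starts "
            f"at {sitting.t_start:.2f}s")
    return standing, sitting
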