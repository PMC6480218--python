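"""End-to-end TUG analysis: segmentation assembly, features, fall risk.

The four detected events (stand-up, 3-m turn, pre-sitting turn, sit-down)
tile the recording into the six TUG sub-tasks: standing, first walk, 3-m
turn, second walk, pre-sitting turn and sitting.  The walks are the spans
between consecutive events; any gap between the end of the pre-sitting turn
and the start of sitting is kept as an explicit labeled "pre-sit stance"
rather than forced to zero, so total test time depends only on the first
and last event bounds.

Per-sub-task mobility features follow the clinical variable set: peak
vertical accelerations at stand-up/sit-down, peak rotation rates in each
turn, step counts per walking/turning segment, and trunk-inclination
excursions, plus all six durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import find_peaks

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .errors import ConfigError, ConsistencyError
from .posture_transitions import TransitionEvent, detect_stand_sit
from .preprocessing import condition_pitch, condition_yaw, unwrap_heading
from .signal_model import ImuRecording
from .turn_detector import TurnEvent, detect_turns

__all__ = ["Interval", "TugSegmentation", "SubTaskFeatures", "RiskAssessment",
           "assemble_segments", "count_steps", "extract_features",
           "classify_risk", "run_pipeline", "annotate_samples"]

#: Events may overlap by up to this much (seconds) and still be resolved at
#: the midpoint rather than rejected.
ORDER_TOLERANCE = 0.2

SUBTASK_NAMES = ("standing", "first_walk", "turn_3m", "second_walk",
                 "presit_turn", "sitting")


@dataclass
class Interval:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_list(self) -> list[float]:
        return [self.start, self.end]


@dataclass
class TugSegmentation:
    """The six labeled sub-task intervals plus total test time (seconds)."""

    standing: Interval
    first_walk: Interval
    turn_3m: Interval
    second_walk: Interval
    presit_turn: Interval
    sitting: Interval
    presit_gap: Interval | None = None
    total_time: float = 0.0
    flags: list[str] = field(default_factory=list)

    def intervals(self) -> dict[str, Interval]:
        return {name: getattr(self, name) for name in SUBTASK_NAMES}

    def durations(self) -> dict[str, float]:
        return {name: iv.duration for name, iv in self.intervals().items()}

    def boundary_times(self) -> dict[str, float]:
        """The 8 detector-owned boundary times."""
        return {
            "standing_start": self.standing.start,
            "standing_end": self.standing.end,
            "turn1_start": self.turn_3m.start,
            "turn1_end": self.turn_3m.end,
            "turn2_start": self.presit_turn.start,
            "turn2_end": self.presit_turn.end,
            "sitting_start": self.sitting.start,
            "sitting_end": self.sitting.end,
        }

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {name: iv.to_list() for name, iv in self.intervals().items()}
        d["presit_gap"] = self.presit_gap.to_list() if self.presit_gap else None
        d["durations"] = self.durations()
        d["total_time"] = self.total_time
        d["flags"] = sorted(self.flags)
        return d


@dataclass
class SubTaskFeatures:
    """Clinical variable set extracted per sub-task.

    ``None`` marks a feature whose source channel is absent from the
    recording (reported as absent, never as zero).
    """

    durations: dict[str, float]
    acc_su: float | None = None
    acc_sd: float | None = None
    vel_t1: float | None = None
    vel_t2: float | None = None
    steps_w1: int | None = None
    steps_w2: int | None = None
    steps_t1: int | None = None
    steps_t2: int | None = None
    pitch_su: float | None = None
    pitch_sd: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "durations": dict(self.durations),
            "acc_su": self.acc_su, "acc_sd": self.acc_sd,
            "vel_t1": self.vel_t1, "vel_t2": self.vel_t2,
            "steps_w1": self.steps_w1, "steps_w2": self.steps_w2,
            "steps_t1": self.steps_t1, "steps_t2": self.steps_t2,
            "pitch_su": self.pitch_su, "pitch_sd": self.pitch_sd,
            "flags": sorted(self.flags),
        }


@dataclass
class RiskAssessment:
    """Fall-risk category from total test time against configurable cutoffs."""

    category: str  # "no" | "low" | "high"
    total_time: float
    thresholds_used: tuple[float, float]

    def to_dict(self) -> dict[str, Any]:
        return {"category": self.category, "total_time": self.total_time,
                "thresholds_used": list(self.thresholds_used)}


def _resolve_boundary(earlier_end: float, later_start: float, label: str,
                      flags: list[str]) -> tuple[float, float]:
    """Snap small overlaps between adjacent events to the midpoint."""
    if earlier_end <= later_start:
        return earlier_end, later_start
    overlap = earlier_end - later_start
    if overlap > ORDER_TOLERANCE:
        raise ConsistencyError(
            f"events overlap by {overlap:.2f}s at {label} "
            f"(> {ORDER_TOLERANCE}s tolerance)")
    mid = 0.5 * (earlier_end + later_start)
    flags.append(f"overlap-snapped:{label}")
    return mid, mid


def assemble_segments(standing: TransitionEvent, sitting: TransitionEvent,
                      turn1: TurnEvent, turn2: TurnEvent) -> TugSegmentation:
    """Tile the six sub-tasks from the four detected events.

    The walks fill the spans between consecutive events; overlaps within
    tolerance are snapped to the midpoint (flagged), larger ones raise.
    Total time runs from the start of standing to the end of sitting.
    """
    flags: list[str] = list(standing.flags) + list(sitting.flags) \
        + list(turn1.flags) + list(turn2.flags)
    st_end, t1_start = _resolve_boundary(standing.t_end, turn1.t_start,
                                         "standing/turn1", flags)
    t1_end, t2_start = _resolve_boundary(turn1.t_end, turn2.t_start,
                                         "turn1/turn2", flags)
    t2_end, sit_start = _resolve_boundary(turn2.t_end, sitting.t_start,
                                          "turn2/sitting", flags)
    if standing.t_start >= st_end or sit_start >= sitting.t_end:
        raise ConsistencyError("degenerate standing or sitting interval")

    seg = TugSegmentation(
        standing=Interval(standing.t_start, st_end),
        first_walk=Interval(st_end, t1_start),
        turn_3m=Interval(t1_start, t1_end),
        second_walk=Interval(t1_end, t2_start),
        presit_turn=Interval(t2_start, t2_end),
        sitting=Interval(sit_start, sitting.t_end),
        presit_gap=Interval(t2_end, sit_start) if sit_start > t2_end else None,
        total_time=sitting.t_end - standing.t_start,
        flags=flags,
    )
    if seg.presit_gap is not None:
        seg.flags.append("pre-sit stance gap retained")
    return seg


def count_steps(acc_z: np.ndarray, fs: float,
                config: AlgorithmConfig = DEFAULT_CONFIG) -> int:
    """Count steps as prominent peaks of the detrended vertical acceleration.

    The segment median (gravity) is subtracted; peaks must exceed
    ``step_min_prominence`` and be at least ``step_min_distance`` apart.
    Short or empty segments count zero.
    """
    acc_z = np.asarray(acc_z, dtype=float)
    if acc_z.size < 2:
        return 0
    detrended = acc_z - np.median(acc_z)
    distance = max(1, int(round(config.step_min_distance * fs)))
    idx, _ = find_peaks(detrended, prominence=config.step_min_prominence,
                        distance=distance)
    return int(idx.size)


def _segment_slice(rec: ImuRecording, iv: Interval) -> slice:
    return slice(rec.index_at(iv.start), rec.index_at(iv.end) + 1)


def extract_features(recording: ImuRecording, seg: TugSegmentation,
                     config: AlgorithmConfig = DEFAULT_CONFIG) -> SubTaskFeatures:
    """Extract the per-sub-task mobility variables from a segmentation."""
    feats = SubTaskFeatures(durations=seg.durations())

    if recording.acc_z is not None:
        for name, attr in (("standing", "acc_su"), ("sitting", "acc_sd")):
            s = _segment_slice(recording, getattr(seg, name))
            acc = recording.acc_z[s]
            if acc.size:
                setattr(feats, attr, float(np.max(np.abs(acc - np.median(acc)))))
        for name, attr in (("first_walk", "steps_w1"), ("second_walk", "steps_w2"),
                           ("turn_3m", "steps_t1"), ("presit_turn", "steps_t2")):
            s = _segment_slice(recording, getattr(seg, name))
            setattr(feats, attr, count_steps(recording.acc_z[s], recording.fs,
                                             config))
    else:
        feats.flags.append("acc_z-absent")

    if recording.gyr_z is not None:
        turn_rate = np.abs(recording.gyr_z)
    else:
        yaw_cont = unwrap_heading(recording.yaw)
        turn_rate = np.abs(np.gradient(yaw_cont, 1.0 / recording.fs))
        feats.flags.append("turn-rate-derived-from-yaw")
    for name, attr in (("turn_3m", "vel_t1"), ("presit_turn", "vel_t2")):
        s = _segment_slice(recording, getattr(seg, name))
        rate = turn_rate[s]
        if rate.size:
            setattr(feats, attr, float(np.max(rate)))

    baseline_k = max(1, int(round(config.baseline_window * recording.fs)))
    pitch0 = np.median(recording.pitch[:baseline_k])
    for name, attr in (("standing", "pitch_su"), ("sitting", "pitch_sd")):
        s = _segment_slice(recording, getattr(seg, name))
        p = recording.pitch[s]
        if p.size:
            setattr(feats, attr, float(np.max(np.abs(p - pitch0))))
    return feats


def classify_risk(total_time: float,
                  thresholds: tuple[float, float] = (10.0, 20.0)
                  ) -> RiskAssessment:
    """Categorize fall risk from total test time.

    ``no`` below the first cutoff, ``low`` between the cutoffs (inclusive),
    ``high`` above the second.  Cutoffs are configurable because published
    bands differ between health systems and age groups.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ConfigError("risk thresholds must be strictly increasing")
    if total_time < lo:
        category = "no"
    elif total_time <= hi:
        category = "low"
    else:
        category = "high"
    return RiskAssessment(category=category, total_time=total_time,
                          thresholds_used=(float(lo), float(hi)))


def run_pipeline(recording: ImuRecording,
                 config: AlgorithmConfig = DEFAULT_CONFIG
                 ) -> tuple[TugSegmentation, SubTaskFeatures, RiskAssessment]:
    """Full analysis: conditioning, detection, assembly, features, risk.

    Deterministic for a fixed recording and configuration.
    """
    pitch_norm = condition_pitch(recording, config)
    yaw_norm = condition_yaw(recording, config)
    standing, sitting = detect_stand_sit(pitch_norm, config)
    turn1, turn2 = detect_turns(yaw_norm, config)
    seg = assemble_segments(standing, sitting, turn1, turn2)
    seg.flags.extend(pitch_norm.flags + yaw_norm.flags)
    features = extract_features(recording, seg, config)
    risk = classify_risk(seg.total_time, config.risk_thresholds)
    return seg, features, risk


def annotate_samples(recording: ImuRecording, seg: TugSegmentation) -> "np.ndarray":
    """Per-sample sub-task labels ('' outside the test) as an object array."""
    labels = np.full(recording.n_samples, "", dtype=object)
    for name, iv in seg.intervals().items():
        labels[_segment_slice(recording, iv)] = name
    if seg.presit_gap is not None:
        labels[_segment_slice(recording, seg.presit_gap)] = "presit_stance"
    return labels
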