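"""Signal conditioning for the orientation channels.

The segmentation operates on conditioned versions of the trunk inclination
(pitch) and heading (yaw): smoothed by a causal forward moving average of
order N and normalized by the absolute maximum, so that thresholds are
dimensionless fractions of the largest excursion.  Raw sensor angles also
need hygiene the detector thresholds implicitly assume: heading must be
unwrapped across the +/-180 deg seam, both angles zero-referenced to the
initial quiet stance, and the yaw oriented so the first turn is a positive
rotation.

Fixed processing order
----------------------
pitch: ``zero_reference -> moving_average -> normalize_abs_max``
yaw:   ``unwrap_heading -> zero_reference -> orient_turn_sign ->
moving_average -> normalize_abs_max``

Each later step assumes the earlier one's contract; ``condition_pitch`` /
``condition_yaw`` apply the chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .signal_model import ImuRecording

__all__ = [
    "ConditionedSignal",
    "moving_average",
    "normalize_abs_max",
    "unwrap_heading",
    "zero_reference",
    "orient_turn_sign",
    "condition_pitch",
    "condition_yaw",
]


@dataclass
class ConditionedSignal:
    """A smoothed, normalized angle signal plus the bookkeeping to undo it.

    ``values`` are dimensionless in [-1, 1] with ``max |values| = 1`` unless
    the signal is degenerate (identically zero -> ``degenerate`` flag).
    ``scale`` is the absolute maximum (degrees) divided out, ``baseline`` the
    degrees subtracted beforehand, ``sign`` the orientation flip applied
    (+1/-1), and ``source`` the unwrapped, zero-referenced signal in degrees
    (before sign flip, smoothing and normalization) for span measurements.
    """

    values: np.ndarray
    t: np.ndarray
    fs: float
    scale: float
    baseline: float
    sign: float = 1.0
    degenerate: bool = False
    source: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def index_at(self, time_s: float) -> int:
        i = int(round((time_s - self.t[0]) * self.fs))
        return min(max(i, 0), self.n - 1)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Causal-forward moving average of order ``n``.

    ``y[k] = mean(x[k .. k+n-1])`` for ``k <= len(x) - n``; the final
    ``n - 1`` samples average the shrinking tail window ``x[k..end]`` so the
    output has the same length as the input and event indices map 1:1.
    """
    x = np.asarray(x, dtype=float)
    if n < 1:
        raise ValueError("moving-average order must be >= 1")
    if x.size < n:
        raise ValueError(f"signal length {x.size} shorter than filter order {n}")
    c = np.concatenate(([0.0], np.cumsum(x)))
    m = x.size
    y = np.empty(m)
    head = m - n + 1
    y[:head] = (c[n:] - c[:head]) / n
    for k in range(head, m):
        y[k] = (c[m] - c[k]) / (m - k)
    return y


def normalize_abs_max(x: np.ndarray, t: np.ndarray | None = None,
                      fs: float = 100.0) -> ConditionedSignal:
    """Normalize by the absolute maximum so the largest excursion is +/-1.

    An identically zero signal is returned unchanged with ``scale = 0`` and
    the ``degenerate`` flag set rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(x.size) / fs
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    if scale == 0.0:
        return ConditionedSignal(values=x.copy(), t=np.asarray(t, float), fs=fs,
                                 scale=0.0, baseline=0.0, degenerate=True,
                                 flags=["degenerate-signal"])
    return ConditionedSignal(values=x / scale, t=np.asarray(t, float), fs=fs,
                             scale=scale, baseline=0.0)


def unwrap_heading(yaw_deg: np.ndarray) -> np.ndarray:
    """Unwrap a heading that wraps at +/-180 deg into a continuous signal.

    Adds or subtracts multiples of 360 deg so successive differences are all
    below 180 deg in magnitude; idempotent on already-continuous signals.
    """
    return np.degrees(np.unwrap(np.radians(np.asarray(yaw_deg, dtype=float))))


def zero_reference(x: np.ndarray, fs: float, baseline_window: float = 0.5
                   ) -> tuple[np.ndarray, float]:
    """Subtract the median of the first ``baseline_window`` seconds.

    Returns ``(zeroed, baseline)``.  The initial quiet stance defines the
    resting angle; the median is robust to the odd spike within it.
    """
    x = np.asarray(x, dtype=float)
    k = max(1, min(x.size, int(round(baseline_window * fs))))
    baseline = float(np.median(x[:k]))
    return x - baseline, baseline


def orient_turn_sign(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip the zero-referenced yaw so its largest excursion is positive.

    The turn-bound equations assume the first turn rotates positively (the
    heading rises to its global maximum); subjects may turn either way.
    Returns ``(oriented, sign)`` with ``sign`` in {+1, -1}; idempotent.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy(), 1.0
    ext = x[np.argmax(np.abs(x))]
    sign = -1.0 if ext < 0 else 1.0
    return x * sign, sign


def condition_pitch(recording: ImuRecording,
                    config: AlgorithmConfig = DEFAULT_CONFIG) -> ConditionedSignal:
    """Full conditioning chain for the inclination channel."""
    zeroed, baseline = zero_reference(recording.pitch, recording.fs,
                                      config.baseline_window)
    smooth = moving_average(zeroed, config.smooth_order_n)
    out = normalize_abs_max(smooth, recording.t, recording.fs)
    out.baseline = baseline
    out.source = zeroed
    return out


def condition_yaw(recording: ImuRecording,
                  config: AlgorithmConfig = DEFAULT_CONFIG) -> ConditionedSignal:
    """Full conditioning chain for the heading channel."""
    unwrapped = unwrap_heading(recording.yaw)
    zeroed, baseline = zero_reference(unwrapped, recording.fs,
                                      config.baseline_window)
    oriented, sign = orient_turn_sign(zeroed)
    smooth = moving_average(oriented, config.smooth_order_n)
    out = normalize_abs_max(smooth, recording.t, recording.fs)
    out.baseline = baseline
    out.sign = sign
    out.source = zeroed
    if sign < 0:
        out.flags.append("yaw-mirrored")
    return out
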