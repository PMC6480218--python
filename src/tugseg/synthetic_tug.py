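"""Synthetic single-IMU TUG recordings with exact ground truth.

The generator emulates the signal morphologies a lumbar-mounted IMU shows
during the test: triangular forward-lean bumps in pitch spanning exactly the
standing and sitting intervals, cubic-smoothstep heading transitions of
~180 degrees spanning the turn intervals, step oscillations in the vertical
acceleration at the gait cadence within walking/turning segments, transient
acceleration peaks at stand-up/sit-down, and the analytic heading derivative
on the transverse gyroscope channel — all plus white Gaussian noise.

Every knot time is placed by construction, so the ground truth is exact
rather than asymptotic: smoothstep transitions have finite support (placed
on the inner 90% of each labeled turn interval so the detector's plateau
criteria fire inside it), and triangular pitch bumps have sharp, well-defined
edges and peaks.

``random_scenario`` draws scenario parameters from truncated normal
distributions whose means and SDs match the published young and older-adult
cohort statistics, giving a reproducible population to exercise the
detectors on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .signal_model import ImuRecording

__all__ = ["TugScenario", "GroundTruth", "simulate", "random_scenario"]

GRAVITY = 9.81


@dataclass
class TugScenario:
    """Parameter set for one synthetic TUG recording.

    Durations are the true sub-task lengths in seconds; angle amplitudes in
    degrees; accelerations in m/s^2; cadence in steps/s.  ``turn_direction``
    selects whether the pre-sitting turn undoes the 3-m turn ("opposite",
    heading returns to baseline — the morphology the literal detector
    assumes) or continues it ("same", heading accumulates to ~360 deg).
    ``peak_turn_rate`` (deg/s), when set, narrows each heading transition to
    ``1.5 * turn_angle / peak_turn_rate`` seconds inside the labeled
    interval; by default the transition spans the inner 90% of the interval
    and the peak rate follows from the duration.  ``seed`` fixes the entire
    noise sample path.
    """

    d_standing: float = 1.16
    d_first_walk: float = 2.51
    d_turn1: float = 1.65
    d_second_walk: float = 2.39
    d_turn2: float = 1.03
    d_sitting: float = 1.48
    d_presit_gap: float = 0.25
    lead_in: float = 1.0
    tail: float = 1.0
    pitch_amp_stand: float = 5.35
    pitch_amp_sit: float = 6.25
    turn_angle: float = 180.0
    turn_direction: str = "opposite"
    peak_turn_rate: float | None = None
    cadence: float = 1.7
    step_acc_amp: float = 2.0
    acc_amp_stand: float = 6.49
    acc_amp_sit: float = 6.09
    pitch_baseline: float = 5.0
    yaw_baseline: float = 0.0
    noise_sd_angle: float = 0.1
    noise_sd_acc: float = 0.15
    noise_sd_gyr: float = 1.0
    fs: float = 100.0
    seed: int = 0
    label: str = "default"

    def __post_init__(self) -> None:
        for name in ("d_standing", "d_first_walk", "d_turn1", "d_second_walk",
                     "d_turn2", "d_sitting"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_presit_gap < 0 or self.lead_in < 0 or self.tail < 0:
            raise ValueError("gap/lead-in/tail durations must be non-negative")
        if self.turn_direction not in ("opposite", "same"):
            raise ValueError("turn_direction must be 'opposite' or 'same'")
        if self.noise_sd_angle < 0 or self.noise_sd_acc < 0 or self.noise_sd_gyr < 0:
            raise ValueError("noise SDs must be non-negative")

    def knots(self) -> dict[str, float]:
        """Cumulative true event times, seconds from recording start."""
        t = self.lead_in
        k = {"standing_start": t}
        t += self.d_standing; k["standing_end"] = t
        t += self.d_first_walk; k["turn1_start"] = t
        t += self.d_turn1; k["turn1_end"] = t
        t += self.d_second_walk; k["turn2_start"] = t
        t += self.d_turn2; k["turn2_end"] = t
        t += self.d_presit_gap; k["sitting_start"] = t
        t += self.d_sitting; k["sitting_end"] = t
        k["recording_end"] = t + self.tail
        return k

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class GroundTruth:
    """Exact event times and signal parameters used by the generator."""

    boundaries: dict[str, float]
    steps: dict[str, int]
    peak_rate_t1: float
    peak_rate_t2: float
    pitch_amp_stand: float
    pitch_amp_sit: float
    acc_amp_stand: float
    acc_amp_sit: float
    total_time: float

    def boundary_times(self) -> dict[str, float]:
        return dict(self.boundaries)


def _triangle(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Unit triangular bump spanning [start, end], peak at the midpoint."""
    c = 0.5 * (start + end)
    half = 0.5 * (end - start)
    return np.clip(1.0 - np.abs(t - c) / half, 0.0, None)


def _smoothstep(t: np.ndarray, a: float, b: float) -> np.ndarray:
    s = np.clip((t - a) / (b - a), 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _smoothstep_rate(t: np.ndarray, a: float, b: float) -> np.ndarray:
    s = np.clip((t - a) / (b - a), 0.0, 1.0)
    return 6.0 * s * (1.0 - s) / (b - a)


def _raised_cosine(t: np.ndarray, start: float, end: float) -> np.ndarray:
    s = np.clip((t - start) / (end - start), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * s))


def _step_count(duration: float, cadence: float) -> int:
    """Number of step-oscillation peaks inside an interval of given length."""
    return int(np.floor(cadence * duration + 0.5))


def _transition_span(scn: TugScenario, start: float, end: float
                     ) -> tuple[float, float]:
    """Support of the heading transition inside a labeled turn interval."""
    d = end - start
    if scn.peak_turn_rate is not None:
        width = min(1.5 * scn.turn_angle / scn.peak_turn_rate, 0.9 * d)
    else:
        width = 0.9 * d
    c = 0.5 * (start + end)
    return c - 0.5 * width, c + 0.5 * width


def simulate(scenario: TugScenario) -> tuple[ImuRecording, GroundTruth]:
    """Generate one synthetic recording and its exact ground truth."""
    scn = scenario
    k = scn.knots()
    n = int(round(k["recording_end"] * scn.fs)) + 1
    t = np.arange(n) / scn.fs
    rng = np.random.default_rng(scn.seed)

    pitch = scn.pitch_baseline \
        + scn.pitch_amp_stand * _triangle(t, k["standing_start"], k["standing_end"]) \
        + scn.pitch_amp_sit * _triangle(t, k["sitting_start"], k["sitting_end"]) \
        + rng.normal(0.0, scn.noise_sd_angle, n)

    a1, b1 = _transition_span(scn, k["turn1_start"], k["turn1_end"])
    a2, b2 = _transition_span(scn, k["turn2_start"], k["turn2_end"])
    sign2 = 1.0 if scn.turn_direction == "same" else -1.0
    yaw_cont = scn.yaw_baseline \
        + scn.turn_angle * _smoothstep(t, a1, b1) \
        + sign2 * scn.turn_angle * _smoothstep(t, a2, b2)
    yaw = ((yaw_cont + rng.normal(0.0, scn.noise_sd_angle, n) + 180.0) % 360.0) - 180.0

    acc_z = np.full(n, GRAVITY)
    steps: dict[str, int] = {}
    for name, (lo, hi) in (("w1", (k["standing_end"], k["turn1_start"])),
                           ("t1", (k["turn1_start"], k["turn1_end"])),
                           ("w2", (k["turn1_end"], k["turn2_start"])),
                           ("t2", (k["turn2_start"], k["turn2_end"]))):
        inside = (t >= lo) & (t <= hi)
        acc_z[inside] += scn.step_acc_amp * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * scn.cadence * (t[inside] - lo)))
        steps[name] = _step_count(hi - lo, scn.cadence)
    for amp, (lo, hi) in ((scn.acc_amp_stand, (k["standing_start"], k["standing_end"])),
                          (scn.acc_amp_sit, (k["sitting_start"], k["sitting_end"]))):
        c, w = 0.5 * (lo + hi), 0.4 * (hi - lo)
        acc_z += amp * _raised_cosine(t, c - 0.5 * w, c + 0.5 * w)
    acc_z += rng.normal(0.0, scn.noise_sd_acc, n)

    gyr_z_true = scn.turn_angle * _smoothstep_rate(t, a1, b1) \
        + sign2 * scn.turn_angle * _smoothstep_rate(t, a2, b2)
    gyr_z = gyr_z_true + rng.normal(0.0, scn.noise_sd_gyr, n)

    rec = ImuRecording(
        t=t, fs=scn.fs, pitch=pitch, yaw=yaw,
        roll=rng.normal(0.0, scn.noise_sd_angle, n),
        acc_x=rng.normal(0.0, scn.noise_sd_acc, n),
        acc_y=rng.normal(0.0, scn.noise_sd_acc, n),
        acc_z=acc_z,
        gyr_x=rng.normal(0.0, scn.noise_sd_gyr, n),
        gyr_y=rng.normal(0.0, scn.noise_sd_gyr, n),
        gyr_z=gyr_z,
        subject_meta={"synthetic": True, "scenario": scn.label, "seed": scn.seed},
    )
    truth = GroundTruth(
        boundaries={key: k[key] for key in (
            "standing_start", "standing_end", "turn1_start", "turn1_end",
            "turn2_start", "turn2_end", "sitting_start", "sitting_end")},
        steps=steps,
        peak_rate_t1=1.5 * scn.turn_angle / (b1 - a1),
        peak_rate_t2=1.5 * scn.turn_angle / (b2 - a2),
        pitch_amp_stand=scn.pitch_amp_stand,
        pitch_amp_sit=scn.pitch_amp_sit,
        acc_amp_stand=scn.acc_amp_stand,
        acc_amp_sit=scn.acc_amp_sit,
        total_time=k["sitting_end"] - k["standing_start"],
    )
    return rec, truth


def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           lo: float, hi: float) -> float:
    """Truncated-normal draw by rejection (falls back to clipping)."""
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


# Cohort statistics: (mean, sd, lower, upper).  Duration rows use the
# video-observed sub-task means/SDs of each cohort, truncated at +/-2 sd for
# the young group and at physiological floors for the older group (whose
# printed SDs exceed the means for some sub-tasks).
_YOUNG = {
    "d_standing": (1.16, 0.15, 0.86, 1.46),
    "d_first_walk": (2.51, 0.35, 1.81, 3.21),
    "d_turn1": (1.65, 0.25, 1.15, 2.15),
    "d_second_walk": (2.39, 0.36, 1.67, 3.11),
    "d_turn2": (1.03, 0.14, 0.75, 1.31),
    "d_sitting": (1.48, 0.17, 1.14, 1.82),
    "flexion": (5.8, 1.6, 3.0, 9.5),
    "acc_amp_stand": (6.49, 1.42, 3.9, 9.2),
    "acc_amp_sit": (6.09, 0.87, 4.5, 7.5),
    "cadence": (1.7, 0.25, 1.1, 2.4),
}
_OLDER = {
    "d_standing": (1.41, 0.71, 0.6, 2.83),
    "d_first_walk": (3.49, 3.26, 1.2, 10.0),
    "d_turn1": (2.23, 1.82, 0.9, 6.5),
    "d_second_walk": (3.75, 3.75, 1.3, 11.0),
    "d_turn2": (1.32, 0.14, 1.04, 1.60),
    "d_sitting": (1.65, 0.56, 0.8, 2.77),
    "flexion": (8.1, 2.2, 3.0, 11.5),
    "acc_amp_stand": (7.20, 1.63, 3.9, 9.5),
    "acc_amp_sit": (7.08, 2.18, 3.2, 10.2),
    "cadence": (2.0, 0.5, 1.2, 3.2),
}


def random_scenario(seed: int, population: str = "young") -> TugScenario:
    """Draw a reproducible scenario from a cohort's parameter distributions.

    Stand and sit pitch amplitudes are drawn as a common per-subject trunk
    flexion magnitude times sub-task phase factors, reflecting the strong
    within-subject coupling of the two excursions; independent draws would
    produce amplitude ratios the fixed normalized thresholds cannot handle
    and that the cohort tables do not show.
    """
    if population not in ("young", "older"):
        raise ValueError("population must be 'young' or 'older'")
    table = _YOUNG if population == "young" else _OLDER
    rng = np.random.default_rng(seed)
    draws = {name: _tnorm(rng, *table[name])
             for name in ("d_standing", "d_first_walk", "d_turn1",
                          "d_second_walk", "d_turn2", "d_sitting",
                          "flexion", "acc_amp_stand", "acc_amp_sit", "cadence")}
    flex = draws.pop("flexion")
    f_stand = _tnorm(rng, 0.92, 0.08, 0.70, 1.15)
    f_sit = _tnorm(rng, 1.08, 0.08, 0.85, 1.30)
    return TugScenario(
        **{name: draws[name] for name in (
            "d_standing", "d_first_walk", "d_turn1", "d_second_walk",
            "d_turn2", "d_sitting", "acc_amp_stand", "acc_amp_sit", "cadence")},
        d_presit_gap=_tnorm(rng, 0.25, 0.08, 0.10, 0.45),
        pitch_amp_stand=flex * f_stand,
        pitch_amp_sit=flex * f_sit,
        turn_angle=_tnorm(rng, 180.0, 8.0, 160.0, 200.0),
        step_acc_amp=_tnorm(rng, 2.0, 0.4, 1.2, 3.0),
        pitch_baseline=_tnorm(rng, 5.0, 3.0, -2.0, 12.0),
        yaw_baseline=float(rng.uniform(-170.0, 170.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
        label=population,
    )
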