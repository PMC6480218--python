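"""Agreement statistics and reference cohort tables.

A method-comparison study against frame-by-frame video timing validates the
IMU segmentation: Pearson correlation quantifies association of the total
test times, Bland-Altman analysis quantifies their agreement (bias and
limits of agreement), and risk-category concordance checks the clinical
decision the total time feeds.  The per-subject total-time tables of both
published cohorts ship as package fixtures so these statistics are
reproducible without the raw recordings.

``segmentation_error`` scores a detected segmentation against generator
ground truth, and ``batch_error_summary`` aggregates a seeded simulation
batch into the per-sub-task mean +/- SD error table shape used to report
segmentation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .config import AlgorithmConfig, DEFAULT_CONFIG
from .synthetic_tug import GroundTruth, random_scenario, simulate
from .tug_pipeline import TugSegmentation, run_pipeline

__all__ = ["PairedTimes", "AgreementStats", "pearson", "bland_altman",
           "risk_agreement", "segmentation_error", "batch_error_summary",
           "load_reference", "HIGH_RISK_CATEGORY"]

HIGH_RISK_CATEGORY = "high"


@dataclass
class PairedTimes:
    """Per-subject paired total times (reference video vs test IMU)."""

    subjects: list
    reference: np.ndarray
    test: np.ndarray
    reference_labels: list[str] | None = None
    test_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.size != self.test.size or self.reference.size < 2:
            raise ValueError("paired times require equal lengths >= 2")
        if np.any(self.reference <= 0) or np.any(self.test <= 0):
            raise ValueError("times must be positive")

    @property
    def n(self) -> int:
        return int(self.reference.size)

    def excluding_label(self, label: str) -> "PairedTimes":
        """Subset without subjects carrying ``label`` in either method."""
        if self.reference_labels is None or self.test_labels is None:
            raise ValueError("labels not present")
        keep = [i for i in range(self.n)
                if self.reference_labels[i] != label
                and self.test_labels[i] != label]
        return PairedTimes(
            subjects=[self.subjects[i] for i in keep],
            reference=self.reference[keep], test=self.test[keep],
            reference_labels=[self.reference_labels[i] for i in keep],
            test_labels=[self.test_labels[i] for i in keep])


@dataclass
class AgreementStats:
    """Bland-Altman summary: bias, SD of differences, limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires equal lengths >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(pearsonr(x, y)[0])


def bland_altman(x, y) -> AgreementStats:
    """Bland-Altman agreement of paired measurements ``x`` (reference) and
    ``y`` (test): differences ``d = x - y``, bias = mean(d), limits of
    agreement = bias +/- 1.96 * SD(d) (sample SD, n-1).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("bland_altman requires equal lengths >= 2")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd, n=int(x.size))


def risk_agreement(table: PairedTimes) -> int:
    """Percent of subjects whose risk categories agree, integer-rounded."""
    if table.reference_labels is None or table.test_labels is None:
        raise ValueError("risk labels missing")
    matches = sum(a == b for a, b in zip(table.reference_labels,
                                         table.test_labels))
    return int(round(100.0 * matches / table.n))


def segmentation_error(truth: GroundTruth, est: TugSegmentation
                       ) -> dict[str, float]:
    """Signed errors (truth - estimate) for the 8 boundary times and the 6
    sub-task durations."""
    errors: dict[str, float] = {}
    est_bounds = est.boundary_times()
    for name, t_true in truth.boundary_times().items():
        errors[f"boundary:{name}"] = t_true - est_bounds[name]
    true_b = truth.boundary_times()
    true_durations = {
        "standing": true_b["standing_end"] - true_b["standing_start"],
        "first_walk": true_b["turn1_start"] - true_b["standing_end"],
        "turn_3m": true_b["turn1_end"] - true_b["turn1_start"],
        "second_walk": true_b["turn2_start"] - true_b["turn1_end"],
        "presit_turn": true_b["turn2_end"] - true_b["turn2_start"],
        "sitting": true_b["sitting_end"] - true_b["sitting_start"],
    }
    for name, d_true in true_durations.items():
        errors[f"duration:{name}"] = d_true - est.durations()[name]
    return errors


def batch_error_summary(n: int = 100, seed: int = 7, population: str = "young",
                        config: AlgorithmConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Mean +/- SD segmentation errors over ``n`` seeded random scenarios.

    Rows are the error keys of :func:`segmentation_error`; scenarios on
    which detection fails are counted in the ``n_failed`` attribute.
    """
    rows: list[dict[str, float]] = []
    failed = 0
    rng = np.random.default_rng(seed)
    for _ in range(n):
        scenario = random_scenario(int(rng.integers(0, 2**31 - 1)), population)
        rec, truth = simulate(scenario)
        try:
            seg, _, _ = run_pipeline(rec, config)
        except Exception:
            failed += 1
            continue
        rows.append(segmentation_error(truth, seg))
    df = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "mean_error_s": df.mean(),
        "sd_error_s": df.std(ddof=1),
        "mean_abs_error_s": df.abs().mean(),
        "max_abs_error_s": df.abs().max(),
    })
    summary.attrs["n_scenarios"] = n
    summary.attrs["n_failed"] = failed
    return summary


def load_reference(cohort: str = "young") -> PairedTimes:
    """Load a packaged reference cohort table (``young`` or ``older``)."""
    if cohort not in ("young", "older"):
        raise ValueError("cohort must be 'young' or 'older'")
    name = f"reference_times_{cohort}.csv"
    with resources.files("tugseg.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, comment="#")
    labels = {}
    if "video_rof" in df.columns:
        labels = {"reference_labels": df["video_rof"].tolist(),
                  "test_labels": df["imu_rof"].tolist()}
    return PairedTimes(subjects=df["subject"].tolist(),
                       reference=df["video_time_s"].to_numpy(float),
                       test=df["imu_time_s"].to_numpy(float), **labels)
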