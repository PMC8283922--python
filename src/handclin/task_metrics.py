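"""Primary outcome-measure extraction for the five assessment tasks.

Each task yields one or two scalar metrics per subject x side x session:

========== ==================== ======= =================
metric     task                 units   better direction
========== ==================== ======= =================
AE         position matching    deg     lower
VelFlex    fast reaching        deg/s   higher
VelExt     fast reaching        deg/s   higher
AROM       range of motion      deg     higher
PROM       range of motion      deg     higher
ForceFlex  maximum force        N       higher
ForceExt   maximum force        N       higher
RMSESlow   trajectory following deg     lower
RMSEFast   trajectory following deg     lower
========== ==================== ======= =================

Two entry layers are provided: trace-level functions that reduce raw trial
signals to per-trial scalars, and the table-level :func:`extract_metric_table`
that aggregates a long-format trial table into the metric table consumed by
the reliability and validity modules. Missing trials degrade gracefully:
aggregates are computed over the available trials and flagged incomplete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import protocols

logger = logging.getLogger("handclin")

#: metric name -> (task, condition, direction_of_better, units, category)
METRICS: dict[str, dict] = {
    "AE": dict(task="matching", condition="none", better="lower", units="deg",
               category="sensory"),
    "VelFlex": dict(task="reaching", condition="flexion", better="higher",
                    units="deg/s", category="motor"),
    "VelExt": dict(task="reaching", condition="extension", better="higher",
                   units="deg/s", category="motor"),
    "AROM": dict(task="rom", condition="active", better="higher", units="deg",
                 category="motor"),
    "PROM": dict(task="rom", condition="passive", better="higher", units="deg",
                 category="motor"),
    "ForceFlex": dict(task="force", condition="flexion", better="higher",
                      units="N", category="motor"),
    "ForceExt": dict(task="force", condition="extension", better="higher",
                     units="N", category="motor"),
    "RMSESlow": dict(task="tracking", condition="slow", better="lower",
                     units="deg", category="sensorimotor"),
    "RMSEFast": dict(task="tracking", condition="fast", better="lower",
                     units="deg", category="sensorimotor"),
}

#: Expected number of trials feeding each metric in a complete assessment.
EXPECTED_TRIALS = {
    "AE": 21, "VelFlex": 10, "VelExt": 10, "AROM": 3, "PROM": 3,
    "ForceFlex": 3, "ForceExt": 3, "RMSESlow": 3, "RMSEFast": 3,
}

#: Trial counts per task for one assessment (both conditions pooled).
TRIALS_PER_TASK = {"matching": 21, "reaching": 20, "rom": 6, "force": 6,
                   "tracking": 6}


def metric_name(task: str, condition: str) -> str:
    """Map a (task, condition) pair to its metric name."""
    for name, info in METRICS.items():
        if info["task"] == task and info["condition"] == condition:
            return name
    raise KeyError(f"no metric for task={task!r}, condition={condition!r}")


def higher_is_worse(metric: str) -> bool:
    return METRICS[metric]["better"] == "lower"


@dataclass(frozen=True)
class MetricValue:
    """One aggregated metric with provenance about how many trials fed it."""

    name: str
    value: float
    n_trials: int
    complete: bool

    @property
    def direction_of_better(self) -> str:
        return METRICS[self.name]["better"]

    @property
    def units(self) -> str:
        return METRICS[self.name]["units"]


# ---------------------------------------------------------------------------
# Per-task extraction
# ---------------------------------------------------------------------------

def position_matching_error(
    presented_deg, reported_deg
) -> tuple[MetricValue, np.ndarray]:
    """Mean absolute position-matching error (AE) plus per-trial errors.

    The per-trial error is the absolute difference between the reported and
    the presented angle; AE is the mean across the (nominally 21) trials.
    """
    presented = np.asarray(presented_deg, dtype=float)
    reported = np.asarray(reported_deg, dtype=float)
    if presented.size == 0:
        raise ValueError("position matching requires at least one trial")
    if presented.shape != reported.shape:
        raise ValueError("presented and reported angle lists differ in length")
    if presented.size != EXPECTED_TRIALS["AE"]:
        logger.warning(
            "position matching: %d trials instead of %d",
            presented.size, EXPECTED_TRIALS["AE"],
        )
    errors = np.abs(reported - presented)
    value = MetricValue("AE", float(errors.mean()), int(errors.size),
                        errors.size == EXPECTED_TRIALS["AE"])
    return value, errors


def peak_velocity(
    velocity_degps: np.ndarray,
    direction: str,
    fs_hz: float = protocols.DEVICE_FS_HZ,
    prefiltered: bool = True,
) -> float:
    """Peak speed toward the target in one reaching trial.

    The signed velocity is rectified by movement direction (flexion positive,
    extension negative), so the peak is always reported as a nonnegative
    speed toward the target. The velocity channel is low-pass conditioned
    unless already filtered on-device.
    """
    v = np.asarray(velocity_degps, dtype=float)
    if not prefiltered:
        v = protocols.lowpass(v, fs_hz=fs_hz)
    sign = 1.0 if direction == "flexion" else -1.0
    if direction not in ("flexion", "extension"):
        raise ValueError(f"unknown direction {direction!r}")
    rectified = sign * v
    return float(max(rectified.max(), 0.0))


def max_velocity(
    per_trial_peaks, direction: str
) -> MetricValue:
    """Reaching metric: mean of the three largest per-trial peak velocities.

    With fewer than three valid trials the metric is flagged missing (NaN).
    """
    name = "VelFlex" if direction == "flexion" else "VelExt"
    peaks = np.asarray(
        [p for p in np.asarray(per_trial_peaks, dtype=float) if np.isfinite(p)]
    )
    if peaks.size < 3:
        logger.warning("reaching %s: only %d valid trials, metric missing",
                       direction, peaks.size)
        return MetricValue(name, float("nan"), int(peaks.size), False)
    top3 = np.sort(peaks)[-3:]
    return MetricValue(name, float(top3.mean()), int(peaks.size),
                       peaks.size == EXPECTED_TRIALS[name])


def range_of_motion(reps, mode: str) -> MetricValue:
    """ROM metric: mean over repetitions of (max flexion - max extension).

    ``reps`` holds either position traces or per-rep ``(max, min)`` extrema.
    """
    if mode not in ("active", "passive"):
        raise ValueError(f"unknown ROM mode {mode!r}")
    name = "AROM" if mode == "active" else "PROM"
    roms = []
    for rep in reps:
        arr = np.asarray(rep, dtype=float)
        if arr.size == 0:
            continue
        roms.append(float(arr.max() - arr.min()))
    if not roms:
        return MetricValue(name, float("nan"), 0, False)
    if len(roms) != EXPECTED_TRIALS[name]:
        logger.warning("ROM %s: %d repetitions instead of %d", mode,
                       len(roms), EXPECTED_TRIALS[name])
    return MetricValue(name, float(np.mean(roms)), len(roms),
                       len(roms) == EXPECTED_TRIALS[name])


def peak_force(
    force_n: np.ndarray,
    direction: str,
    fs_hz: float = protocols.DEVICE_FS_HZ,
    prefiltered: bool = True,
) -> float:
    """Peak direction-rectified fingertip force in one trial (N)."""
    f = np.asarray(force_n, dtype=float)
    if not prefiltered:
        f = protocols.lowpass(f, fs_hz=fs_hz)
    if direction not in ("flexion", "extension"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "flexion" else -1.0
    return float(max((sign * f).max(), 0.0))


def max_force(per_trial_peaks, direction: str) -> MetricValue:
    """Force metric: mean of the per-trial peak forces (nominally 3 trials)."""
    name = "ForceFlex" if direction == "flexion" else "ForceExt"
    peaks = np.asarray(
        [p for p in np.asarray(per_trial_peaks, dtype=float) if np.isfinite(p)]
    )
    if peaks.size == 0:
        return MetricValue(name, float("nan"), 0, False)
    return MetricValue(name, float(peaks.mean()), int(peaks.size),
                       peaks.size == EXPECTED_TRIALS[name])


def tracking_rmse(target_deg, response_deg) -> float:
    """Root-mean-square tracking error of one trajectory-following trial.

    Target and response must already share a common time base over the 30 s
    trial; the full trial is scored, including the initial pursuit onset.
    """
    target = np.asarray(target_deg, dtype=float)
    response = np.asarray(response_deg, dtype=float)
    if target.shape != response.shape:
        raise ValueError("target and response must share one time base")
    if target.size == 0:
        raise ValueError("empty tracking trial")
    return float(np.sqrt(np.mean((response - target) ** 2)))


def aggregate_tracking(per_trial_rmse, speed: str) -> MetricValue:
    """Tracking metric: mean RMSE over the (nominally 3) trials of one speed."""
    if speed not in ("slow", "fast"):
        raise ValueError(f"unknown tracking speed {speed!r}")
    name = "RMSESlow" if speed == "slow" else "RMSEFast"
    vals = np.asarray(
        [v for v in np.asarray(per_trial_rmse, dtype=float) if np.isfinite(v)]
    )
    if vals.size == 0:
        return MetricValue(name, float("nan"), 0, False)
    return MetricValue(name, float(vals.mean()), int(vals.size),
                       vals.size == EXPECTED_TRIALS[name])


# ---------------------------------------------------------------------------
# Table-level extraction
# ---------------------------------------------------------------------------

#: Required columns of the long-format trial table.
TRIAL_TABLE_COLUMNS = (
    "subject_id", "side", "session", "task", "condition", "trial_idx",
    "presented_deg", "reported_deg", "value",
)


def trial_metric_values(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial metric contributions from a long-format trial table.

    For position matching the per-trial value is the absolute matching error
    computed from the ``presented_deg``/``reported_deg`` payload; for all
    other tasks the scalar ``value`` column already carries the per-trial
    quantity (peak velocity, per-rep ROM, peak force, per-trial RMSE).

    Returns a frame with columns subject_id, side, session, metric,
    trial_idx, value.
    """
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    df = trials.copy()
    df["metric"] = [
        metric_name(t, c) for t, c in zip(df["task"], df["condition"])
    ]
    is_matching = df["task"] == "matching"
    value = df["value"].astype(float).to_numpy()
    value[is_matching.to_numpy()] = np.abs(
        df.loc[is_matching, "reported_deg"].astype(float).to_numpy()
        - df.loc[is_matching, "presented_deg"].astype(float).to_numpy()
    )
    df["value"] = value
    return df[["subject_id", "side", "session", "metric", "trial_idx", "value"]]


def _aggregate(metric: str, values: np.ndarray) -> MetricValue:
    if metric in ("VelFlex", "VelExt"):
        return max_velocity(values, METRICS[metric]["condition"])
    values = values[np.isfinite(values)]
    if values.size == 0:
        return MetricValue(metric, float("nan"), 0, False)
    return MetricValue(metric, float(values.mean()), int(values.size),
                       values.size == EXPECTED_TRIALS[metric])


def extract_metric_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format trial table into the per-cell metric table.

    Output columns: subject_id, side, session, metric, value, n_trials,
    complete. Aggregation is the per-metric rule (top-3 mean for reaching
    peak velocity, plain mean otherwise) and is invariant to trial order.
    """
    trial_vals = trial_metric_values(trials)
    rows = []
    keys = ["subject_id", "side", "session", "metric"]
    for key, grp in trial_vals.groupby(keys, sort=True):
        mv = _aggregate(key[3], grp["value"].to_numpy(dtype=float))
        rows.append(dict(zip(keys, key)) | dict(
            value=mv.value, n_trials=mv.n_trials, complete=mv.complete,
        ))
    out = pd.DataFrame(rows, columns=keys + ["value", "n_trials", "complete"])
    n_bad = int((~out["complete"]).sum())
    if n_bad:
        logger.info("metric table: %d cells aggregated from incomplete trials",
                    n_bad)
    return out
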