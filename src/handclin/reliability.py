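"""Test-retest clinimetrics: ICC(A,k), SEM/SRD, systematic shift, Bland-Altman.

The test-retest design is two sessions on separate days, each session scoring
one metric per subject as the aggregate of several trials. The statistics
here operate on the *measurement panel* of one metric: an (n subjects x 2
sessions) matrix of session scores, optionally backed by the pooled
trial-level values used for range normalization and replicate-noise
estimation.

Decision thresholds mirror the assessment protocol: ICC above 0.7 is
acceptable, SRD% below 30 indicates tolerable measurement error, and a
systematic shift within [-6.35, 6.35] (% of the observed range) indicates
the absence of a strong learning effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_metrics import METRICS, higher_is_worse

logger = logging.getLogger("handclin")

#: Reliability decision thresholds.
ICC_THRESHOLD = 0.7
SRD_PCT_THRESHOLD = 30.0
SHIFT_BOUND = 6.35
#: SRD multiplier: 1.96 * sqrt(2), the 95% band of a test-retest difference.
SRD_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class AnovaMS:
    """Mean squares of the complete two-way (subject x session) ANOVA."""

    ms_subject: float
    ms_session: float
    ms_error: float
    n_subjects: int
    n_sessions: int


def two_way_anova(panel: np.ndarray) -> AnovaMS:
    """Mean squares of a complete two-way crossed design without replication.

    ``panel`` is (n subjects x k sessions). Subjects are random, sessions are
    the repeated measurement occasions of the absolute-agreement model.
    """
    x = np.asarray(panel, dtype=float)
    if x.ndim != 2:
        raise ValueError("panel must be a 2-D (subjects x sessions) array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_subject = k * float(((row_means - grand) ** 2).sum())
    ss_session = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid ** 2).sum())
    return AnovaMS(
        ms_subject=ss_subject / (n - 1),
        ms_session=ss_session / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        n_subjects=n,
        n_sessions=k,
    )


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    defined: bool
    anova: AnovaMS | None = None


def icc_a_k(panel: np.ndarray, alpha: float = 0.05) -> IccResult:
    """Absolute-agreement, average-measures intraclass correlation ICC(A,k).

    Two-way random-effects model on the session scores:
    ``ICC(A,k) = (MS_subject - MS_error) / (MS_subject + (MS_session - MS_error)/n)``.
    The confidence interval is the F-based interval of the single-measure
    form ICC(A,1) (Satterthwaite degrees of freedom), converted to the
    average-measures scale with the Spearman-Brown step-up.

    A panel with no variance at all (all cells identical) leaves the
    coefficient undefined; the result is flagged rather than raised.
    """
    x = np.asarray(panel, dtype=float)
    ms = two_way_anova(x)
    n, k = ms.n_subjects, ms.n_sessions
    denom_k = ms.ms_subject + (ms.ms_session - ms.ms_error) / n
    if np.ptp(x) == 0.0 or denom_k == 0.0:
        logger.warning("ICC undefined: degenerate panel with no variance")
        return IccResult(float("nan"), float("nan"), float("nan"), False, ms)
    icc_k = (ms.ms_subject - ms.ms_error) / denom_k

    # Single-measure form and its F-based CI (two-way random, absolute
    # agreement), then step up the bounds to the average-measures scale.
    denom_1 = (ms.ms_subject + (k - 1) * ms.ms_error
               + k * (ms.ms_session - ms.ms_error) / n)
    rho1 = (ms.ms_subject - ms.ms_error) / denom_1
    if rho1 >= 1.0 or ms.ms_error == 0.0:
        return IccResult(float(icc_k), float(icc_k), float(icc_k), True, ms)
    a = k * rho1 / (n * (1.0 - rho1))
    b = 1.0 + k * rho1 * (n - 1) / (n * (1.0 - rho1))
    num_v = (a * ms.ms_session + b * ms.ms_error) ** 2
    den_v = ((a * ms.ms_session) ** 2 / (k - 1)
             + (b * ms.ms_error) ** 2 / ((n - 1) * (k - 1)))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo1 = (n * (ms.ms_subject - f1 * ms.ms_error)
           / (f1 * (k * ms.ms_session + (k * n - k - n) * ms.ms_error)
              + n * ms.ms_subject))
    hi1 = (n * (f2 * ms.ms_subject - ms.ms_error)
           / (k * ms.ms_session + (k * n - k - n) * ms.ms_error
              + n * f2 * ms.ms_subject))

    def step_up(r1: float) -> float:
        return k * r1 / (1.0 + (k - 1) * r1)

    return IccResult(float(icc_k), float(step_up(lo1)), float(step_up(hi1)),
                     True, ms)


@dataclass(frozen=True)
class SemSrd:
    sem: float
    srd: float
    srd_pct: float
    value_range: float
    trial_sd: float
    defined: bool


def trial_replicate_sd(trial_values: pd.DataFrame) -> float:
    """Pooled within-cell (subject x session) SD of trial-level values.

    Quantifies the trial-to-trial replicate noise underneath the session
    scores; complements the session-level SEM when trial data are present.
    """
    ss, df = 0.0, 0
    for _, grp in trial_values.groupby(["subject_id", "session"]):
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= 2:
            ss += float(((v - v.mean()) ** 2).sum())
            df += v.size - 1
    return math.sqrt(ss / df) if df > 0 else float("nan")


def sem_srd(
    panel: np.ndarray,
    pooled_values: np.ndarray | None = None,
    trial_values: pd.DataFrame | None = None,
) -> SemSrd:
    """Standard error of measurement and smallest real difference.

    SEM is the square root of the error variance of the two-way ANOVA on
    session scores; SRD = 1.96 * sqrt(2) * SEM. SRD% expresses the SRD as a
    percentage of the observed range, where the range is max - min over all
    trial-level values of the metric pooled across subjects and sessions
    (``pooled_values``); the session scores themselves are used as fallback.
    """
    x = np.asarray(panel, dtype=float)
    ms = two_way_anova(x)
    sem = math.sqrt(max(ms.ms_error, 0.0))
    srd = SRD_FACTOR * sem
    ref = np.asarray(pooled_values, dtype=float) if pooled_values is not None \
        else x.ravel()
    ref = ref[np.isfinite(ref)]
    value_range = float(np.ptp(ref)) if ref.size else 0.0
    if value_range == 0.0:
        logger.warning("SRD%% undefined: zero observed range")
        srd_pct, defined = float("nan"), False
    else:
        srd_pct, defined = 100.0 * srd / value_range, True
    tsd = trial_replicate_sd(trial_values) if trial_values is not None \
        else float("nan")
    return SemSrd(sem, srd, srd_pct, value_range, tsd, defined)


def systematic_shift(
    session1: np.ndarray,
    session2: np.ndarray,
    value_range: float,
    metric: str | None = None,
) -> float:
    """Mean test-to-retest difference as a % of the observed range.

    Oriented so a negative shift always means improvement on retest: for
    lower-is-better metrics the raw mean(session2 - session1) already has
    that orientation; for higher-is-better metrics the sign is flipped.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if value_range == 0.0 or not np.isfinite(value_range):
        logger.warning("systematic shift undefined: zero observed range")
        return float("nan")
    raw = 100.0 * float(np.mean(s2 - s1)) / value_range
    if metric is not None and not higher_is_worse(metric):
        raw = -raw
    return raw


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(session1: np.ndarray, session2: np.ndarray) -> BlandAltman:
    """Mean retest difference and 95% limits of agreement (mean +- 1.96 SD)."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired scores")
    diffs = s2 - s1
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd,
                       (s1 + s2) / 2.0, diffs)


def test_retest_spearman(
    session1: np.ndarray, session2: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between test and retest session scores."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(s1) == 0.0 or np.ptp(s2) == 0.0:
        logger.warning("test-retest correlation undefined: constant scores")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(s1, s2)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def metric_panel(
    metric_table: pd.DataFrame, metric: str, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """(n x 2) session-score panel for one metric/side, complete pairs only.

    Returns (panel, subject_ids).
    """
    sub = metric_table[
        (metric_table["metric"] == metric) & (metric_table["side"] == side)
    ]
    wide = sub.pivot_table(index="subject_id", columns="session",
                           values="value").dropna()
    if wide.shape[1] != 2:
        raise ValueError(
            f"metric {metric!r} on side {side!r} does not have 2 sessions"
        )
    return wide.to_numpy(dtype=float), wide.index.to_numpy()


def reliability_report(
    metric_table: pd.DataFrame,
    trial_values: pd.DataFrame,
    side: str = "affected",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table of test-retest statistics, one row per metric on one side.

    Columns mirror the clinimetric report shape: session means +- SD, mean
    retest difference, ICC(A,k) with CI, SRD, SRD%, systematic shift,
    Bland-Altman mean/limits, Spearman test-retest correlation, and boolean
    flags against the 0.7 / 30% / +-6.35 decision rules.
    """
    rows = []
    for metric in METRICS:
        sub = metric_table[
            (metric_table["metric"] == metric) & (metric_table["side"] == side)
        ]
        if sub.empty:
            rows.append(dict(metric=metric, side=side, n_subjects=0,
                             available=False))
            continue
        try:
            panel, _ = metric_panel(metric_table, metric, side)
        except ValueError:
            rows.append(dict(metric=metric, side=side, n_subjects=0,
                             available=False))
            continue
        tv = trial_values[
            (trial_values["metric"] == metric) & (trial_values["side"] == side)
        ]
        pooled = tv["value"].to_numpy(dtype=float) if not tv.empty else None
        icc = icc_a_k(panel, alpha=alpha)
        meas = sem_srd(panel, pooled_values=pooled,
                       trial_values=tv if not tv.empty else None)
        shift = systematic_shift(panel[:, 0], panel[:, 1], meas.value_range,
                                 metric=metric)
        ba = bland_altman(panel[:, 0], panel[:, 1])
        rho, p = test_retest_spearman(panel[:, 0], panel[:, 1])
        rows.append(dict(
            metric=metric,
            side=side,
            n_subjects=panel.shape[0],
            available=True,
            mean_t1=float(panel[:, 0].mean()),
            sd_t1=float(panel[:, 0].std(ddof=1)),
            mean_t2=float(panel[:, 1].mean()),
            sd_t2=float(panel[:, 1].std(ddof=1)),
            mean_diff=float((panel[:, 1] - panel[:, 0]).mean()),
            sd_diff=float((panel[:, 1] - panel[:, 0]).std(ddof=1)),
            icc=icc.icc, icc_ci_low=icc.ci_low, icc_ci_high=icc.ci_high,
            sem=meas.sem, srd=meas.srd, srd_pct=meas.srd_pct,
            value_range=meas.value_range, trial_sd=meas.trial_sd,
            shift_pct=shift,
            ba_mean_diff=ba.mean_diff, ba_loa_low=ba.loa_low,
            ba_loa_high=ba.loa_high,
            retest_rho=rho, retest_p=p,
            icc_ok=bool(icc.defined and icc.icc > ICC_THRESHOLD),
            srd_ok=bool(meas.defined and meas.srd_pct < SRD_PCT_THRESHOLD),
            shift_ok=bool(np.isfinite(shift) and abs(shift) <= SHIFT_BOUND),
        ))
    return pd.DataFrame(rows)
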