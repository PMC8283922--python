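"""Virtual control and stroke cohorts with the study's statistical structure.

The generator emulates the clinimetric structure the analysis pipeline
assumes, down to raw per-trial signals, so every downstream stage (signal
conditioning, metric extraction, reliability, validity) can be exercised
without access to clinical data:

* two latent severities per subject, motor and proprioceptive, on [0, 1]
  (0 = intact); motor metrics load on the motor severity, the matching error
  on the proprioceptive one, and the sensorimotor tracking error on a
  weighted mix of both;
* per-metric control baselines plus a severity effect calibrated so that the
  affected-side stroke distributions hit the configured targets (the
  ``paper_like`` preset targets the published stroke test-session values,
  e.g. AE 14.63 +- 6.43 deg); control-hand baselines are synthetic,
  plausibility-calibrated values;
* variance components: between-subject, between-session and trial-to-trial,
  a configurable session-2 systematic shift, demographic confounds (age and
  gender on force, gender on velocity, tested hand on motor metrics) and a
  presented-angle magnitude effect on the matching error;
* device-workspace saturation and optional raw-trace synthesis (bell-shaped
  reaching velocity pulses, ROM/force plateaus, lagged-gain tracking with
  tremor) for end-to-end extraction tests; a fast scalar mode serves
  Monte-Carlo statistics.

All randomness flows from one master seed through per-subject, per-session
substreams, so cohorts regenerate stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import protocols
from .task_metrics import METRICS, TRIALS_PER_TASK, higher_is_worse

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricModel:
    """Generative model of one metric's population structure (metric units).

    ``control_mean``/``control_sd`` describe the between-subject distribution
    of neurologically intact hands; the severity effect needed to reach
    ``stroke_mean`` on the affected side is solved at configuration time
    (accounting for floor/cap saturation). ``trial_sd`` and ``session_sd``
    are the within-session replicate SD and the between-session (day-to-day)
    SD. ``shift`` is a programmed systematic session-2 offset in metric
    units, positive = worse on retest.
    """

    name: str
    control_mean: float
    control_sd: float
    stroke_mean: float
    stroke_sd: float
    trial_sd: float
    session_sd: float
    severity: str            # {"motor", "proprio", "mixed"}
    shift: float = 0.0
    floor: float = 0.0
    cap: float | None = None
    age_slope: float = 0.0       # per year, centered at the control mean age
    female_effect: float = 0.0
    left_hand_effect: float = 0.0


def _severity_grid(n: int = 401) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def _clip(x, floor, cap):
    return np.clip(x, floor, np.inf if cap is None else cap)


@lru_cache(maxsize=None)
def _solve_severity_effect(
    control_mean: float, stroke_mean: float, floor: float, cap: float | None,
    worse_sign: float,
) -> float:
    """Severity slope so that E_s[clip(mu(s))] over s ~ U(0,1) hits the target.

    ``mu(s) = control_mean + worse_sign * effect * s`` with workspace/physical
    saturation applied; solved by bisection (the expectation is monotone in
    the effect size).
    """
    s = _severity_grid()

    def mean_at(e: float) -> float:
        return float(_clip(control_mean + worse_sign * e * s, floor, cap).mean())

    target = stroke_mean
    if abs(target - control_mean) < 1e-12:
        return 0.0
    lo, hi = 0.0, 1.0
    while abs(mean_at(hi) - control_mean) < abs(target - control_mean) \
            and hi < 1e7:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if abs(mean_at(mid) - control_mean) < abs(target - control_mean):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@lru_cache(maxsize=None)
def top_k_of_n_normal_mean(n: int = 10, k: int = 3) -> float:
    """E[mean of the k largest of n iid standard normals] (order-statistic
    integral). Used to debias the reaching peak draws so the top-3-of-10
    session aggregate lands on the configured target."""
    total = 0.0
    for i in range(n - k + 1, n + 1):
        coef = math.factorial(n) / (math.factorial(i - 1) * math.factorial(n - i))

        def integrand(x, i=i, coef=coef):
            return coef * x * stats.norm.cdf(x) ** (i - 1) \
                * stats.norm.sf(x) ** (n - i) * stats.norm.pdf(x)

        val, _ = integrate.quad(integrand, -10, 10, limit=200)
        total += val
    return total / k


@dataclass(frozen=True)
class TraceParams:
    """Parameters of the raw-trace synthesis."""

    fs_hz: float = 1000.0
    #: Time from movement onset to peak velocity (s): group mean and SD.
    time_to_peak_stroke: tuple[float, float] = (0.160, 0.057)
    time_to_peak_control: tuple[float, float] = (0.122, 0.022)
    reach_onset_s: float = 0.4
    force_rise_s: float = 0.5
    force_hold_s: float = 3.0
    #: Tracking-response degradation per unit severity: gain loss and lag (s).
    track_gain_slope: float = 0.3
    track_lag_slope: float = 0.4


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort-generator configuration (see module docstring)."""

    metrics: dict[str, MetricModel]
    n_stroke: int = 30
    n_control: int = 31
    n_sessions_stroke: int = 2
    n_sessions_control: int = 1
    #: Fraction of the affected-side severity expressed on the less-affected
    #: side, per task category.
    la_fraction: dict = field(default_factory=lambda: {
        "sensory": 0.5, "motor": 0.4, "sensorimotor": 0.3})
    #: Gaussian-copula correlation between the two latent severities.
    severity_corr: float = 0.4
    #: Mixing weights (proprioceptive, motor) of the sensorimotor severity.
    mixed_weights: tuple[float, float] = (0.6, 0.4)
    #: Relative increase of the matching-error SD per 10 deg of presented
    #: angle above the 20 deg midpoint (angle-magnitude effect).
    angle_slope: float = 0.3
    #: Study design constraint: at most this fraction of stroke subjects with
    #: intact proprioception (kUDT = 2).
    max_intact_fraction: float = 0.4
    enforce_intact_constraint: bool = True
    #: Demographics: (mean, sd, low, high) of age per group.
    stroke_age: tuple[float, float, float, float] = (64.50, 14.02, 25.0, 92.0)
    control_age: tuple[float, float, float, float] = (66.87, 7.92, 50.0, 88.0)
    p_male_stroke: float = 19 / 30
    p_male_control: float = 20 / 31
    p_left_handed_stroke: float = 4 / 30
    trace: TraceParams = field(default_factory=TraceParams)

    def __post_init__(self) -> None:
        if self.n_stroke < 2 or self.n_control < 2:
            raise ValueError("cohort sizes must be at least 2")
        for m in self.metrics.values():
            if min(m.control_sd, m.stroke_sd, m.trial_sd, m.session_sd) < 0:
                raise ValueError(f"negative SD in metric model {m.name}")
        if not 0.0 <= self.max_intact_fraction <= 1.0:
            raise ValueError("max_intact_fraction must be within [0, 1]")

    # -- derived quantities -------------------------------------------------

    def worse_sign(self, metric: str) -> float:
        return 1.0 if higher_is_worse(metric) else -1.0

    def severity_effect(self, metric: str) -> float:
        m = self.metrics[metric]
        return _solve_severity_effect(
            m.control_mean, m.stroke_mean, m.floor, m.cap,
            self.worse_sign(metric))

    def stroke_subject_sd(self, metric: str) -> float:
        """Residual between-subject SD so affected-side totals approach the
        configured stroke SD after the severity-spread contribution."""
        m = self.metrics[metric]
        e = self.severity_effect(metric)
        s = _severity_grid()
        mu = _clip(m.control_mean + self.worse_sign(metric) * e * s,
                   m.floor, m.cap)
        var_from_severity = float(mu.var())
        extra = m.stroke_sd ** 2 - var_from_severity
        return math.sqrt(max(extra, m.control_sd ** 2 * 0.04))

    def mixed_severity(self, s_motor, s_proprio):
        wp, wm = self.mixed_weights
        return (wp * np.asarray(s_proprio) + wm * np.asarray(s_motor)) \
            / (wp + wm)

    def metric_severity(self, metric: str, s_motor, s_proprio):
        kind = self.metrics[metric].severity
        if kind == "motor":
            return np.asarray(s_motor, dtype=float)
        if kind == "proprio":
            return np.asarray(s_proprio, dtype=float)
        return self.mixed_severity(s_motor, s_proprio)

    def expected_metric_value(self, metric: str, severity: float) -> float:
        """Noise-free expected session value at a given governing severity."""
        m = self.metrics[metric]
        e = self.severity_effect(metric)
        return float(_clip(m.control_mean + self.worse_sign(metric) * e
                           * severity, m.floor, m.cap))


def paper_like_config(**overrides) -> GeneratorConfig:
    """Preset calibrated to the published affected-side stroke distributions.

    Stroke targets are the published test-session means/SDs; control-hand
    baselines are synthetic plausibility values (the control supplementary
    table is not reproduced here), chosen so group separations land near the
    published AUCs.
    """
    metrics = {
        "AE": MetricModel("AE", 5.0, 1.5, 14.63, 6.43, trial_sd=0.0,
                          session_sd=1.0, severity="proprio", floor=0.5,
                          cap=40.0),
        "VelFlex": MetricModel("VelFlex", 550.0, 100.0, 314.94, 180.30,
                               trial_sd=55.0, session_sd=25.0,
                               severity="motor", floor=2.0,
                               female_effect=-60.0, left_hand_effect=-25.0),
        "VelExt": MetricModel("VelExt", 420.0, 90.0, 149.06, 146.27,
                              trial_sd=40.0, session_sd=15.0,
                              severity="motor", floor=2.0,
                              female_effect=-50.0, left_hand_effect=-20.0),
        "AROM": MetricModel("AROM", 82.0, 8.0, 43.89, 36.20, trial_sd=3.0,
                            session_sd=2.0, severity="motor", floor=0.0,
                            cap=90.0, left_hand_effect=-2.0),
        "PROM": MetricModel("PROM", 88.0, 3.0, 83.88, 10.48, trial_sd=2.0,
                            session_sd=1.5, severity="motor", floor=10.0,
                            cap=90.0, left_hand_effect=-1.0),
        "ForceFlex": MetricModel("ForceFlex", 28.0, 8.0, 11.64, 11.55,
                                 trial_sd=1.2, session_sd=0.8,
                                 severity="motor", floor=0.2,
                                 age_slope=-0.12, female_effect=-6.0,
                                 left_hand_effect=-1.5),
        "ForceExt": MetricModel("ForceExt", 12.0, 4.0, 4.12, 4.52,
                                trial_sd=0.6, session_sd=0.4,
                                severity="motor", floor=0.1,
                                age_slope=-0.05, female_effect=-2.5,
                                left_hand_effect=-0.8),
        "RMSESlow": MetricModel("RMSESlow", 8.0, 2.0, 21.09, 8.68,
                                trial_sd=1.5, session_sd=1.0,
                                severity="mixed", floor=1.0, cap=45.0),
        "RMSEFast": MetricModel("RMSEFast", 10.0, 2.5, 21.45, 7.80,
                                trial_sd=1.8, session_sd=1.2,
                                severity="mixed", floor=1.0, cap=45.0),
    }
    return GeneratorConfig(metrics=metrics, **overrides)


def null_config(**overrides) -> GeneratorConfig:
    """No group differences: stroke targets equal control baselines, no
    demographic confounds, identical age sampling in both groups."""
    base = paper_like_config()
    metrics = {
        name: replace(m, stroke_mean=m.control_mean, stroke_sd=m.control_sd,
                      age_slope=0.0, female_effect=0.0, left_hand_effect=0.0)
        for name, m in base.metrics.items()
    }
    kw = dict(stroke_age=base.control_age, p_male_stroke=base.p_male_control)
    kw.update(overrides)
    return GeneratorConfig(metrics=metrics, **kw)


def high_noise_config(**overrides) -> GeneratorConfig:
    """Paper-like separations with tripled within-subject noise."""
    base = paper_like_config()
    metrics = {
        name: replace(m, trial_sd=3.0 * m.trial_sd,
                      session_sd=3.0 * m.session_sd)
        for name, m in base.metrics.items()
    }
    return GeneratorConfig(metrics=metrics, **overrides)


def noiseless_config(**overrides) -> GeneratorConfig:
    """Degenerate preset for identity tests: intact subjects perform
    perfectly (zero error metrics), no noise, no confounds, no shift."""
    base = paper_like_config()
    metrics = {}
    for name, m in base.metrics.items():
        control_mean = 0.0 if higher_is_worse(name) else m.control_mean
        metrics[name] = replace(
            m, control_mean=control_mean, control_sd=0.0, trial_sd=0.0,
            session_sd=0.0, shift=0.0, floor=0.0, age_slope=0.0,
            female_effect=0.0, left_hand_effect=0.0,
        )
    kw = dict(angle_slope=0.0)
    kw.update(overrides)
    return GeneratorConfig(metrics=metrics, **kw)


PRESETS = {
    "paper_like": paper_like_config,
    "null": null_config,
    "high_noise": high_noise_config,
    "noiseless": noiseless_config,
}


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, low, high)


def simulate_clinical_scores(
    s_motor: float, s_proprio: float, rng: np.random.Generator
) -> dict:
    """Noisy monotone maps from the latent severities to clinical scores.

    FMA (0-66) decreases in motor severity, kUDT (2/1/0) decreases in
    proprioceptive severity, BBT in motor severity; MoCA and MAS are drawn
    around the cohort-typical values.
    """
    fma = float(np.clip(round(66.0 * (1.0 - s_motor) + rng.normal(0, 4.0)),
                        0, 66))
    latent = s_proprio + rng.normal(0, 0.08)
    kudt = 2 if latent < 0.30 else (1 if latent < 0.65 else 0)
    bbt_aff = float(np.clip(
        round(72.0 * (1.0 - s_motor) ** 1.5 + rng.normal(0, 7.0)), 0, 90))
    bbt_la = float(np.clip(round(rng.normal(60.3, 11.3)), 30, 90))
    moca = float(np.clip(round(rng.normal(22.0, 5.8)), 0, 30))
    mas = float(rng.choice([0, 1, 2, 3], p=[0.93, 0.04, 0.02, 0.01]))
    return dict(FMA=fma, kUDT=float(kudt), BBT_affected=bbt_aff,
                BBT_less_affected=bbt_la, MoCA=moca, MAS=mas)


def sample_cohort(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Reproducible cohort of stroke and control subject profiles.

    Severities span intact to severe (uniform marginals coupled by a
    Gaussian copula); the proprioception inclusion constraint (at most
    ``max_intact_fraction`` of stroke subjects with kUDT = 2) is enforced by
    re-drawing the proprioceptive severity of excess intact subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC0)))
    rows = []
    # stroke subjects
    n = config.n_stroke
    ages = _truncated_normal(rng, *config.stroke_age, size=n)
    male = rng.random(n) < config.p_male_stroke
    left_handed = rng.random(n) < config.p_left_handed_stroke
    affected_right = rng.random(n) < 0.5
    cov = np.array([[1.0, config.severity_corr], [config.severity_corr, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    s_motor = stats.norm.cdf(z[:, 0])
    s_proprio = stats.norm.cdf(z[:, 1])
    for i in range(n):
        rows.append(dict(
            subject_id=f"S{i + 1:02d}", group="stroke",
            age=float(ages[i]), gender="male" if male[i] else "female",
            handedness="left" if left_handed[i] else "right",
            affected_side="right" if affected_right[i] else "left",
            s_motor=float(s_motor[i]), s_proprio=float(s_proprio[i]),
        ))
    # control subjects: intact, right-handed by design
    m = config.n_control
    ages_c = _truncated_normal(rng, *config.control_age, size=m)
    male_c = rng.random(m) < config.p_male_control
    for i in range(m):
        rows.append(dict(
            subject_id=f"C{i + 1:02d}", group="control",
            age=float(ages_c[i]), gender="male" if male_c[i] else "female",
            handedness="right", affected_side="",
            s_motor=0.0, s_proprio=0.0,
        ))
    df = pd.DataFrame(rows)

    clin = [simulate_clinical_scores(r.s_motor, r.s_proprio, rng)
            for r in df.itertuples()]
    df = pd.concat([df, pd.DataFrame(clin)], axis=1)

    if config.enforce_intact_constraint and config.n_stroke > 0:
        stroke_mask = df["group"] == "stroke"
        max_n = int(math.floor(config.max_intact_fraction * config.n_stroke))
        for _ in range(100):
            intact = stroke_mask & (df["kUDT"] == 2.0)
            excess = int(intact.sum()) - max_n
            if excess <= 0:
                break
            idx = rng.choice(np.flatnonzero(intact.to_numpy()), size=excess,
                             replace=False)
            for j in idx:
                df.loc[j, "s_proprio"] = float(rng.uniform(0.35, 1.0))
                upd = simulate_clinical_scores(
                    float(df.loc[j, "s_motor"]), float(df.loc[j, "s_proprio"]),
                    rng)
                df.loc[j, "kUDT"] = upd["kUDT"]
        else:
            raise RuntimeError("could not satisfy the intact-proprioception "
                               "constraint; check the configuration")
    return df


# ---------------------------------------------------------------------------
# Trial-level simulation (fast scalar mode)
# ---------------------------------------------------------------------------

def _sides_for(group: str) -> tuple[str, ...]:
    return ("affected", "less_affected") if group == "stroke" \
        else ("dominant", "nondominant")


def _side_severity(config, metric, subject, side):
    s = config.metric_severity(metric, subject["s_motor"],
                               subject["s_proprio"])
    if side in ("dominant", "nondominant"):
        return 0.0 if side == "dominant" else 0.0
    frac = 1.0 if side == "affected" \
        else config.la_fraction[METRICS[metric]["category"]]
    return float(s) * frac


def _confound_offset(config, metric, subject, side):
    """Demographic confound contribution, centered on the control mix so the
    configured population means are unaffected by the confound terms."""
    from .validity import hand_of

    m = config.metrics[metric]
    age_center = config.control_age[0]
    off = m.age_slope * (float(subject["age"]) - age_center)
    female = 1.0 if subject["gender"] == "female" else 0.0
    off += m.female_effect * (female - (1.0 - config.p_male_control))
    left = 1.0 if hand_of(subject, side) == "left" else 0.0
    off += m.left_hand_effect * (left - 0.5)  # both hands of each subject
    return off


def subject_level_mean(
    config: GeneratorConfig, metric: str, subject: pd.Series, side: str,
    subject_re: float,
) -> float:
    """Latent per-subject per-side expected metric value (before session and
    trial noise), with workspace/physiological saturation applied."""
    m = config.metrics[metric]
    sev = _side_severity(config, metric, subject, side)
    mu = (m.control_mean
          + config.worse_sign(metric) * config.severity_effect(metric) * sev
          + _confound_offset(config, metric, subject, side)
          + subject_re)
    return float(_clip(mu, m.floor, m.cap))


#: Condition layout per task: (condition, n_trials, metric) in protocol order.
_TASK_LAYOUT = (
    ("matching", (("none", 21, "AE"),)),
    ("reaching", (("flexion", 10, "VelFlex"), ("extension", 10, "VelExt"))),
    ("rom", (("active", 3, "AROM"), ("passive", 3, "PROM"))),
    ("force", (("flexion", 3, "ForceFlex"), ("extension", 3, "ForceExt"))),
    ("tracking", (("slow", 3, "RMSESlow"), ("fast", 3, "RMSEFast"))),
)


def _matching_trials(config, session_mu, rng):
    """Presented/reported angle pairs with the angle-magnitude effect.

    Signed errors are zero-mean normal with SD scaled so the expected mean
    absolute error equals ``session_mu``; the SD grows with the presented
    angle (larger matching error at larger flexion angles), normalized to
    preserve the session-level expectation.
    """
    seq = protocols.generate_angle_sequence(int(rng.integers(2 ** 31)))
    presented = np.asarray(seq.angles_deg, dtype=float)
    a = max(float(session_mu), 0.0)
    sigma_fold = a * math.sqrt(math.pi / 2.0)
    scale = 1.0 + config.angle_slope * (presented - 20.0) / 10.0
    scale = np.clip(scale, 0.05, None)
    scale /= scale.mean()
    errors = rng.normal(0.0, 1.0, presented.size) * sigma_fold * scale
    return presented, presented + errors


def simulate_session(
    subject: pd.Series,
    session: int,
    config: GeneratorConfig,
    seed: int,
    sides: tuple[str, ...] | None = None,
    subject_re: dict | None = None,
) -> pd.DataFrame:
    """Scalar trial-level dataset of one subject's session (all 5 tasks,
    both sides). Session 2 adds the configured systematic shift, oriented so
    positive shift = worse performance on retest.

    ``subject_re`` carries the per-(metric, side) subject random effects so
    that the two sessions of one subject share them; when omitted they are
    drawn here from a session-independent substream.
    """
    group = subject["group"]
    sides = sides or _sides_for(group)
    if subject_re is None:
        subject_re = draw_subject_effects(subject, config, seed)
    rows = []
    for side in sides:
        cell_rng = np.random.default_rng(np.random.SeedSequence(
            (int(seed), _stable_id(subject["subject_id"]), int(session),
             _stable_id(side))))
        for task, layout in _TASK_LAYOUT:
            trial_base = 0
            for condition, n_trials, metric in layout:
                m = config.metrics[metric]
                mu = subject_level_mean(config, metric, subject, side,
                                        subject_re[(metric, side)])
                sess_mu = mu + cell_rng.normal(0.0, m.session_sd)
                if session == 2 and m.shift != 0.0:
                    sess_mu += config.worse_sign(metric) * m.shift
                sess_mu = float(_clip(sess_mu, m.floor, m.cap))
                if task == "matching":
                    presented, reported = _matching_trials(config, sess_mu,
                                                           cell_rng)
                    values = np.full(n_trials, np.nan)
                elif metric in ("VelFlex", "VelExt"):
                    # debias the top-3-of-10 aggregate
                    center = sess_mu - top_k_of_n_normal_mean() * m.trial_sd
                    values = np.clip(
                        center + cell_rng.normal(0, m.trial_sd, n_trials),
                        0.0, None)
                    presented = reported = np.full(n_trials, np.nan)
                else:
                    values = _clip(
                        sess_mu + cell_rng.normal(0, m.trial_sd, n_trials),
                        max(m.floor, 0.0) if higher_is_worse(metric) else 0.0,
                        m.cap)
                    presented = reported = np.full(n_trials, np.nan)
                for k in range(n_trials):
                    rows.append(dict(
                        subject_id=subject["subject_id"], side=side,
                        session=int(session), task=task, condition=condition,
                        trial_idx=trial_base + k,
                        presented_deg=float(presented[k]),
                        reported_deg=float(reported[k]),
                        value=float(values[k]),
                    ))
                trial_base += n_trials
    return pd.DataFrame(rows)


def _stable_id(text: str) -> int:
    return sum((i + 1) * ord(c) for i, c in enumerate(str(text))) % (2 ** 20)


def draw_subject_effects(
    subject: pd.Series, config: GeneratorConfig, seed: int
) -> dict:
    """Per-(metric, side) between-subject random effects, shared across
    sessions, from a subject-specific substream."""
    rng = np.random.default_rng(np.random.SeedSequence(
        (int(seed), _stable_id(subject["subject_id"]), 0xE)))
    out = {}
    for metric in config.metrics:
        sd_ctrl = config.metrics[metric].control_sd
        sd_stroke = config.stroke_subject_sd(metric)
        for side in _sides_for(subject["group"]):
            sd = sd_stroke if subject["group"] == "stroke" else sd_ctrl
            out[(metric, side)] = float(rng.normal(0.0, sd))
    return out


def simulate_trials(
    cohort: pd.DataFrame, config: GeneratorConfig, seed: int
) -> pd.DataFrame:
    """Full scalar trial table of a cohort: stroke subjects over
    ``n_sessions_stroke`` sessions, controls over ``n_sessions_control``."""
    frames = []
    for _, subject in cohort.iterrows():
        n_sessions = config.n_sessions_stroke if subject["group"] == "stroke" \
            else config.n_sessions_control
        re = draw_subject_effects(subject, config, seed)
        for session in range(1, n_sessions + 1):
            frames.append(simulate_session(subject, session, config, seed,
                                           subject_re=re))
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (subjects, trials) for one simulated cohort."""
    cohort = sample_cohort(config, seed)
    trials = simulate_trials(cohort, config, seed)
    return cohort, trials


def expected_trial_rows(config: GeneratorConfig) -> int:
    """Closed-form row count of the scalar trial table."""
    per_assessment = sum(TRIALS_PER_TASK.values())
    return per_assessment * 2 * (
        config.n_stroke * config.n_sessions_stroke
        + config.n_control * config.n_sessions_control)


# ---------------------------------------------------------------------------
# Raw-trace synthesis
# ---------------------------------------------------------------------------

def synthesize_reaching_trace(
    peak_degps: float, direction: str, time_to_peak_s: float,
    fs_hz: float = 1000.0, window_s: float = protocols.REACHING_WINDOW_S,
    onset_s: float = 0.4,
) -> protocols.TrialTrace:
    """Bell-shaped velocity pulse of one ballistic reaching trial.

    The velocity profile is a Gaussian pulse of the requested peak speed,
    signed by movement direction; its width is set so the travelled distance
    does not exceed the 40 deg start-to-target span, and the integrated
    position is saturated to the device workspace.
    """
    stim = protocols.reaching_stimulus(direction)
    n = int(round(window_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    sign = 1.0 if direction == "flexion" else -1.0
    if peak_degps <= 0:
        v = np.zeros(n)
    else:
        width = min(0.12, 40.0 / (peak_degps * math.sqrt(2.0 * math.pi)))
        center = onset_s + max(time_to_peak_s, 0.01)
        v = sign * peak_degps * np.exp(-((t - center) ** 2)
                                       / (2.0 * width ** 2))
    pos = stim.start_deg + np.cumsum(v) / fs_hz
    pos, _ = protocols.saturate_position(pos)
    return protocols.TrialTrace(fs_hz=fs_hz, position_deg=pos,
                                velocity_degps=v)


def synthesize_rom_trace(
    rom_deg: float, fs_hz: float = 1000.0, duration_s: float = 4.0,
    center_deg: float = 15.0,
) -> protocols.TrialTrace:
    """One ROM repetition: smooth excursion to maximum flexion, then to
    maximum extension, then back toward the center."""
    flex_max = min(center_deg + 0.55 * rom_deg, protocols.WORKSPACE_DEG[1])
    ext_min = flex_max - rom_deg
    n = int(round(duration_s * fs_hz)) + 1
    t = np.linspace(0.0, 1.0, n)
    # piecewise half-cosine: center -> flex_max (0..0.3) -> ext_min (0.3..0.75)
    # -> center (0.75..1)
    pos = np.empty(n)
    seg1 = t <= 0.3
    seg2 = (t > 0.3) & (t <= 0.75)
    seg3 = t > 0.75
    u = t[seg1] / 0.3
    pos[seg1] = center_deg + (flex_max - center_deg) * 0.5 * (1 - np.cos(np.pi * u))
    u = (t[seg2] - 0.3) / 0.45
    pos[seg2] = flex_max + (ext_min - flex_max) * 0.5 * (1 - np.cos(np.pi * u))
    u = (t[seg3] - 0.75) / 0.25
    pos[seg3] = ext_min + (center_deg - ext_min) * 0.5 * (1 - np.cos(np.pi * u))
    pos, _ = protocols.saturate_position(pos)
    return protocols.TrialTrace(fs_hz=fs_hz, position_deg=pos)


def synthesize_force_trace(
    peak_n: float, direction: str, fs_hz: float = 1000.0,
    rise_s: float = 0.5, hold_s: float = 3.0,
) -> protocols.TrialTrace:
    """Maximum-force trial: smooth rise to a plateau at the requested peak,
    3 s hold, release. The force channel is signed (flexion positive)."""
    sign = 1.0 if direction == "flexion" else -1.0
    total = rise_s + hold_s + rise_s
    n = int(round(total * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    env = np.ones(n)
    rise = t < rise_s
    env[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / rise_s))
    fall = t > rise_s + hold_s
    env[fall] = 0.5 * (1 + np.cos(np.pi * np.clip(
        (t[fall] - rise_s - hold_s) / rise_s, 0, 1)))
    force = sign * peak_n * env
    pos = np.full(n, 15.0)  # end-effector blocked at 15 deg flexion
    return protocols.TrialTrace(fs_hz=fs_hz, position_deg=pos, force_n=force)


def _tracking_base_rms(spec: protocols.TrajectorySpec, gain: float,
                       lag_s: float) -> float:
    """Closed-form RMS deviation of a lagged, gain-scaled multi-sine response
    (tremor excluded): each component contributes
    a^2 (1 + g^2 - 2 g cos(2 pi f tau)) / 2."""
    ms = 0.0
    for f, a in zip(spec.component_freqs_hz, spec.component_amp_deg):
        ms += a ** 2 * (1.0 + gain ** 2
                        - 2.0 * gain * math.cos(2.0 * math.pi * f * lag_s)) / 2.0
    return math.sqrt(ms)


def synthesize_tracking_trial(
    rmse_target: float, severity: float, speed: str,
    rng: np.random.Generator, config: GeneratorConfig,
    fs_hz: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(target, response) pair of one tracking trial realizing a requested
    RMSE.

    The response follows ``center + gain * (target(t - lag) - center) +
    tremor``; gain loss and lag grow with the governing severity. When the
    severity-implied deterministic deviation already exceeds the requested
    RMSE, the degradation is scaled back by bisection; otherwise white
    tremor makes up the remaining error power.
    """
    spec = protocols.trajectory_preset(speed)
    t, target = protocols.generate_target_trajectory(spec, fs_hz)
    tp = config.trace

    def params(u: float) -> tuple[float, float]:
        g = max(0.0, 1.0 - tp.track_gain_slope * severity * u)
        lag = tp.track_lag_slope * severity * u
        return g, lag

    g, lag = params(1.0)
    base = _tracking_base_rms(spec, g, lag)
    if base > rmse_target:
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _tracking_base_rms(spec, *params(mid)) > rmse_target:
                hi = mid
            else:
                lo = mid
        g, lag = params(lo)
        base = _tracking_base_rms(spec, g, lag)
    tremor_sd = math.sqrt(max(rmse_target ** 2 - base ** 2, 0.0))
    lagged = np.interp(t - lag, t, target, left=target[0])
    response = (spec.center_deg + g * (lagged - spec.center_deg)
                + rng.normal(0.0, tremor_sd, t.size))
    response, _ = protocols.saturate_position(response)
    return target, response


def simulate_session_traces(
    subject: pd.Series,
    session: int,
    config: GeneratorConfig,
    seed: int,
    side: str = "affected",
) -> dict:
    """Raw-trace realization of one subject x side x session.

    Returns a dict with per-task trial lists whose extracted metrics are
    consistent with the scalar mode: ``matching`` (presented, reported)
    pairs, ``reaching`` (direction, TrialTrace), ``rom`` (mode, TrialTrace),
    ``force`` (direction, TrialTrace), ``tracking`` (speed, target,
    response).
    """
    scalars = simulate_session(subject, session, config, seed, sides=(side,))
    rng = np.random.default_rng(np.random.SeedSequence(
        (int(seed), _stable_id(subject["subject_id"]), int(session),
         _stable_id(side), 0x7)))
    tp = config.trace
    ttp_mean, ttp_sd = (tp.time_to_peak_stroke
                        if subject["group"] == "stroke"
                        else tp.time_to_peak_control)
    out: dict = {"matching": [], "reaching": [], "rom": [], "force": [],
                 "tracking": []}
    for row in scalars.itertuples():
        if row.task == "matching":
            out["matching"].append((row.presented_deg, row.reported_deg))
        elif row.task == "reaching":
            ttp = max(0.02, rng.normal(ttp_mean, ttp_sd))
            out["reaching"].append((row.condition, synthesize_reaching_trace(
                row.value, row.condition, ttp, fs_hz=tp.fs_hz,
                onset_s=tp.reach_onset_s)))
        elif row.task == "rom":
            out["rom"].append((row.condition,
                               synthesize_rom_trace(row.value, fs_hz=tp.fs_hz)))
        elif row.task == "force":
            out["force"].append((row.condition, synthesize_force_trace(
                row.value, row.condition, fs_hz=tp.fs_hz,
                rise_s=tp.force_rise_s, hold_s=tp.force_hold_s)))
        else:
            metric = "RMSESlow" if row.condition == "slow" else "RMSEFast"
            sev = _side_severity(config, metric, subject, side)
            target, response = synthesize_tracking_trial(
                row.value, sev, row.condition, rng, config)
            out["tracking"].append((row.condition, target, response))
    return out


# ---------------------------------------------------------------------------
# Dataset export / import
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = (
    "subject_id", "group", "age", "gender", "handedness", "affected_side",
    "s_motor", "s_proprio", "FMA", "kUDT", "BBT_affected",
    "BBT_less_affected", "MoCA", "MAS",
)


def export_dataset(subjects: pd.DataFrame, trials: pd.DataFrame,
                   directory) -> tuple[str, str]:
    """Write subjects.csv and trials.csv; returns the two paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spath = directory / "subjects.csv"
    tpath = directory / "trials.csv"
    subjects.to_csv(spath, index=False)
    trials.to_csv(tpath, index=False)
    return str(spath), str(tpath)


def read_dataset(directory) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dataset written by :func:`export_dataset`."""
    from pathlib import Path

    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv",
                           keep_default_na=True)
    subjects["affected_side"] = subjects["affected_side"].fillna("")
    trials = pd.read_csv(directory / "trials.csv")
    return subjects, trials
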