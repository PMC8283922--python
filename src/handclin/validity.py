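"""Discriminant and concurrent validity, normative z-scores, independence.

The validity analysis compares each robotic metric across three groups
(control hands, the affected and the less-affected side of stroke subjects),
quantifies separation with rank statistics (Kruskal-Wallis, ROC AUC),
classifies individual stroke subjects as impaired against a confound-adjusted
normative control reference, relates the metrics to clinical scores
(FMA, BBT, kUDT) with Spearman correlations, and checks independence between
task categories with partial Spearman correlations.

Confound removal follows a normative-modelling scheme: a linear mixed-effects
model with subject random intercept is fitted per task on control trial-level
data (fixed effects: age, gender, tested hand, the task-specific effect and
trial number); the fixed-effect contributions are subtracted before z-scoring
patients against the adjusted control distribution. By default this
adjustment is applied to motor-category metrics only, which are the ones the
confounds demonstrably load on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .task_metrics import METRICS, _aggregate, higher_is_worse

logger = logging.getLogger("handclin")

#: Discriminant-validity threshold: a metric separates two groups if AUC > 0.7.
AUC_THRESHOLD = 0.7
#: Clinical impairment cut-offs.
FMA_CUTOFF = 60.0   # impaired if FMA < 60
KUDT_CUTOFF = 2.0   # impaired if kUDT < 2
#: Number of pairwise group comparisons behind the Bonferroni correction.
N_PAIRWISE = 3
#: Normative impairment rule: worse than this percentile of controls.
IMPAIRMENT_PERCENTILE = 95.0

#: Correlation-strength bands on |rho|.
STRENGTH_BANDS = ((0.1, "negligible"), (0.4, "weak"), (0.7, "moderate"),
                  (np.inf, "strong"))

#: Default metric selected per task for the independence analysis (the most
#: reliable/valid metric of each task, one per task category).
DEFAULT_INDEPENDENCE_METRICS = ("AE", "VelExt", "AROM", "ForceFlex", "RMSESlow")


def correlation_strength(rho: float) -> str:
    """Label the strength of a correlation coefficient by |rho| bands."""
    a = abs(rho)
    if a < 0.1:
        return "negligible"
    if a < 0.4:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# Rank-based group comparisons
# ---------------------------------------------------------------------------

def kruskal_bonferroni(groups: list[np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test plus Bonferroni-corrected pairwise tests.

    Pairwise follow-up p-values are multiplied by the number of pairwise
    comparisons (3 for the three-group design) and capped at 1. Groups with
    all values identical across the board take the no-separation path
    (H = 0, p = 1) and are flagged.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(g.size > 0 for g in groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)

    def _kw(*gs):
        if np.ptp(np.concatenate(gs)) == 0.0:  # no separation possible
            return 0.0, 1.0, True
        try:
            h, p = stats.kruskal(*gs)
        except ValueError:
            return 0.0, 1.0, True
        if not np.isfinite(h):
            return 0.0, 1.0, True
        return float(h), float(p), False

    h, p, degenerate = _kw(*groups)
    pairwise = {}
    m = N_PAIRWISE
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            _, p_raw, _ = _kw(groups[i], groups[j])
            pairwise[(i, j)] = min(1.0, p_raw * m)
    return dict(h=h, p=p, pairwise_p=pairwise, degenerate=degenerate,
                n=pooled.size)


def roc_auc(
    control_values: np.ndarray,
    patient_values: np.ndarray,
    metric: str | None = None,
    higher_worse: bool | None = None,
) -> float:
    """ROC area: probability a random patient value is worse than a random
    control value, ties counted 1/2 (equivalently Mann-Whitney U / (n1*n2)).

    Oriented through the metric's direction-of-better so AUC > 0.5 always
    means the patient group performs worse.
    """
    a = np.asarray(control_values, dtype=float)
    b = np.asarray(patient_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if higher_worse is None:
        if metric is None:
            raise ValueError("pass either metric or higher_worse")
        higher_worse = higher_is_worse(metric)
    sign = 1.0 if higher_worse else -1.0
    combined = sign * np.concatenate([b, a])
    ranks = stats.rankdata(combined)
    r_b = ranks[: b.size].sum()
    u_b = r_b - b.size * (b.size + 1) / 2.0  # U of patients on the worse scale
    return float(u_b / (a.size * b.size))


def paired_sides_test(
    affected: np.ndarray, less_affected: np.ndarray, metric: str
) -> dict:
    """Per-subject comparison of the two body sides.

    Two-sided paired t-test on the per-subject differences, plus the AUC of
    the affected vs. the less-affected distributions (oriented so AUC > 0.5
    means the affected side is worse). Zero-variance differences are handled
    explicitly: all-zero -> (t=0, p=1); constant non-zero -> p ~ 0, flagged.
    """
    a = np.asarray(affected, dtype=float)
    la = np.asarray(less_affected, dtype=float)
    if a.size != la.size or a.size < 2:
        raise ValueError("paired test needs >=2 matched pairs")
    diffs = a - la
    flagged = False
    if np.ptp(diffs) == 0.0:
        flagged = True
        if diffs[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            t = float(np.inf * np.sign(diffs[0]))
            p = 0.0
    else:
        t, p = stats.ttest_rel(a, la)
        t, p = float(t), float(p)
    auc = roc_auc(la, a, metric=metric)
    return dict(t=t, p=p, auc=auc, n=a.size, degenerate=flagged)


# ---------------------------------------------------------------------------
# Confound modelling (normative LME on controls)
# ---------------------------------------------------------------------------

#: Fixed-effect covariates of the confound model, in design order.
CONFOUND_TERMS = ("age", "female", "left_hand", "task_effect", "trial")

#: Model-quality rules on the C1/C2 residual criteria (% of observed range).
QUALITY_RULES = (("good", 10.0, 20.0), ("moderate", 15.0, 25.0))


@dataclass
class ConfoundModel:
    """Fitted normative confound model of one task's trial-level values."""

    task: str
    coef: dict[str, float]
    se: dict[str, float]
    tstat: dict[str, float]
    pvalue: dict[str, float]
    reference: dict[str, float]
    c1: float
    c2: float
    quality: str
    method: str
    dropped: tuple[str, ...] = ()

    def significant(self, term: str, alpha: float = 0.05) -> bool:
        return self.pvalue.get(term, 1.0) < alpha

    def adjustment(self, covariates: pd.DataFrame) -> np.ndarray:
        """Fixed-effect offset of each row relative to the reference point."""
        offset = np.zeros(len(covariates))
        for term in CONFOUND_TERMS:
            if term in self.coef:
                x = covariates[term].to_numpy(dtype=float)
                offset += self.coef[term] * (x - self.reference[term])
        return offset


def _quality_label(c1: float, c2: float) -> str:
    for label, c1_max, c2_max in QUALITY_RULES:
        if c1 <= c1_max and c2 <= c2_max:
            return label
    return "poor"


def fit_confound_model(control_trials: pd.DataFrame, task: str) -> ConfoundModel:
    """Fit the normative mixed-effects model on control trial-level values.

    ``control_trials`` must carry columns value, subject_id and the covariates
    age, female, left_hand, task_effect, trial. The model has a subject random
    intercept; per-effect significance is judged with the t-statistic. The C1
    and C2 quality criteria are the mean and the SD of the absolute residuals,
    as a percentage of the observed value range.

    Zero-variance (collinear/constant) design columns are dropped with a
    warning. When the mixed model cannot be estimated (for example on
    noiseless data with zero residual variance) the fixed effects fall back
    to an ordinary least-squares fit.
    """
    import statsmodels.api as sm

    df = control_trials.dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError("no control data to fit the confound model on")
    y = df["value"].to_numpy(dtype=float)
    terms = [t for t in CONFOUND_TERMS if t in df.columns]
    dropped = tuple(t for t in terms if np.ptp(df[t].to_numpy(dtype=float)) == 0.0)
    if dropped:
        logger.warning("confound model %s: dropping constant terms %s",
                       task, dropped)
    terms = [t for t in terms if t not in dropped]
    X = df[terms].to_numpy(dtype=float)
    reference = {t: float(df[t].mean()) for t in terms}
    Xc = X - np.array([reference[t] for t in terms])[None, :]
    exog = np.column_stack([np.ones(len(df)), Xc])
    names = ["intercept"] + terms

    method = "mixedlm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=df["subject_id"].to_numpy())
            fit = model.fit(reml=True)
            params = np.asarray(fit.fe_params, dtype=float)
            bse = np.asarray(fit.bse_fe, dtype=float)
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
            raise ValueError("non-finite mixed-model estimates")
        fitted = exog @ params
    except Exception:  # degenerate variance structure -> fixed-effects fit
        method = "ols"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(y, exog).fit()
        params = np.asarray(fit.params, dtype=float)
        bse = np.asarray(fit.bse, dtype=float)
        fitted = exog @ params

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=max(len(df) - exog.shape[1], 1))
    pvals = np.where(np.isfinite(tvals), pvals, np.where(params == 0.0, 1.0, 0.0))

    resid = y - fitted
    rng_ = float(np.ptp(y))
    if rng_ > 0:
        c1 = 100.0 * float(np.mean(np.abs(resid))) / rng_
        c2 = 100.0 * float(np.std(np.abs(resid), ddof=0)) / rng_
    else:
        c1 = c2 = 0.0
    return ConfoundModel(
        task=task,
        coef=dict(zip(names, params.tolist())),
        se=dict(zip(names, bse.tolist())),
        tstat=dict(zip(names, np.asarray(tvals, dtype=float).tolist())),
        pvalue=dict(zip(names, np.asarray(pvals, dtype=float).tolist())),
        reference=reference,
        c1=c1, c2=c2, quality=_quality_label(c1, c2),
        method=method, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Normative z-scores and impairment classification
# ---------------------------------------------------------------------------

def adjust_values(
    values: np.ndarray,
    covariates: pd.DataFrame,
    model: ConfoundModel | None,
) -> np.ndarray:
    """Remove fixed-effect confound contributions from trial-level values.

    With ``model=None`` the values pass through unchanged (the default for
    non-motor metrics). Covariates outside the model's fitted support produce
    an extrapolation warning but are still adjusted linearly.
    """
    values = np.asarray(values, dtype=float)
    if model is None:
        return values
    for term in model.reference:
        if term in ("age",) and term in covariates:
            x = covariates[term].to_numpy(dtype=float)
            lo, hi = model.reference[term] - 3 * 14.0, model.reference[term] + 3 * 14.0
            if np.any((x < lo) | (x > hi)):
                logger.warning("confound adjustment extrapolates beyond the "
                               "control %s support", term)
    return values - model.adjustment(covariates)


@dataclass
class NormativeReference:
    """Adjusted control distribution one metric is z-scored against."""

    metric: str
    mean: float
    sd: float
    threshold_z: float   # strict '>' on the worse-oriented z scale
    n: int


def zscore_worse(
    adjusted_values: np.ndarray, reference: NormativeReference
) -> np.ndarray:
    """Worse-oriented z-scores against the adjusted control reference.

    z = (value - control mean) / control SD, sign-flipped for
    higher-is-better metrics so that larger z always means worse performance.
    """
    v = np.asarray(adjusted_values, dtype=float)
    z = (v - reference.mean) / reference.sd
    if not higher_is_worse(reference.metric):
        z = -z
    return z


def build_reference(
    metric: str, control_adjusted: np.ndarray,
    percentile: float = IMPAIRMENT_PERCENTILE,
) -> NormativeReference:
    """Normative reference from the adjusted control session scores.

    The impairment threshold is the empirical ``percentile`` of the controls'
    worse-oriented z-scores; a subject is impaired iff strictly beyond it.
    The quantile uses the Weibull plotting position (i/(n+1)), whose expected
    exceedance for a new intact subject equals the nominal 5% tail.
    """
    v = np.asarray(control_adjusted, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.std(v, ddof=1) == 0.0:
        raise ValueError(f"degenerate control reference for {metric}")
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    ref = NormativeReference(metric, mean, sd, float("nan"), v.size)
    z_ctrl = zscore_worse(v, ref)
    thr = float(np.quantile(z_ctrl, percentile / 100.0, method="weibull"))
    return NormativeReference(metric, mean, sd, thr, v.size)


def classify_impaired(z_worse: np.ndarray, reference: NormativeReference
                      ) -> np.ndarray:
    """Impairment calls: strictly worse than the control 95th percentile."""
    return np.asarray(z_worse, dtype=float) > reference.threshold_z


def classify_and_agree(
    robot_impaired: pd.Series, clinical_scores: pd.Series, cutoff: float
) -> dict:
    """% impaired by the robotic z-scores and % agreement with a clinical rule.

    Clinical impairment is ``score < cutoff`` (FMA < 60, kUDT < 2). Subjects
    with a missing clinical score are excluded from the agreement but still
    counted in the robotic % impaired.
    """
    robot = robot_impaired.dropna().astype(bool)
    pct_impaired = 100.0 * robot.mean() if len(robot) else float("nan")
    clin = clinical_scores.reindex(robot.index)
    both = clin.notna()
    if both.sum() == 0:
        return dict(pct_impaired=float(pct_impaired),
                    pct_agreement=float("nan"), n=len(robot), n_agree=0)
    clin_impaired = clin[both] < cutoff
    agree = 100.0 * float((robot[both] == clin_impaired).mean())
    return dict(pct_impaired=float(pct_impaired), pct_agreement=agree,
                n=len(robot), n_agree=int(both.sum()))


def concurrent_correlations(
    metric_values: pd.Series, clinical: pd.DataFrame,
    scores: tuple[str, ...] = ("FMA", "BBT", "kUDT"),
) -> dict[str, dict]:
    """Spearman correlation of one metric with each clinical score + label."""
    out = {}
    for score in scores:
        paired = pd.concat([metric_values, clinical[score]], axis=1).dropna()
        if len(paired) < 3:
            out[score] = dict(rho=float("nan"), p=float("nan"), label="n/a",
                              n=len(paired))
            continue
        x = paired.iloc[:, 0].to_numpy(dtype=float)
        y = paired.iloc[:, 1].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            logger.warning("concurrent correlation undefined for %s: "
                           "constant input", score)
            out[score] = dict(rho=float("nan"), p=float("nan"),
                              label="undefined", n=len(paired))
            continue
        rho, p = stats.spearmanr(x, y)
        out[score] = dict(rho=float(rho), p=float(p),
                          label=correlation_strength(float(rho)), n=len(paired))
    return out


# ---------------------------------------------------------------------------
# Independence: partial Spearman correlations
# ---------------------------------------------------------------------------

def partial_spearman(
    data: pd.DataFrame, covariate_mode: str = "rest"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise partial Spearman correlations between selected metrics.

    All variables are rank-transformed, then for each pair the correlation is
    computed on the residuals of a least-squares projection onto the
    controlling set (default: all remaining selected metrics). p-values use
    the t-approximation with n - 2 - g degrees of freedom (g controlled
    variables). Complete cases only. Singular controlling designs flag the
    pair with NaN.
    """
    df = data.dropna()
    cols = list(df.columns)
    n = len(df)
    if n < len(cols) + 2:
        raise ValueError("too few complete cases for the partial correlation")
    ranks = df.apply(lambda c: stats.rankdata(c.to_numpy(dtype=float)))
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols,
                         columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            others = [c for c in cols if c not in (ci, cj)] \
                if covariate_mode == "rest" else []
            xi = ranks[ci].to_numpy(dtype=float)
            xj = ranks[cj].to_numpy(dtype=float)
            if others:
                Z = np.column_stack(
                    [np.ones(n)] + [ranks[c].to_numpy(dtype=float) for c in others]
                )
                try:
                    xi = xi - Z @ np.linalg.lstsq(Z, xi, rcond=None)[0]
                    xj = xj - Z @ np.linalg.lstsq(Z, xj, rcond=None)[0]
                except np.linalg.LinAlgError:
                    rho.loc[ci, cj] = rho.loc[cj, ci] = float("nan")
                    pvals.loc[ci, cj] = pvals.loc[cj, ci] = float("nan")
                    continue
            denom = np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
            if denom == 0.0:
                r = float("nan")
            else:
                r = float((xi * xj).sum() / denom)
            g = len(others)
            dof = n - 2 - g
            if np.isfinite(r) and dof > 0 and abs(r) < 1.0:
                t = r * np.sqrt(dof / (1.0 - r ** 2))
                p = float(2.0 * stats.t.sf(abs(t), dof))
            else:
                p = 0.0 if (np.isfinite(r) and abs(r) >= 1.0) else float("nan")
            rho.loc[ci, cj] = rho.loc[cj, ci] = r
            pvals.loc[ci, cj] = pvals.loc[cj, ci] = p
    return rho, pvals


# ---------------------------------------------------------------------------
# Assembly: trial-level analysis frame and the per-metric validity report
# ---------------------------------------------------------------------------

def hand_of(subject_row: pd.Series, side: str) -> str:
    """Physical hand (left/right) tested for a given side role."""
    if side == "affected":
        return subject_row["affected_side"]
    if side == "less_affected":
        return "left" if subject_row["affected_side"] == "right" else "right"
    if side == "dominant":
        return "right" if subject_row["handedness"] == "right" else "left"
    if side == "nondominant":
        return "left" if subject_row["handedness"] == "right" else "right"
    raise ValueError(f"unknown side role {side!r}")


def analysis_frame(trials: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Trial-level frame with per-trial metric values and model covariates.

    Adds: metric, per-trial value (absolute error for matching), age, female,
    left_hand (tested hand), task_effect (direction/speed/mode indicator, or
    the presented-angle magnitude for matching) and trial (trial index).
    """
    from .task_metrics import metric_name

    subj = subjects.set_index("subject_id")
    df = trials.copy()
    df["metric"] = [metric_name(t, c) for t, c in zip(df["task"], df["condition"])]
    is_match = (df["task"] == "matching").to_numpy()
    value = df["value"].to_numpy(dtype=float)
    value[is_match] = np.abs(
        df.loc[is_match, "reported_deg"].astype(float).to_numpy()
        - df.loc[is_match, "presented_deg"].astype(float).to_numpy()
    )
    df["value"] = value
    df["age"] = subj.loc[df["subject_id"], "age"].to_numpy(dtype=float)
    df["female"] = (subj.loc[df["subject_id"], "gender"] == "female"
                    ).to_numpy(dtype=float)
    df["group"] = subj.loc[df["subject_id"], "group"].to_numpy()
    hands = [
        hand_of(subj.loc[s], side) for s, side in zip(df["subject_id"], df["side"])
    ]
    df["left_hand"] = (np.asarray(hands) == "left").astype(float)
    effect = np.zeros(len(df))
    effect[is_match] = df.loc[is_match, "presented_deg"].astype(float).to_numpy()
    second = df["condition"].isin(["extension", "passive", "fast"]).to_numpy()
    effect[~is_match] = second[~is_match].astype(float)
    df["task_effect"] = effect
    df["trial"] = df["trial_idx"].astype(float)
    return df


def fit_confound_models(frame: pd.DataFrame) -> dict[str, ConfoundModel]:
    """One normative confound model per task, fitted on control trials only."""
    models = {}
    ctrl = frame[frame["group"] == "control"]
    for task in sorted(ctrl["task"].unique()):
        models[task] = fit_confound_model(ctrl[ctrl["task"] == task], task)
    return models


def adjusted_session_scores(
    frame: pd.DataFrame,
    metric: str,
    model: ConfoundModel | None,
    session: int = 1,
) -> pd.DataFrame:
    """Confound-adjusted session scores per subject x side for one metric.

    Trial-level values are adjusted (all confound terms removed, including
    trial number), then aggregated with the metric's own rule (top-3 mean for
    reaching peak velocity, mean otherwise).
    """
    sub = frame[(frame["metric"] == metric) & (frame["session"] == session)]
    rows = []
    for (sid, side), grp in sub.groupby(["subject_id", "side"], sort=True):
        adj = adjust_values(grp["value"].to_numpy(dtype=float), grp, model)
        mv = _aggregate(metric, adj)
        rows.append(dict(subject_id=sid, side=side, group=grp["group"].iloc[0],
                         value=mv.value, n_trials=mv.n_trials))
    return pd.DataFrame(rows)


#: Control side roles pooled as the normative reference (both hands).
CONTROL_SIDES = ("dominant", "nondominant")


def validity_report(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    adjust_all_metrics: bool = False,
    independence_metrics: tuple[str, ...] = DEFAULT_INDEPENDENCE_METRICS,
) -> dict:
    """Full validity analysis of session-1 scores.

    Returns a dict with:

    * ``metrics``: per-metric DataFrame (group means, Kruskal-Wallis +
      Bonferroni pairwise p, AUCs for the three group contrasts, paired
      side-vs-side t-test, % impaired per side, classification agreement
      with FMA/kUDT, Spearman correlations with FMA/BBT/kUDT + strength),
    * ``confound_models``: the per-task normative models (controls only),
    * ``partial_rho`` / ``partial_p``: the independence matrices,
    * ``zscores``: long frame of worse-oriented z-scores per stroke
      subject x side x metric.
    """
    frame = analysis_frame(trials, subjects)
    models = fit_confound_models(frame)
    subj = subjects.set_index("subject_id")
    stroke_ids = subj.index[subj["group"] == "stroke"]

    rows, zrows = [], []
    affected_scores: dict[str, pd.Series] = {}
    for metric, info in METRICS.items():
        if metric not in set(frame["metric"]):
            rows.append(dict(metric=metric, available=False))
            continue
        task = info["task"]
        use_model = adjust_all_metrics or info["category"] == "motor"
        model = models.get(task) if use_model else None

        scores = adjusted_session_scores(frame, metric, model)
        ctrl = scores[(scores["group"] == "control")
                      & scores["side"].isin(CONTROL_SIDES)]
        aff = scores[scores["side"] == "affected"].set_index("subject_id")
        la = scores[scores["side"] == "less_affected"].set_index("subject_id")

        # Unadjusted raw session scores for the group comparisons (the
        # adjustment only matters for the normative z-scores).
        raw = adjusted_session_scores(frame, metric, None)
        raw_ctrl = raw[(raw["group"] == "control")
                       & raw["side"].isin(CONTROL_SIDES)]["value"].to_numpy()
        raw_aff_s = raw[raw["side"] == "affected"].set_index("subject_id")["value"]
        raw_la_s = raw[raw["side"] == "less_affected"].set_index("subject_id")["value"]
        raw_aff = raw_aff_s.dropna().to_numpy()
        raw_la = raw_la_s.dropna().to_numpy()

        kw = kruskal_bonferroni([raw_ctrl, raw_aff, raw_la])
        auc_ca = roc_auc(raw_ctrl, raw_aff, metric=metric)
        auc_cla = roc_auc(raw_ctrl, raw_la, metric=metric)
        paired_ids = raw_aff_s.dropna().index.intersection(raw_la_s.dropna().index)
        paired = paired_sides_test(
            raw_aff_s.loc[paired_ids].to_numpy(),
            raw_la_s.loc[paired_ids].to_numpy(), metric,
        )

        reference = build_reference(metric, ctrl["value"].to_numpy(dtype=float))
        z_aff = pd.Series(
            zscore_worse(aff["value"].to_numpy(dtype=float), reference),
            index=aff.index)
        z_la = pd.Series(
            zscore_worse(la["value"].to_numpy(dtype=float), reference),
            index=la.index)
        imp_aff = pd.Series(classify_impaired(z_aff.to_numpy(), reference),
                            index=z_aff.index, dtype=object)
        imp_la = pd.Series(classify_impaired(z_la.to_numpy(), reference),
                           index=z_la.index, dtype=object)
        for sid in z_aff.index:
            zrows.append(dict(subject_id=sid, side="affected", metric=metric,
                              z=float(z_aff[sid]), impaired=bool(imp_aff[sid])))
        for sid in z_la.index:
            zrows.append(dict(subject_id=sid, side="less_affected",
                              metric=metric, z=float(z_la[sid]),
                              impaired=bool(imp_la[sid])))

        clinical = subj.loc[subj.index.intersection(stroke_ids),
                            ["FMA", "kUDT", "BBT_affected", "MoCA"]]
        agree_fma = classify_and_agree(imp_aff, clinical["FMA"], FMA_CUTOFF)
        agree_kudt = classify_and_agree(imp_aff, clinical["kUDT"], KUDT_CUTOFF)

        conc = concurrent_correlations(
            raw_aff_s,
            clinical.rename(columns={"BBT_affected": "BBT"}),
        )
        affected_scores[metric] = raw_aff_s

        rows.append(dict(
            metric=metric, available=True, category=info["category"],
            n_control=len(ctrl), n_affected=len(aff), n_less_affected=len(la),
            mean_control=float(np.mean(raw_ctrl)),
            sd_control=float(np.std(raw_ctrl, ddof=1)),
            mean_affected=float(np.mean(raw_aff)),
            sd_affected=float(np.std(raw_aff, ddof=1)),
            mean_less_affected=float(np.mean(raw_la)),
            sd_less_affected=float(np.std(raw_la, ddof=1)),
            kw_h=kw["h"], kw_p=kw["p"],
            p_control_vs_affected=kw["pairwise_p"][(0, 1)],
            p_control_vs_less_affected=kw["pairwise_p"][(0, 2)],
            p_affected_vs_less_affected=kw["pairwise_p"][(1, 2)],
            auc_control_vs_affected=auc_ca,
            auc_control_vs_less_affected=auc_cla,
            auc_sides=paired["auc"],
            paired_t=paired["t"], paired_p=paired["p"],
            pct_impaired_affected=agree_fma["pct_impaired"],
            pct_impaired_less_affected=(
                100.0 * float(imp_la.astype(bool).mean()) if len(imp_la)
                else float("nan")),
            agree_fma_pct=agree_fma["pct_agreement"],
            agree_kudt_pct=agree_kudt["pct_agreement"],
            rho_fma=conc["FMA"]["rho"], p_fma=conc["FMA"]["p"],
            strength_fma=conc["FMA"]["label"],
            rho_bbt=conc["BBT"]["rho"], p_bbt=conc["BBT"]["p"],
            strength_bbt=conc["BBT"]["label"],
            rho_kudt=conc["kUDT"]["rho"], p_kudt=conc["kUDT"]["p"],
            strength_kudt=conc["kUDT"]["label"],
            confound_adjusted=use_model,
            model_quality=models[task].quality if task in models else "n/a",
            discriminative=bool(auc_ca > AUC_THRESHOLD),
        ))

    available = [m for m in independence_metrics if m in affected_scores]
    if len(available) >= 3:
        wide = pd.DataFrame({m: affected_scores[m] for m in available})
        partial_rho, partial_p = partial_spearman(wide)
    else:
        partial_rho = partial_p = pd.DataFrame()

    return dict(
        metrics=pd.DataFrame(rows),
        confound_models=models,
        partial_rho=partial_rho,
        partial_p=partial_p,
        zscores=pd.DataFrame(zrows),
    )
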