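"""End-to-end orchestration: simulate -> extract -> reliability -> validity.

The pipeline consumes either a synthetic-cohort preset or a pair of CSV
inputs (long-format trial table + subject table), runs metric extraction,
the test-retest reliability analysis (stroke subjects, both sides) and the
validity analysis (session-1 scores), and writes a structured report bundle:
long-format CSVs with JSON mirrors plus a run manifest (configuration hash,
seed, package versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reliability, synthetic_cohort, task_metrics, validity

logger = logging.getLogger("handclin")

#: Decision thresholds of the assessment protocol, recorded in the manifest.
THRESHOLDS = dict(
    icc=reliability.ICC_THRESHOLD,
    srd_pct=reliability.SRD_PCT_THRESHOLD,
    shift=reliability.SHIFT_BOUND,
    auc=validity.AUC_THRESHOLD,
    fma=validity.FMA_CUTOFF,
    kudt=validity.KUDT_CUTOFF,
    alpha=0.05,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    preset: str = "paper_like"
    trials_csv: str | None = None
    subjects_csv: str | None = None
    out_dir: str | None = None
    seed: int = 0
    adjust_all_metrics: bool = False
    independence_metrics: tuple[str, ...] = \
        validity.DEFAULT_INDEPENDENCE_METRICS
    log_level: str = "WARNING"
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML (or JSON) file."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "independence_metrics" in payload:
            payload["independence_metrics"] = tuple(
                payload["independence_metrics"])
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        log level excluded, so re-runs elsewhere hash identically)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Structured outputs of one pipeline run."""

    subjects: pd.DataFrame
    trials: pd.DataFrame
    metric_table: pd.DataFrame
    trial_values: pd.DataFrame
    reliability_affected: pd.DataFrame
    reliability_less_affected: pd.DataFrame
    validity_metrics: pd.DataFrame
    partial_rho: pd.DataFrame
    partial_p: pd.DataFrame
    zscores: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = dict(
            subjects=self.subjects,
            trials=self.trials,
            metric_table=self.metric_table,
            reliability_affected=self.reliability_affected,
            reliability_less_affected=self.reliability_less_affected,
            validity=self.validity_metrics,
            zscores=self.zscores,
        )
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            if name not in ("trials", "subjects"):
                df.to_json(out / f"{name}.json", orient="records", indent=1)
        self.partial_rho.to_csv(out / "partial_rho.csv")
        self.partial_p.to_csv(out / "partial_p.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(summarize(self))


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

#: Clinical-score validity ranges.
CLINICAL_RANGES = dict(FMA=(0, 66), kUDT=(0, 2), MoCA=(0, 30), MAS=(0, 6),
                       BBT_affected=(0, 120), BBT_less_affected=(0, 120))


def validate_inputs(
    trials: pd.DataFrame, subjects: pd.DataFrame
) -> list[dict]:
    """Machine-readable schema/consistency report for a dataset.

    Checks column presence, duplicate trial keys, per-task trial-count
    conformance, clinical-score ranges and group labels. Returns a list of
    issue dicts (empty when the dataset is clean); each issue carries a
    ``severity`` of "error" or "warning".
    """
    issues: list[dict] = []

    def issue(severity, kind, detail):
        issues.append(dict(severity=severity, kind=kind, detail=detail))

    for col in task_metrics.TRIAL_TABLE_COLUMNS:
        if col not in trials.columns:
            issue("error", "missing_column", f"trials.{col}")
    for col in ("subject_id", "group", "age", "gender"):
        if col not in subjects.columns:
            issue("error", "missing_column", f"subjects.{col}")
    if issues:
        return issues

    bad_group = set(subjects["group"]) - {"stroke", "control"}
    if bad_group:
        issue("error", "bad_group_label", sorted(bad_group))
    dup = subjects["subject_id"].duplicated()
    if dup.any():
        issue("error", "duplicate_subject",
              sorted(subjects.loc[dup, "subject_id"]))

    keys = ["subject_id", "side", "session", "task", "condition", "trial_idx"]
    dup_t = trials.duplicated(subset=keys)
    if dup_t.any():
        issue("error", "duplicate_trial_key", int(dup_t.sum()))
    unknown = trials[~trials["task"].isin(task_metrics.TRIALS_PER_TASK)]
    if len(unknown):
        issue("error", "unknown_task", sorted(set(unknown["task"])))

    orphans = set(trials["subject_id"]) - set(subjects["subject_id"])
    if orphans:
        issue("error", "trials_without_subject", sorted(orphans))

    counts = trials.groupby(
        ["subject_id", "side", "session", "task"], sort=True
    ).size()
    for (sid, side, session, task), n in counts.items():
        expected = task_metrics.TRIALS_PER_TASK.get(task)
        if expected is not None and n != expected:
            issue("warning", "trial_count",
                  f"{sid}/{side}/s{session}/{task}: {n} trials, "
                  f"expected {expected}")

    for score, (lo, hi) in CLINICAL_RANGES.items():
        if score not in subjects.columns:
            continue
        vals = pd.to_numeric(subjects[score], errors="coerce")
        out_of_range = subjects.loc[vals.notna() & ((vals < lo) | (vals > hi)),
                                    "subject_id"]
        if len(out_of_range):
            issue("error", "clinical_score_range",
                  f"{score} outside [{lo}, {hi}] for "
                  f"{sorted(out_of_range)}")
    return issues


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_or_simulate(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.trials_csv is not None:
        trials = pd.read_csv(config.trials_csv)
        if config.subjects_csv is None:
            raise ValueError("subjects_csv is required when trials_csv is set")
        subjects = pd.read_csv(config.subjects_csv)
        subjects["affected_side"] = subjects.get(
            "affected_side", pd.Series("", index=subjects.index)).fillna("")
        return subjects, trials
    gen = synthetic_cohort.PRESETS[config.preset](**config.generator_overrides)
    return synthetic_cohort.simulate_dataset(gen, config.seed)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return (optionally write) the bundle.

    Deterministic given the seed. Malformed inputs raise with the issue list
    attached; partially missing tasks degrade to per-metric availability
    flags and the pipeline continues.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level)
    subjects, trials = _load_or_simulate(config)
    issues = validate_inputs(trials, subjects)
    errors = [i for i in issues if i["severity"] == "error"]
    if errors:
        raise ValueError(f"invalid inputs: {errors}")

    metric_table = task_metrics.extract_metric_table(trials)
    trial_values = task_metrics.trial_metric_values(trials)

    stroke_ids = set(subjects.loc[subjects["group"] == "stroke", "subject_id"])
    stroke_metrics = metric_table[metric_table["subject_id"].isin(stroke_ids)]
    stroke_trials = trial_values[trial_values["subject_id"].isin(stroke_ids)]

    rel = {}
    for side in ("affected", "less_affected"):
        rel[side] = reliability.reliability_report(
            stroke_metrics, stroke_trials, side=side)

    val = validity.validity_report(
        trials, subjects,
        adjust_all_metrics=config.adjust_all_metrics,
        independence_metrics=config.independence_metrics,
    )

    manifest = dict(
        config=dataclasses.asdict(config),
        config_hash=config.config_hash(),
        seed=config.seed,
        thresholds=THRESHOLDS,
        n_subjects=len(subjects),
        n_trials=len(trials),
        versions=dict(
            handclin=__version__,
            numpy=np.__version__,
            pandas=pd.__version__,
        ),
        warnings=[i for i in issues if i["severity"] == "warning"][:50],
    )
    bundle = ReportBundle(
        subjects=subjects, trials=trials, metric_table=metric_table,
        trial_values=trial_values,
        reliability_affected=rel["affected"],
        reliability_less_affected=rel["less_affected"],
        validity_metrics=val["metrics"],
        partial_rho=val["partial_rho"], partial_p=val["partial_p"],
        zscores=val["zscores"], manifest=manifest,
    )
    if config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Human-readable summary
# ---------------------------------------------------------------------------

def summarize(bundle: ReportBundle) -> str:
    """Per-metric verdict lines with strict threshold semantics.

    A metric is "reliable" iff ICC > 0.7 and SRD% < 30 and |shift| <= 6.35
    (strict inequalities for ICC and SRD%), and "discriminative" iff the
    control-vs-affected AUC > 0.7.
    """
    lines = [
        f"handclin {bundle.manifest['versions']['handclin']} "
        f"(seed {bundle.manifest['seed']}, "
        f"config {bundle.manifest['config_hash']})",
        "",
    ]
    rel = bundle.reliability_affected.set_index("metric")
    val = bundle.validity_metrics.set_index("metric")
    for metric in task_metrics.METRICS:
        parts = [f"{metric}:"]
        if metric in rel.index and bool(rel.loc[metric].get("available",
                                                            False)):
            r = rel.loc[metric]
            ok = bool(r["icc_ok"]) and bool(r["srd_ok"]) and bool(r["shift_ok"])
            parts.append(
                f"{'reliable' if ok else 'not reliable'} "
                f"(ICC={r['icc']:.2f}, SRD%={r['srd_pct']:.1f}, "
                f"shift={r['shift_pct']:.2f})")
        else:
            parts.append("reliability unavailable")
        if metric in val.index and bool(val.loc[metric].get("available",
                                                            False)):
            v = val.loc[metric]
            parts.append(
                f"{'discriminative' if bool(v['discriminative']) else 'not discriminative'} "
                f"(AUC={v['auc_control_vs_affected']:.2f}); "
                f"{v['pct_impaired_affected']:.1f}% impaired (affected); "
                f"FMA rho={v['rho_fma']:.2f} ({v['strength_fma']}), "
                f"BBT rho={v['rho_bbt']:.2f} ({v['strength_bbt']}), "
                f"kUDT rho={v['rho_kudt']:.2f} ({v['strength_kudt']})")
        else:
            parts.append("validity unavailable")
        lines.append(" ".join(parts))
    if len(bundle.partial_rho):
        lines.append("")
        lines.append("Partial Spearman (independence of selected metrics):")
        lines.append(bundle.partial_rho.round(2).to_string())
    return "\n".join(lines) + "\n"
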