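"""End-to-end orchestration: preprocess -> subject metrics -> group inference.

``analyze_cohort`` drives an in-memory CohortDataset (as produced by the
simulator or assembled from file bundles); ``run_pipeline`` is the
file-based wrapper used by the CLI. Invalid recordings are excluded and
counted in the feasibility ledger, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .group import (
    QCLedger,
    SensitivityReport,
    brain_behavior_correlation,
    feasibility_report,
    group_change_table,
    sensitivity_suite,
)
from .io import PipelineConfig, read_recording, write_metrics_table
from .preprocess import run_preprocessing
from .protocol import TaskDesign
from .subject import FC_PAIRS, SubjectMetrics, compute_subject_metrics
from .synth import CohortDataset

logger = logging.getLogger(__name__)


def metrics_to_tidy(
    metrics: SubjectMetrics,
    statuses: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flatten one subject-visit's metrics to subject/visit/condition/
    family/metric_id/value rows. Conditions whose status is not 'valid'
    are emitted as NaN so pairwise deletion handles them downstream."""
    rows = []
    statuses = statuses or {}
    for k, cond in enumerate(metrics.conditions):
        ok = statuses.get(cond, "valid") == "valid"
        for c in range(metrics.beta.shape[0]):
            rows.append((metrics.subject_id, metrics.visit, cond, "beta",
                         f"ch{c + 1}", metrics.beta[c, k] if ok else np.nan))
            rows.append((metrics.subject_id, metrics.visit, cond, "cohen_d",
                         f"ch{c + 1}", metrics.cohen_d[c, k] if ok else np.nan))
        vec = metrics.fc_pairs.get(cond)
        for pi, (i, j) in enumerate(FC_PAIRS):
            val = vec[pi] if (ok and vec is not None) else np.nan
            rows.append((metrics.subject_id, metrics.visit, cond, "fc",
                         f"FC{pi + 1}", val))
    return pd.DataFrame(
        rows, columns=["subject", "visit", "condition", "family",
                       "metric_id", "value"]
    )


def behavioral_change_table(behavioral: pd.DataFrame) -> pd.DataFrame:
    """Per-subject change scores per instrument (post - pre)."""
    wide = behavioral.pivot_table(index=["subject", "instrument"],
                                  columns="visit", values="score").reset_index()
    wide["change"] = wide["post"] - wide["pre"]
    return wide


def brain_behavior_table(
    metric_df: pd.DataFrame,
    behavioral: pd.DataFrame,
    neural_targets: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Pearson correlations between neural change scores and every
    behavioral instrument's change score.

    ``neural_targets`` lists (condition, family, metric_id) triples, e.g.
    ("distraction", "beta", "ch4").
    """
    beh = behavioral_change_table(behavioral)
    rows = []
    for cond, fam, mid in neural_targets:
        sub = metric_df[(metric_df["condition"] == cond)
                        & (metric_df["family"] == fam)
                        & (metric_df["metric_id"] == mid)]
        wide = sub.pivot_table(index="subject", columns="visit", values="value")
        if not {"pre", "post"} <= set(wide.columns):
            continue
        neural = (wide["post"] - wide["pre"]).rename("neural")
        for inst, idf in beh.groupby("instrument"):
            joined = idf.set_index("subject").join(neural, how="inner")
            res = brain_behavior_correlation(joined["neural"].to_numpy(),
                                             joined["change"].to_numpy())
            if res is None:
                rows.append((cond, fam, mid, inst, np.nan, np.nan, 0))
            else:
                r, p, n = res
                rows.append((cond, fam, mid, inst, r, p, n))
    return pd.DataFrame(rows, columns=["condition", "family", "metric_id",
                                       "instrument", "r", "p", "n"])


@dataclass
class PipelineResult:
    subject_metrics: pd.DataFrame
    group_results: pd.DataFrame
    behavioral_results: pd.DataFrame
    brain_behavior: pd.DataFrame
    qc_ledger: QCLedger
    sensitivity: SensitivityReport | None
    config: PipelineConfig
    qc_details: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_cohort(
    cohort: CohortDataset,
    config: PipelineConfig | None = None,
    run_sensitivity: bool = True,
    brain_behavior_targets: list[tuple[str, str, str]] | None = None,
) -> PipelineResult:
    """Run preprocessing, subject metrics, and group inference over a
    paired cohort."""
    cfg = config or PipelineConfig()
    design = cohort.design

    planted = {}
    if cohort.session_log is not None:
        for row in cohort.session_log.itertuples():
            planted[(row.subject, row.visit, row.condition)] = row.status

    tidy_frames = []
    qc_rows = []
    for subj in cohort.subjects:
        for visit, rec in (("pre", subj.pre), ("post", subj.post)):
            if rec is None:
                for cond in design.condition_labels:
                    qc_rows.append((subj.subject_id, visit, cond, "missing", np.nan))
                continue
            hb, qc = run_preprocessing(
                rec, cfg.motion, cfg.filter, cfg.pathlength_cm,
                invalid_ceiling=cfg.qc_invalid_ceiling,
            )
            metrics = compute_subject_metrics(
                hb, design, subj.subject_id, visit, cfg.hrf, cfg.filter,
                cfg.baseline_window_s, cfg.d_denominator,
            )
            statuses = {}
            fs = rec.sampling_rate
            for cond in design.condition_labels:
                key = (subj.subject_id, visit, cond)
                if planted.get(key) == "missing":
                    statuses[cond] = "missing"
                else:
                    # condition-level QC: masked fraction within its span
                    lo, hi = design.condition_span(cond)
                    i0, i1 = int(lo * fs), min(int(hi * fs), rec.n_times)
                    frac = float((~hb.valid_mask[:, i0:i1]).mean())
                    statuses[cond] = ("invalid"
                                      if frac > cfg.qc_invalid_ceiling else "valid")
                qc_rows.append((subj.subject_id, visit, cond, statuses[cond],
                                qc.masked_fraction))
            tidy_frames.append(metrics_to_tidy(metrics, statuses))

    if not tidy_frames:
        raise InvalidInputError("no recordings survived preprocessing")
    metric_df = pd.concat(tidy_frames, ignore_index=True)

    qc_details = pd.DataFrame(
        qc_rows, columns=["subject", "visit", "condition", "status",
                          "session_masked_fraction"]
    )
    ledger = feasibility_report(
        qc_details[["subject", "visit", "condition", "status"]]
    )

    group_frames = []
    for fam, fisher in (("beta", False), ("cohen_d", False),
                        ("fc", cfg.fisher_z_fc)):
        fam_df = metric_df[metric_df["family"] == fam]
        group_frames.append(
            group_change_table(fam_df, family=fam, fisher_transform=fisher)
        )
    group_results = pd.concat(group_frames, ignore_index=True)

    beh_df = cohort.behavioral.rename(columns={"instrument": "metric_id",
                                               "score": "value"}).copy()
    beh_df["condition"] = "behavioral"
    behavioral_results = group_change_table(beh_df, family="behavioral")

    if brain_behavior_targets is None:
        link = cohort.truth.get("link") if cohort.truth else None
        if link is not None:
            brain_behavior_targets = [
                (link.condition, "beta", f"ch{link.channel}"),
                (link.condition, "cohen_d", f"ch{link.channel}"),
            ]
        else:
            brain_behavior_targets = []
    brain_behavior = brain_behavior_table(metric_df, cohort.behavioral,
                                          brain_behavior_targets)

    sensitivity = None
    if run_sensitivity:
        cov = pd.DataFrame(
            [(s.subject_id, s.time_since_injury_d, s.injury_type)
             for s in cohort.subjects],
            columns=["subject", "time_since_injury_d", "injury_type"],
        )
        targets = [(c, m) for (c, f, m) in brain_behavior_targets]
        if not targets:
            targets = None
        sens_df = metric_df[metric_df["family"].isin(["beta", "cohen_d"])].copy()
        sens_df["metric_id"] = sens_df["family"] + ":" + sens_df["metric_id"]
        if targets is not None:
            targets = [(c, f"{f}:{m}") for (c, f, m) in brain_behavior_targets]
        sensitivity = sensitivity_suite(sens_df, cov, targets)

    return PipelineResult(
        subject_metrics=metric_df, group_results=group_results,
        behavioral_results=behavioral_results, brain_behavior=brain_behavior,
        qc_ledger=ledger, sensitivity=sensitivity, config=cfg,
        qc_details=qc_details,
    )


def load_cohort_from_bundles(input_dir: str | Path,
                             design: TaskDesign) -> CohortDataset:
    """Assemble a CohortDataset from bundle directories named
    <subject>_<visit>/ plus an optional behavioral.csv and covariates.csv."""
    from .synth import CohortSubject

    d = Path(input_dir)
    recs: dict[tuple[str, str], object] = {}
    for sub in sorted(p for p in d.iterdir() if p.is_dir()):
        if not (sub / "signals.csv").exists():
            continue
        rec = read_recording(sub)
        recs[(rec.subject_id, rec.visit)] = rec
    subject_ids = sorted({s for s, _ in recs})
    if not subject_ids:
        raise InvalidInputError(f"{d}: no recording bundles found")
    cov_path = d / "covariates.csv"
    cov = pd.read_csv(cov_path) if cov_path.exists() else None
    subjects = []
    for sid in subject_ids:
        pre = recs.get((sid, "pre"))
        post = recs.get((sid, "post"))
        age = pre.subject_age if pre else (post.subject_age if post else 47.0)
        tsi, ity = np.nan, "unknown"
        if cov is not None and (cov["subject"] == sid).any():
            row = cov[cov["subject"] == sid].iloc[0]
            tsi = float(row.get("time_since_injury_d", np.nan))
            ity = str(row.get("injury_type", "unknown"))
        subjects.append(CohortSubject(sid, age, tsi, ity, pre, post))
    beh_path = d / "behavioral.csv"
    behavioral = (pd.read_csv(beh_path) if beh_path.exists()
                  else pd.DataFrame(columns=["subject", "visit", "instrument",
                                             "score"]))
    return CohortDataset(subjects=subjects, behavioral=behavioral, truth={},
                         design=design, seed=0, session_log=None)


def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 out_dir: str | Path, design: TaskDesign) -> PipelineResult:
    """File-based end-to-end run; writes all tidy result tables plus the
    QC ledger and a run log under ``out_dir``."""
    cohort = load_cohort_from_bundles(input_dir, design)
    has_behavior = len(cohort.behavioral) > 0
    result = analyze_cohort(cohort, config,
                            run_sensitivity=has_behavior,
                            brain_behavior_targets=None if has_behavior else [])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_table(result.subject_metrics, out / "subject_metrics.csv", config)
    write_metrics_table(result.group_results, out / "group_results.csv", config)
    write_metrics_table(result.behavioral_results,
                        out / "behavioral_results.csv", config)
    write_metrics_table(result.brain_behavior, out / "brain_behavior.csv", config)
    write_metrics_table(result.qc_details, out / "qc_details.csv", config)
    (out / "qc_ledger.json").write_text(json.dumps(result.qc_ledger.as_dict(),
                                                   indent=1))
    if result.sensitivity is not None:
        write_metrics_table(result.sensitivity.spearman,
                            out / "sensitivity_spearman.csv", config)
        write_metrics_table(result.sensitivity.leave_one_out,
                            out / "sensitivity_loo.csv", config)
        write_metrics_table(result.sensitivity.ancova,
                            out / "sensitivity_ancova.csv", config)
    (out / "run_log.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(cohort.subjects),
        "qc": result.qc_ledger.as_dict(),
        "config": config.resolved(),
    }, indent=1))
    return result


def format_report(result: PipelineResult, alpha: float = 0.05) -> str:
    """Text summary in the conventional reporting format."""
    lines = ["QC: {possible} possible, {valid} valid ({valid_pct}%), "
             "{missing} missing, {invalid} invalid".format(
                 **result.qc_ledger.as_dict())]
    for df, title in ((result.behavioral_results, "Behavioral change"),
                      (result.group_results, "Neural change")):
        lines.append(f"-- {title} --")
        sig = df[df["p"] < alpha]
        for row in sig.itertuples():
            lines.append(
                f"{row.condition} {row.metric_id}: MD={row.MD:+.2f}, "
                f"t={row.t:.3f}, P={row.p:.3f}, q={row.q:.3f}, d={row.d:.2f}"
            )
        if sig.empty:
            lines.append(f"(no rows with P < {alpha})")
    if len(result.brain_behavior):
        lines.append("-- Brain-behavior correlations --")
        for row in result.brain_behavior.itertuples():
            lines.append(
                f"{row.condition} {row.metric_id} x {row.instrument}: "
                f"r={row.r:.3f}, P={row.p:.3f}, n={row.n}"
            )
    return "\n".join(lines)
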