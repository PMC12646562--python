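"""End-to-end orchestration: score, label, fit, diagnose, calibrate, report.

The pipeline turns a validated cohort (real or synthetic) into a single
reproducible report: cohort summary, pre/post-drainage comparisons,
responder counts, Firth models of shunt nonresponse on each improvement
rate (unadjusted and adjusted for sex and Evans index), ROC diagnostics
with stratified-bootstrap CIs, DeLong comparisons of the digital scores
against the traditional battery, permutation p-values for the rate
covariates, and calibration of the combined-improvement model.

The positive class throughout is shunt *nonresponse*; by default ROC
scores are the Firth-model predicted probabilities of nonresponse
(``roc_mode="probability"``), with sign-flipped raw rates available as
``roc_mode="rate"``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort_model import NormTable, PatientRecord, write_report
from .diagnostics import (
    DiagnosticsError,
    ResamplingConfig,
    auc,
    calibration_slope,
    confusion_metrics,
    delong_test,
    mean_calibration_error,
    permutation_pvalue,
    pre_post_comparison,
    spiegelhalter_test,
    youden_cutoff,
)
from .firth import FirthError, fit_firth, predict_prob
from .outcomes import cohort_labels
from .scoring import ScoringOptions, improvement_profile

__all__ = ["PipelineConfig", "analysis_frame", "run_pipeline"]

log = logging.getLogger("inpheld")

RATES = ("gait_rate", "cognitive_rate", "combined_rate", "traditional_rate")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs besides the data."""

    scoring: ScoringOptions = field(default_factory=ScoringOptions)
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    adjustment: tuple[str, ...] = ("sex_male", "evans_index")
    roc_mode: str = "probability"  # probability | rate
    calibration_bins: int = 5
    any_visit: bool = False
    desh_max: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.roc_mode not in ("probability", "rate"):
            raise ValueError("roc_mode in (probability, rate)")


def analysis_frame(records: Iterable[PatientRecord], norms: NormTable,
                   config: PipelineConfig) -> pd.DataFrame:
    """Per-patient covariates, improvement rates and outcome labels."""
    label_table, _ = cohort_labels(records, any_visit=config.any_visit)
    label_map = label_table.set_index("id")["shunt_responder"]
    rows = []
    for rec in records:
        prof = improvement_profile(rec, norms, config.scoring)
        status = label_map.loc[rec.id]
        rows.append({
            "id": rec.id,
            "age": rec.age,
            "sex_male": 1.0 if rec.sex == "male" else 0.0,
            "education": rec.education,
            "evans_index": rec.evans_index,
            "desh_score": rec.desh_score,
            "shunted": rec.shunted,
            "shunt_responder": status,
            "nonresponder": {"responder": 0.0, "nonresponder": 1.0}.get(
                status, np.nan),
            "cognitive_z_pre": prof.cognitive_z_pre,
            "cognitive_z_post": prof.cognitive_z_post,
            "gait_rate": prof.gait_rate,
            "cognitive_rate": prof.cognitive_rate,
            "combined_rate": prof.combined_rate,
            "traditional_rate": prof.traditional_rate,
            "flags": "|".join(sorted(prof.flags)),
        })
    return pd.DataFrame(rows)


def _cohort_summary(records: list[PatientRecord], df: pd.DataFrame) -> dict:
    def med_iqr(series):
        s = series.dropna()
        if not len(s):
            return None
        return {"median": float(s.median()),
                "q1": float(s.quantile(0.25)), "q3": float(s.quantile(0.75))}

    return {
        "n_total": len(records),
        "n_shunted": int(df["shunted"].sum()),
        "male_prevalence": float(df["sex_male"].mean()) if len(df) else None,
        "age": med_iqr(df["age"]),
        "evans_index": med_iqr(df["evans_index"]),
        "desh_score": med_iqr(df["desh_score"].astype(float)),
        "cognitive_z_baseline": med_iqr(df["cognitive_z_pre"]),
        "improvement_rates": {r: med_iqr(df[r]) for r in RATES},
    }


_PREPOST_MEASURES = {
    # attribute path -> test kind; medians-style measures use the signed-rank
    "traditional.mmse": "wilcoxon_signed_rank",
    "traditional.tug_time": "wilcoxon_signed_rank",
    "traditional.tmwt_time": "wilcoxon_signed_rank",
    "traditional.tmwt_steps": "wilcoxon_signed_rank",
    "cognitive.one_back": "wilcoxon_signed_rank",
    "cognitive.stroop_correct": "wilcoxon_signed_rank",
    "gait.stride_length": "paired_t",
    "gait.step_height": "paired_t",
    "gait.gait_velocity": "paired_t",
    "gait.turning_time": "wilcoxon_signed_rank",
}


def _prepost_table(records: list[PatientRecord]) -> dict:
    out = {}
    for path, kind in _PREPOST_MEASURES.items():
        panel, attr = path.split(".")
        pre, post = [], []
        for rec in records:
            p0 = getattr(rec, f"{panel}_pre")
            p1 = getattr(rec, f"{panel}_post")
            if p0 is not None and p1 is not None:
                pre.append(float(getattr(p0, attr)))
                post.append(float(getattr(p1, attr)))
        if len(pre) < 2:
            out[attr] = None
            continue
        try:
            statistic, p = pre_post_comparison(pre, post, kind=kind)
        except (DiagnosticsError, ValueError):
            statistic, p = np.nan, np.nan
        out[attr] = {"n": len(pre), "kind": kind,
                     "pre_mean": float(np.mean(pre)),
                     "post_mean": float(np.mean(post)),
                     "statistic": statistic, "p": p}
    return out


def _model_design(sh: pd.DataFrame, rate: str, adjustment: tuple[str, ...]):
    cols = ["intercept", rate, *adjustment]
    X = np.column_stack([np.ones(len(sh)), *(sh[c].to_numpy(dtype=float)
                                             for c in cols[1:])])
    return X, cols


def _fit_models(sh: pd.DataFrame, y: np.ndarray, config: PipelineConfig,
                rng: np.random.Generator) -> dict:
    """Unadjusted + adjusted Firth model per rate, with permutation p."""
    models = {}
    for rate in RATES:
        entry = {}
        for label, adjustment in (("unadjusted", ()),
                                  ("adjusted", config.adjustment)):
            X, names = _model_design(sh, rate, adjustment)
            try:
                fit = fit_firth(X, y, column_names=names)
                summary = fit.summary()
                X_null = np.delete(X, 1, axis=1)
                null_names = [n for n in names if n != rate]
                p_perm, stat, bad = permutation_pvalue(
                    X, X_null, y.astype(int), config.resampling, rng=rng,
                    full_names=names, null_names=null_names)
                summary["permutation_p"] = p_perm
                summary["permutation_stat"] = stat
                summary["permutation_nonconverged"] = bad
                entry[label] = summary
            except FirthError as exc:
                entry[label] = {"error": str(exc)}
        models[rate] = entry
    return models


def _scores_for(sh: pd.DataFrame, y: np.ndarray, rate: str,
                mode: str) -> np.ndarray:
    """Nonresponse score: model probability (default) or sign-flipped rate."""
    x = sh[rate].to_numpy(dtype=float)
    if mode == "rate":
        return -x
    X = np.column_stack([np.ones(len(x)), x])
    fit = fit_firth(X, y, column_names=("intercept", rate))
    return predict_prob(fit, X)


def _diagnostics_for(sh: pd.DataFrame, y: np.ndarray, rate: str,
                     config: PipelineConfig, rng: np.random.Generator) -> dict:
    scores = _scores_for(sh, y, rate, config.roc_mode)
    a = auc(scores, y)
    cutoff, j = youden_cutoff(scores, y)
    cm = confusion_metrics(scores, y, cutoff)

    # one stratified-bootstrap pass re-deriving score, cutoff and metrics
    strata = [np.flatnonzero(y == c) for c in (0, 1)]
    B = config.resampling.bootstrap_B
    boot = {k: [] for k in ("auc", "cutoff", "sensitivity", "specificity",
                            "ppv", "npv")}
    failed = 0
    for _ in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                              for s in strata])
        try:
            sb, yb = sh.iloc[idx], y[idx]
            scores_b = _scores_for(sb, yb, rate, config.roc_mode)
            ab = auc(scores_b, yb)
            cb, _ = youden_cutoff(scores_b, yb)
            mb = confusion_metrics(scores_b, yb, cb)
        except (DiagnosticsError, FirthError):
            failed += 1
            continue
        boot["auc"].append(ab)
        boot["cutoff"].append(cb)
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            if mb[k] is not None:
                boot[k].append(mb[k])

    level = config.resampling.level
    qs = [100 * (1 - level) / 2, 100 * (1 + level) / 2]

    def ci(key):
        vals = boot[key]
        if not vals:
            return None
        lo, hi = np.percentile(vals, qs)
        return [float(lo), float(hi)]

    out = {
        "score_mode": config.roc_mode,
        "positive_class": "nonresponder",
        "auc": a, "auc_ci": ci("auc"),
        "cutoff": cutoff, "cutoff_ci": ci("cutoff"),
        "youden_j": j,
        "confusion": {k: cm[k] for k in ("tp", "fp", "tn", "fn")},
        "bootstrap_failures": failed,
    }
    for k in ("sensitivity", "specificity", "ppv", "npv"):
        out[k] = cm[k]
        out[f"{k}_ci"] = ci(k)
    return out, scores


def _calibration(sh: pd.DataFrame, y: np.ndarray,
                 config: PipelineConfig) -> dict:
    X, names = _model_design(sh, "combined_rate", config.adjustment)
    fit = fit_firth(X, y, column_names=names)
    probs = predict_prob(fit, X)
    z, p = spiegelhalter_test(probs, y)
    try:
        slope, intercept, fallback = calibration_slope(probs, y)
    except DiagnosticsError as exc:
        slope = intercept = np.nan
        fallback = str(exc)
    return {
        "model": "combined_rate (adjusted)",
        "spiegelhalter_z": z, "spiegelhalter_p": p,
        "slope": slope, "intercept": intercept,
        "firth_fallback": fallback,
        "mean_calibration_error_pct": mean_calibration_error(
            probs, y, bins=config.calibration_bins),
    }


def run_pipeline(records: list[PatientRecord], norms: NormTable,
                 config: Optional[PipelineConfig] = None) -> dict:
    """Execute every stage and return the report dictionary.

    Identical records + config (incl. seed) give an identical report.
    Model/ROC/calibration stages are skipped, with an explicit notice,
    when the shunted subgroup has a single-class outcome.
    """
    config = config if config is not None else PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_models, rng_diag = (np.random.default_rng(c) for c in ss.spawn(2))

    df = analysis_frame(records, norms, config)
    _, label_summary = cohort_labels(records, any_visit=config.any_visit)
    report: dict = {
        "software": {"name": "inpheld", "version": __version__},
        "seed": config.seed,
        "config": {
            "scoring": asdict(config.scoring),
            "resampling": asdict(config.resampling),
            "adjustment": list(config.adjustment),
            "roc_mode": config.roc_mode,
            "calibration_bins": config.calibration_bins,
            "any_visit": config.any_visit,
        },
        "cohort_summary": _cohort_summary(records, df),
        "prepost_comparison": _prepost_table(records),
        "responder_counts": label_summary,
        "notices": [],
    }

    sh = df[df["shunted"]].dropna(subset=list(RATES)).reset_index(drop=True)
    y = sh["nonresponder"].to_numpy(dtype=float)
    if len(sh) == 0 or len(np.unique(y)) < 2:
        report["notices"].append(
            "single-class outcome among shunted patients: model, ROC and "
            "calibration stages skipped")
        report["models"] = report["diagnostics"] = report["delong"] = None
        report["calibration"] = None
        return report

    log.info("fitting Firth models on %d shunted patients", len(sh))
    report["models"] = _fit_models(sh, y, config, rng_models)

    diagnostics, score_vectors = {}, {}
    for rate in RATES:
        diagnostics[rate], score_vectors[rate] = _diagnostics_for(
            sh, y, rate, config, rng_diag)
    report["diagnostics"] = diagnostics

    delong = {}
    for rate in ("combined_rate", "gait_rate", "cognitive_rate"):
        z, p = delong_test(score_vectors[rate],
                           score_vectors["traditional_rate"], y)
        delong[f"{rate}_vs_traditional"] = {"z": z, "p": p}
    report["delong"] = delong

    try:
        report["calibration"] = _calibration(sh, y, config)
    except (FirthError, DiagnosticsError) as exc:
        report["calibration"] = {"error": str(exc)}
        report["notices"].append(f"calibration stage failed: {exc}")
    return report
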