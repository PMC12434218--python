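"""File formats, pipeline configuration and the simulate-score-summarize-regress run.

All tabular interchange is header-first CSV: episodes
(``patient_id,level,start_day,end_day``), covariates
(``patient_id,transplant_type,disease,cell_source,tbi,age_group,gender``)
and scores (per-level day counts plus the Day +100 endpoint).  The
transition model travels as JSON (states x states, row-major), and
:class:`PipelineConfig` round-trips losslessly through JSON with unknown
keys rejected.  Outputs are written atomically (temp file then rename) and
each stage logs one ``key=value`` line to standard error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    GroupedScores,
    compare_groups,
    median_with_bootstrap_ci,
    summarize_cohort,
)
from .regression import (
    DesignSpec,
    bivariable_screen,
    build_design,
    fit_logistic,
    forest_plot_data,
    or_per_scale,
    roc_curve,
)
from .scoring import (
    DEFAULT_WINDOW,
    InterventionEpisode,
    PatientRecord,
    ScoreResult,
    ScoreWindow,
    SupportLevel,
    ValidationError,
    WeightScheme,
    compute_patient_auc,
    filter_complete_followup,
    pn_outcome_at,
)
from .synthetic_cohort import (
    CohortConfig,
    CovariateProfile,
    TransitionModel,
    attach_logistic_outcomes,
    default_transition_model,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_episodes",
    "read_covariates",
    "write_episodes",
    "write_covariates",
    "write_scores",
    "assemble_records",
    "score_records",
    "run_pipeline",
    "atomic_write_text",
]

log = logging.getLogger("nutriscore")

EPISODE_COLUMNS = ["patient_id", "level", "start_day", "end_day"]
COVARIATE_COLUMNS = [
    "patient_id",
    "transplant_type",
    "disease",
    "cell_source",
    "tbi",
    "age_group",
    "gender",
]
SCORE_COLUMNS = [
    "patient_id",
    "auc",
    "days_routine",
    "days_oral",
    "days_enteral",
    "days_pn",
    "days_bespoke_pn",
    "level_day100",
    "pn_at_day100",
]


def atomic_write_text(path: Path, text: str) -> None:
    """Write via a sibling temp file and rename, so readers never see partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_episodes(path: str | Path) -> list[InterventionEpisode]:
    """Parse and validate an episodes CSV; all row errors reported together."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EPISODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    episodes: list[InterventionEpisode] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            level = SupportLevel.from_token(row.level)
            try:
                start, end = int(row.start_day), int(row.end_day)
            except ValueError:
                raise ValidationError(
                    f"non-integer day ({row.start_day!r}, {row.end_day!r})"
                ) from None
            episodes.append(
                InterventionEpisode(
                    patient_id=row.patient_id, level=level, start_day=start, end_day=end
                )
            )
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    if not episodes:
        log.warning("event=read_episodes path=%s rows=0 (empty file)", path)
    return episodes


def read_covariates(path: str | Path) -> dict[str, CovariateProfile]:
    """Parse and validate a covariates CSV keyed by patient id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    profiles: dict[str, CovariateProfile] = {}
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.patient_id
        if pid in profiles:
            errors.append(f"row {i}: duplicate patient_id {pid!r}")
            continue
        allo = row.transplant_type == "allogeneic"
        try:
            if allo:
                for name in ("disease", "cell_source", "tbi"):
                    if getattr(row, name) == "":
                        raise ValidationError(
                            f"allogeneic row missing field {name!r}"
                        )
            profiles[pid] = CovariateProfile(
                transplant_type=row.transplant_type,
                age_group=row.age_group,
                gender=row.gender,
                disease=row.disease or None,
                cell_source=row.cell_source or None,
                tbi=(row.tbi.lower() in ("1", "true", "yes")) if row.tbi else None,
            )
        except ValidationError as exc:
            errors.append(f"row {i} (patient {pid!r}): {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return profiles


def read_scores(
    path: str | Path,
) -> tuple[list[ScoreResult], dict[str, bool]]:
    """Parse a scores CSV back into results plus the Day +100 endpoint flags."""
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    results: list[ScoreResult] = []
    outcomes: dict[str, bool] = {}
    for row in df.itertuples(index=False):
        days = {
            SupportLevel.ROUTINE: int(row.days_routine),
            SupportLevel.ORAL: int(row.days_oral),
            SupportLevel.ENTERAL: int(row.days_enteral),
            SupportLevel.PN: int(row.days_pn),
            SupportLevel.BESPOKE_PN: int(row.days_bespoke_pn),
        }
        level = (
            SupportLevel.NONE
            if row.level_day100 == "none"
            else SupportLevel.from_token(row.level_day100)
        )
        results.append(
            ScoreResult(
                patient_id=str(row.patient_id),
                auc=float(row.auc),
                days_by_level=days,
                level_at_last_day=level,
                overlap_mode_used="additive",
            )
        )
        outcomes[str(row.patient_id)] = bool(int(row.pn_at_day100))
    return results, outcomes


def write_episodes(path: str | Path, records: Sequence[PatientRecord]) -> None:
    rows = [
        {
            "patient_id": ep.patient_id,
            "level": ep.level.token,
            "start_day": ep.start_day,
            "end_day": ep.end_day,
        }
        for rec in records
        for ep in rec.episodes
    ]
    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    atomic_write_text(Path(path), df.to_csv(index=False))


def write_covariates(path: str | Path, records: Sequence[PatientRecord]) -> None:
    rows = []
    for rec in records:
        p = rec.covariates
        rows.append(
            {
                "patient_id": rec.patient_id,
                "transplant_type": p.transplant_type,
                "disease": p.disease or "",
                "cell_source": p.cell_source or "",
                "tbi": "" if p.tbi is None else ("yes" if p.tbi else "no"),
                "age_group": p.age_group,
                "gender": p.gender,
            }
        )
    df = pd.DataFrame(rows, columns=COVARIATE_COLUMNS)
    atomic_write_text(Path(path), df.to_csv(index=False))


def write_scores(
    path: str | Path,
    records: Sequence[PatientRecord],
    scores: Sequence[ScoreResult],
    window: ScoreWindow = DEFAULT_WINDOW,
) -> None:
    rows = []
    for rec, s in zip(records, scores):
        rows.append(
            {
                "patient_id": s.patient_id,
                "auc": s.auc,
                "days_routine": s.days_by_level[SupportLevel.ROUTINE],
                "days_oral": s.days_by_level[SupportLevel.ORAL],
                "days_enteral": s.days_by_level[SupportLevel.ENTERAL],
                "days_pn": s.days_by_level[SupportLevel.PN],
                "days_bespoke_pn": s.days_by_level[SupportLevel.BESPOKE_PN],
                "level_day100": s.level_at_last_day.token,
                "pn_at_day100": int(pn_outcome_at(rec, window=window)),
            }
        )
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    atomic_write_text(Path(path), df.to_csv(index=False))


def assemble_records(
    episodes: Sequence[InterventionEpisode],
    covariates: Mapping[str, CovariateProfile],
    followup_days: int = 100,
) -> list[PatientRecord]:
    """Join episode and covariate tables into patient records.

    Every episode's patient must appear in the covariate table; covariate
    rows without episodes become episode-free (score 0) records.
    """
    by_patient: dict[str, list[InterventionEpisode]] = {pid: [] for pid in covariates}
    orphans = sorted({ep.patient_id for ep in episodes} - set(covariates))
    if orphans:
        raise ValidationError(f"episodes reference unknown patients: {orphans}")
    for ep in episodes:
        by_patient[ep.patient_id].append(ep)
    return [
        PatientRecord(
            patient_id=pid,
            episodes=eps,
            covariates=covariates[pid],
            followup_days=max(followup_days, max((e.end_day for e in eps), default=0)),
        )
        for pid, eps in by_patient.items()
    ]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, JSON-round-trippable."""

    out_dir: str = "nutriscore_out"
    seed: int = 0
    # scoring
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "routine": 1.0, "oral": 2.0, "enteral": 4.0, "pn": 6.0, "bespoke_pn": 7.0
        }
    )
    window_first_day: int = 0
    window_last_day: int = 99
    overlap_mode: str = "additive"
    allow_truncated_followup: bool = False
    # inputs (ignored when simulate=True)
    episodes_path: str | None = None
    covariates_path: str | None = None
    # simulation
    simulate: bool = True
    n_patients: int = 131
    # logistic outcomes keep the endpoint stochastic given the score; the
    # purely de-escalating trajectory default would make Day+100 >=PN an
    # almost deterministic threshold of the score and separate the MLE
    outcome_mode: str = "logistic"
    model_path: str | None = None
    # statistics
    n_boot: int = 2000
    alpha: float = 0.05
    # regression
    or_scale: float = 100.0
    firth: bool = False

    def window(self) -> ScoreWindow:
        return ScoreWindow(self.window_first_day, self.window_last_day)

    def weight_scheme(self) -> WeightScheme:
        pts = {SupportLevel.NONE: 0.0}
        for token, value in self.weights.items():
            pts[SupportLevel.from_token(token)] = float(value)
        return WeightScheme(pts)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class RunManifest:
    """Provenance of one pipeline run; counts reconcile read = scored + excluded."""

    version: str
    config_hash: str
    started_at: str
    finished_at: str
    input_digests: dict[str, str]
    n_read: int
    n_excluded_censored: int
    n_scored: int
    stages_completed: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def score_records(
    records: Sequence[PatientRecord], config: PipelineConfig
) -> tuple[list[PatientRecord], list[PatientRecord], list[ScoreResult]]:
    """Apply the censoring policy then score; returns (kept, excluded, scores)."""
    window = config.window()
    kept, excluded = filter_complete_followup(
        records, window, allow_truncated=config.allow_truncated_followup
    )
    weights = config.weight_scheme()
    scores = [
        compute_patient_auc(rec, weights, window, config.overlap_mode) for rec in kept
    ]
    return kept, excluded, scores


def _subgroup_variables(records, scores) -> list[tuple[str, GroupedScores]]:
    by_id = {s.patient_id: s.auc for s in scores}

    def grouped(name, key, subset) -> GroupedScores | None:
        groups: dict[str, list[float]] = {}
        for rec in subset:
            label = key(rec.covariates)
            groups.setdefault(label, []).append(by_id[rec.patient_id])
        groups = {k: v for k, v in groups.items() if v}
        return GroupedScores(name, groups) if len(groups) >= 2 else None

    allo = [
        r
        for r in records
        if r.covariates is not None and r.covariates.transplant_type == "allogeneic"
    ]
    candidates = [
        grouped("gender", lambda p: p.gender, records),
        grouped("age_group", lambda p: p.age_group, records),
        grouped("transplant_type", lambda p: p.transplant_type, records),
        grouped("disease", lambda p: p.disease, allo),
        grouped("cell_source", lambda p: p.cell_source, allo),
        grouped("tbi", lambda p: "yes" if p.tbi else "no", allo),
    ]
    return [(g.variable, g) for g in candidates if g is not None]


def subgroup_median_table(
    records: Sequence[PatientRecord],
    scores: Sequence[ScoreResult],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subgroup medians with bootstrap CIs and the group test p-value.

    Dichotomous variables use Student's t; three-level variables one-way
    ANOVA.  One row per subgroup level.
    """
    rows = []
    for variable, grouped in _subgroup_variables(records, scores):
        result = compare_groups(grouped)
        for level, values in grouped.groups.items():
            ci = median_with_bootstrap_ci(values, alpha, n_boot, seed)
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "n": len(values),
                    "median_auc": ci.median,
                    "ci_low": ci.ci_low,
                    "ci_high": ci.ci_high,
                    "p_value": result.p_value,
                    "method": result.method,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variable", "level", "n", "median_auc",
            "ci_low", "ci_high", "p_value", "method",
        ],
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate (optional) -> score -> summarize -> regress.

    All outputs land under ``config.out_dir``; any stage failure aborts
    with the completed-stage list in the partially written manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stages: list[str] = []
    digests: dict[str, str] = {}
    window = config.window()

    if config.simulate:
        cohort_cfg = CohortConfig(
            n_patients=config.n_patients,
            seed=config.seed,
            window=window,
            outcome_mode=config.outcome_mode,
        )
        model = (
            TransitionModel.from_json(Path(config.model_path).read_text())
            if config.model_path
            else default_transition_model()
        )
        records = generate_cohort(cohort_cfg, model)
        if config.outcome_mode == "logistic":
            attach_logistic_outcomes(
                records,
                weights=config.weight_scheme(),
                window=window,
                rng=np.random.default_rng(np.random.SeedSequence((config.seed, 1 << 20))),
            )
        write_episodes(out / "episodes.csv", records)
        write_covariates(out / "covariates.csv", records)
        log.info("event=simulate n=%d seed=%d", len(records), config.seed)
        stages.append("simulate")
    else:
        if not config.episodes_path or not config.covariates_path:
            raise ValidationError(
                "episodes_path and covariates_path required when simulate=False"
            )
        episodes = read_episodes(config.episodes_path)
        covariates = read_covariates(config.covariates_path)
        digests["episodes"] = _digest(Path(config.episodes_path))
        digests["covariates"] = _digest(Path(config.covariates_path))
        records = assemble_records(episodes, covariates, followup_days=window.length)
        log.info("event=read n=%d", len(records))

    n_read = len(records)
    kept, excluded, scores = score_records(records, config)
    write_scores(out / "scores.csv", kept, scores, window)
    log.info(
        "event=score read=%d excluded_censored=%d scored=%d",
        n_read, len(excluded), len(kept),
    )
    stages.append("score")

    summary = summarize_cohort(kept, scores)
    atomic_write_text(out / "summary.json", json.dumps(summary, indent=2))
    medians = subgroup_median_table(
        kept, scores, n_boot=config.n_boot, alpha=config.alpha, seed=config.seed
    )
    atomic_write_text(out / "subgroup_medians.csv", medians.to_csv(index=False))
    log.info("event=summarize subgroups=%d", len(medians))
    stages.append("summarize")

    spec = DesignSpec()
    X, y = build_design(kept, scores, spec, window)
    fit = fit_logistic(X, y, firth=config.firth)
    table = fit.summary.reset_index()
    atomic_write_text(out / "multivariable_model.csv", table.to_csv(index=False))
    bi = bivariable_screen(kept, scores, spec, window)
    atomic_write_text(out / "bivariable_model.csv", bi.reset_index().to_csv(index=False))
    roc = roc_curve(fit.predict(X), y)
    roc_df = pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds})
    atomic_write_text(out / "roc_points.csv", roc_df.to_csv(index=False))
    atomic_write_text(
        out / "forest_plot.csv", forest_plot_data(fit).to_csv(index=False)
    )
    report = {
        "n_obs": fit.n_obs,
        "log_likelihood": fit.log_likelihood,
        "iterations": fit.iterations,
        "converged": fit.converged,
        "auc_roc": roc.auc_roc,
        "or_per_scale": or_per_scale(fit, "auc", config.or_scale),
    }
    atomic_write_text(out / "fit_report.json", json.dumps(report, indent=2))
    log.info("event=regress n=%d auc_roc=%.3f", fit.n_obs, roc.auc_roc)
    stages.append("regress")

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(config.to_json().encode()).hexdigest(),
        started_at=started,
        finished_at=datetime.now(timezone.utc).isoformat(),
        input_digests=digests,
        n_read=n_read,
        n_excluded_censored=len(excluded),
        n_scored=len(kept),
        stages_completed=stages,
    )
    atomic_write_text(out / "manifest.json", manifest.to_json())
    return manifest
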