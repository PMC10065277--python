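"""End-to-end orchestration: cohort in, reproducible report bundle out.

The pipeline either simulates a cohort or ingests one from fixture files,
then runs preprocessing -> HRV -> behavioural extraction -> statistics and
writes a bundle of tidy CSV/JSON outputs plus a run log.  Re-running with
the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DesignError, PipelineError, UserInputError
from .hrv import HRVMeasure, pre_trigger_rmssd, window_rmssd
from .paradigm import (
    ATTRIBUTION_LEVELS,
    EYE_LEVELS,
    ConditionKey,
    DistanceTable,
    detect_episode_minima,
    extract_condition_distances,
    standardize_hrv,
)
from .preprocess import (
    CleaningReport,
    align_triggers,
    correct_artifacts,
    drop_incomplete,
    read_trigger_overrides,
    resample_proximity,
)
from .stats import (
    bootstrap_regression,
    chi_square,
    mann_whitney_rb,
    mixed_anova,
    power_simulation,
    spearman_fdr,
    summarize_groups,
)
from .stream_io import reconstruct_timestamps
from .synthetic import (
    ASD,
    CP,
    Cohort,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    read_cohort,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

#: drop below the initial distance that marks the start of the task, cm
_TASK_ONSET_DROP_CM = 20.0


@dataclass
class PipelineConfig:
    """Flat run configuration; flags override file keys in the CLI."""

    mode: str = "simulate"
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    baseline_span: tuple[float, float] = (0.0, 60.0)
    task_offset: tuple[float, float] = (60.0, 120.0)
    pre_trigger_span_s: float = 10.0
    separation_cm: float = 300.0
    alpha: float = 0.05
    n_boot: int = 2000
    power_reps: int = 0
    seed: int = 0
    output_dir: str = "proxhrv_out"
    trigger_overrides: str | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise UserInputError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not self.input_dir:
            raise UserInputError("ingest mode requires input_dir")
        if self.mode == "simulate" and self.input_dir:
            raise UserInputError("simulate mode must not set input_dir")
        for name in ("baseline_span", "task_offset"):
            a, b = getattr(self, name)
            if b <= a:
                raise UserInputError(f"{name} must be a positive span")
        if self.pre_trigger_span_s <= 0:
            raise UserInputError("pre_trigger_span_s must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in data and isinstance(data["simulation"], Mapping):
            data["simulation"] = config_from_dict(data["simulation"])
        for name in ("baseline_span", "task_offset"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"] = config_to_dict(self.simulation)
        out["baseline_span"] = list(self.baseline_span)
        out["task_offset"] = list(self.task_offset)
        return out


@dataclass
class ParticipantResult:
    participant: str
    group: str
    distances: DistanceTable
    pooled: dict
    task_start_s: float
    baseline: HRVMeasure | None = None
    task: HRVMeasure | None = None
    pre_trigger: dict[ConditionKey, HRVMeasure] = field(default_factory=dict)
    hrv_std: dict[ConditionKey, float] = field(default_factory=dict)
    cleaning: CleaningReport | None = None


@dataclass
class PipelineResult:
    bundle_dir: Path
    distances: pd.DataFrame
    hrv: pd.DataFrame
    stats: dict
    cleaning: dict
    participants: dict[str, ParticipantResult]


def detect_task_start(trace) -> float:
    """Task onset: first 1 Hz sample dropping markedly below the start level."""
    d = trace.distance_cm
    if len(d) == 0:
        raise UserInputError("empty trace")
    onset = np.flatnonzero(d < d[0] - _TASK_ONSET_DROP_CM)
    if onset.size == 0:
        raise UserInputError("no task movement found in trace")
    return float(trace.t_ms[0]) / 1000.0 + float(onset[0])


def _process_participant(session, config: PipelineConfig, overrides) -> ParticipantResult:
    pid = session.participant

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise PipelineError(name, pid, str(exc)) from exc

    resampled = stage("resample", resample_proximity, session.proximity)
    task_start = stage("task_onset", detect_task_start, resampled)
    triggers = stage(
        "detect_minima",
        detect_episode_minima,
        resampled,
        episode_order=session.episode_order,
        separation_cm=config.separation_cm,
    )
    triggers = stage("align_triggers", align_triggers, triggers, resampled, overrides)
    table = stage("extract_distances", extract_condition_distances, resampled, triggers)
    result = ParticipantResult(
        participant=pid,
        group=session.group,
        distances=table,
        pooled=table.pooled(),
        task_start_s=task_start,
    )
    if session.rr is not None:
        stream = stage("timestamps", reconstruct_timestamps, session.rr)
        stream, cleaning = stage("correct_artifacts", correct_artifacts, stream)
        result.cleaning = cleaning
        result.baseline = stage(
            "baseline_hrv", window_rmssd, stream, *config.baseline_span
        )
        result.task = stage(
            "task_hrv",
            window_rmssd,
            stream,
            task_start + config.task_offset[0],
            task_start + config.task_offset[1],
        )
        for trig in triggers:
            result.pre_trigger[trig.key] = stage(
                "pre_trigger_hrv",
                pre_trigger_rmssd,
                stream,
                trig.t_s,
                config.pre_trigger_span_s,
            )
        result.hrv_std = standardize_hrv(result.pre_trigger, result.baseline)
    return result


def _distances_frame(participants: dict[str, ParticipantResult]) -> pd.DataFrame:
    rows = []
    for pid in sorted(participants):
        res = participants[pid]
        for key, value in sorted(res.distances.raw.items()):
            rows.append(
                {
                    "participant": pid,
                    "group": res.group,
                    "eye_contact": key.eye_contact,
                    "attribution": key.attribution,
                    "role": key.role,
                    "distance_cm": value,
                }
            )
        for (eye, attribution), value in sorted(res.pooled.items()):
            rows.append(
                {
                    "participant": pid,
                    "group": res.group,
                    "eye_contact": eye,
                    "attribution": attribution,
                    "role": "pooled",
                    "distance_cm": value,
                }
            )
    return pd.DataFrame(rows)


def _hrv_frame(participants: dict[str, ParticipantResult]) -> pd.DataFrame:
    rows = []
    for pid in sorted(participants):
        res = participants[pid]
        if res.baseline is None:
            continue

        def row(window_type, condition, m: HRVMeasure, std=math.nan):
            return {
                "participant": pid,
                "group": res.group,
                "window_type": window_type,
                "condition": condition,
                "rmssd_ms": m.rmssd,
                "mean_hr_bpm": m.mean_hr,
                "n_beats": m.n_beats,
                "valid": m.valid,
                "rmssd_standardized": std,
            }

        rows.append(row("baseline", "", res.baseline))
        if res.task is not None:
            rows.append(row("task", "", res.task))
        for key in sorted(res.pre_trigger):
            rows.append(
                row("pre_trigger", str(key), res.pre_trigger[key], res.hrv_std.get(key, math.nan))
            )
    return pd.DataFrame(rows)


def _run_statistics(
    participants: dict[str, ParticipantResult],
    hrv_kept: dict[str, dict],
    metadata: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    stats: dict = {}
    # --- distance battery (all participants) -------------------------------
    mean_rows = [
        {
            "participant": pid,
            "group": res.group,
            "mean_distance_cm": res.distances.mean_distance(),
        }
        for pid, res in sorted(participants.items())
    ]
    mean_df = pd.DataFrame(mean_rows)
    summary = summarize_groups(mean_df, "mean_distance_cm", "group")
    stats["distance_group_summary"] = summary.to_dict(orient="records")
    stats["distance_mean_difference_cm"] = summary.attrs.get("mean_difference")
    asd = mean_df.loc[mean_df["group"] == ASD, "mean_distance_cm"].to_numpy()
    cp = mean_df.loc[mean_df["group"] == CP, "mean_distance_cm"].to_numpy()
    if asd.size and cp.size:
        mw = mann_whitney_rb(asd, cp)
        stats["distance_mann_whitney"] = {
            "U": mw.u, "r": mw.rank_biserial_r, "p": mw.p,
            "ci": [mw.ci_low, mw.ci_high], "n1": mw.n1, "n2": mw.n2,
        }

    pooled_rows = [
        {
            "participant": pid,
            "group": res.group,
            "eye_contact": eye,
            "attribution": attribution,
            "distance_cm": value,
        }
        for pid, res in sorted(participants.items())
        for (eye, attribution), value in sorted(res.pooled.items())
    ]
    pooled_df = pd.DataFrame(pooled_rows)
    anova = mixed_anova(
        pooled_df, dv="distance_cm", subject="participant", between="group",
        within=("eye_contact", "attribution"),
    )
    stats["distance_anova"] = anova.table.to_dict(orient="records")

    # --- HRV battery (complete-record participants only) -------------------
    covariate_cols = [c for c in ("caffeine", "smoking", "exercise") if c in metadata.columns]
    hrv_long = []
    for pid in sorted(hrv_kept):
        res = participants[pid]
        for time, m in (("baseline", res.baseline), ("interpersonal", res.task)):
            hrv_long.append(
                {"participant": pid, "group": res.group, "time": time, "rmssd": m.rmssd,
                 "mean_hr": m.mean_hr}
            )
    hrv_long = pd.DataFrame(hrv_long)
    if len(hrv_long) and hrv_long["participant"].nunique() >= 4:
        merged = hrv_long.merge(metadata, on="participant", how="left", suffixes=("", "_m"))
        # a covariate constant over the analysed subjects carries no information
        usable_covs = [c for c in covariate_cols if merged[c].nunique() > 1]
        for dv in ("rmssd", "mean_hr"):
            stats[f"{dv}_time_anova"] = mixed_anova(
                merged, dv=dv, subject="participant", between="group", within=("time",),
            ).table.to_dict(orient="records")
            if usable_covs:
                try:
                    stats[f"{dv}_time_ancova"] = mixed_anova(
                        merged, dv=dv, subject="participant", between="group",
                        within=("time",), covariates=usable_covs,
                    ).table.to_dict(orient="records")
                except DesignError as exc:
                    logger.warning("ANCOVA for %s skipped: %s", dv, exc)
                    stats[f"{dv}_time_ancova"] = {"skipped": str(exc)}

        std_rows = []
        for pid in sorted(hrv_kept):
            res = participants[pid]
            for eye in EYE_LEVELS:
                for attribution in ATTRIBUTION_LEVELS:
                    vals = [
                        res.hrv_std.get(ConditionKey(eye, attribution, role), math.nan)
                        for role in ("active", "passive")
                    ]
                    std_rows.append(
                        {
                            "participant": pid,
                            "group": res.group,
                            "eye_contact": eye,
                            "attribution": attribution,
                            "hrv_std": float(np.mean(vals)),
                            "distance_cm": res.pooled[(eye, attribution)],
                        }
                    )
        std_df = pd.DataFrame(std_rows).dropna()
        if std_df["participant"].nunique() >= 4:
            stats["hrv_std_anova"] = mixed_anova(
                std_df, dv="hrv_std", subject="participant", between="group",
                within=("eye_contact", "attribution"),
            ).table.to_dict(orient="records")

            # regression: distance ~ standardised HRV x group, bootstrap SEs
            X = pd.DataFrame(
                {
                    "hrv_std": std_df["hrv_std"].to_numpy(),
                    "group_cp": (std_df["group"] == CP).astype(float).to_numpy(),
                }
            )
            X["hrv_std_x_group"] = X["hrv_std"] * X["group_cp"]
            reg = bootstrap_regression(
                std_df["distance_cm"].to_numpy(), X,
                n_boot=config.n_boot, seed=config.seed,
            )
            stats["distance_regression"] = {
                "params": reg.params.reset_index(names="term").to_dict(orient="records"),
                "F": reg.f, "df1": reg.df1, "df2": reg.df2,
                "r_squared": reg.r_squared, "n_boot": reg.n_boot,
            }

        # exploratory Spearman screen, per group
        per_person = []
        for pid in sorted(hrv_kept):
            res = participants[pid]
            std_vals = [v for v in res.hrv_std.values() if not math.isnan(v)]
            per_person.append(
                {
                    "participant": pid,
                    "group": res.group,
                    "mean_distance": res.distances.mean_distance(),
                    "rmssd_baseline": res.baseline.rmssd,
                    "rmssd_task": res.task.rmssd,
                    "hrv_std_mean": float(np.mean(std_vals)) if std_vals else math.nan,
                }
            )
        pp = pd.DataFrame(per_person)
        for grp in (ASD, CP):
            sub = pp[pp["group"] == grp].drop(columns=["participant", "group"])
            if len(sub) >= 4:
                report = spearman_fdr(sub, level=config.alpha)
                stats[f"spearman_{grp.lower()}"] = {
                    "rho": report.rho.round(6).to_dict(),
                    "q": report.q.round(6).to_dict(),
                }

    # --- covariate contingency tests ---------------------------------------
    for cov in covariate_cols:
        table = pd.crosstab(metadata["group"], metadata[cov])
        if table.shape == (2, 2) and (table.to_numpy() > 0).all():
            cs = chi_square(table.to_numpy())
            stats[f"chi_square_{cov}"] = {"statistic": cs.statistic, "p": cs.p}

    # --- optional simulation-based power ------------------------------------
    if config.power_reps >= 100 and asd.size >= 2 and cp.size >= 2:
        pr = power_simulation(
            [
                (float(asd.mean()), float(asd.std(ddof=1)), asd.size),
                (float(cp.mean()), float(cp.std(ddof=1)), cp.size),
            ],
            n_reps=config.power_reps,
            alpha=config.alpha,
            seed=config.seed,
        )
        stats["distance_power_simulation"] = {
            "rejection_rate": pr.rejection_rate, "mc_se": pr.mc_se, "n_reps": pr.n_reps,
        }
    return stats


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain and write the report bundle to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim)
    else:
        cohort = read_cohort(config.input_dir)
    overrides = (
        read_trigger_overrides(config.trigger_overrides) if config.trigger_overrides else None
    )

    participants: dict[str, ParticipantResult] = {}
    hrv_records: dict[str, dict[str, HRVMeasure | None]] = {}
    for pid in sorted(cohort.sessions):
        session = cohort.sessions[pid]
        res = _process_participant(session, config, overrides)
        participants[pid] = res
        logger.info("processed %s (%s): task start %.0f s", pid, res.group, res.task_start_s)
        record: dict[str, HRVMeasure | None] = {"baseline": res.baseline, "task": res.task}
        for key in session.episode_order:
            record[f"pre_trigger:{key}"] = res.pre_trigger.get(key)
        hrv_records[pid] = record

    hrv_kept, drop_report = drop_incomplete(hrv_records)

    cleaning = {
        "n_replaced_threshold": sum(
            r.cleaning.n_replaced_threshold for r in participants.values() if r.cleaning
        ),
        "n_replaced_zscore": sum(
            r.cleaning.n_replaced_zscore for r in participants.values() if r.cleaning
        ),
        "participants_dropped": drop_report.participants_dropped,
        "per_participant": {
            pid: r.cleaning.to_dict() for pid, r in sorted(participants.items()) if r.cleaning
        },
    }

    distances = _distances_frame(participants)
    hrv = _hrv_frame(participants)
    stats = _run_statistics(participants, hrv_kept, cohort.metadata, config)
    stats["n_participants"] = len(participants)
    stats["n_hrv_complete"] = len(hrv_kept)

    distances.to_csv(out / "distances.csv", index=False)
    hrv.to_csv(out / "hrv.csv", index=False)
    (out / "cleaning_report.json").write_text(
        json.dumps(cleaning, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True, default=str) + "\n"
    )
    log_lines = [
        f"proxhrv {__version__}",
        "config:",
        yaml.safe_dump(config.to_dict(), sort_keys=True),
        f"participants: {len(participants)}; complete HRV records: {len(hrv_kept)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        bundle_dir=out,
        distances=distances,
        hrv=hrv,
        stats=stats,
        cleaning=cleaning,
        participants=participants,
    )
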