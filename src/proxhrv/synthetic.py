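"""Synthetic sessions with the statistical structure the analysis assumes.

Each simulated session mirrors the recorded paradigm: both parties start
5 m apart, a stationary baseline of at least 60 s precedes eight
approach-hold-return episodes, a chest-strap RR stream spans the whole
session, and the proximity channel carries bounded measurement noise.
Group-level presets default to the published sample's distance and HRV
summary statistics, so cohorts "shaped like the study" can be generated
with one call.

RR noise model: independent Gaussian deviations around a constant mean
with sd = target_rmssd / sqrt(2), which makes the expected RMSSD equal the
target (E[(RR_{i+1}-RR_i)^2] = 2 sigma^2).  Artifact spikes are drawn
uniformly from [1200, 2000] ms so that every injected artifact triggers the
threshold replacement rule.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import UserInputError
from .paradigm import (
    ConditionKey,
    Trigger,
    TriggerSet,
    all_condition_keys,
    block_episode_order,
    validate_episode_order,
)
from .stream_io import (
    RAW,
    ProximityTrace,
    RRSeries,
    read_proximity,
    read_rr_export,
    write_proximity,
    write_rr_export,
)

ASD = "ASD"
CP = "CP"
GROUPS = (ASD, CP)

#: floor of the truncated stop-distance distribution (intimate-zone bound), cm
STOP_DISTANCE_FLOOR_CM = 30.0
#: floor for drawn true RMSSD values, ms
RMSSD_FLOOR_MS = 3.0
_ARTIFACT_SPIKE_RANGE_MS = (1200.0, 2000.0)
_DEFAULT_START = datetime(2019, 11, 3, 10, 0, 0)


@dataclass(frozen=True)
class GroupPreset:
    """Population-level generative parameters for one study group."""

    distance_mean_cm: float
    distance_sd_cm: float
    baseline_rmssd_mean_ms: float
    baseline_rmssd_sd_ms: float
    task_rmssd_mean_ms: float
    task_rmssd_sd_ms: float
    baseline_rr_ms: float
    task_rr_ms: float

    def __post_init__(self):
        for name, value in dataclasses.asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


def paper_presets() -> dict[str, GroupPreset]:
    """Published per-group distance/HRV/HR summary statistics as presets.

    Mean RR values are derived from the reported mean heart rates
    (RR = 60000 / HR).
    """
    return {
        ASD: GroupPreset(
            distance_mean_cm=103.670,
            distance_sd_cm=47.322,
            baseline_rmssd_mean_ms=32.90,
            baseline_rmssd_sd_ms=15.97,
            task_rmssd_mean_ms=26.57,
            task_rmssd_sd_ms=8.79,
            baseline_rr_ms=60000.0 / 90.65,
            task_rr_ms=60000.0 / 96.66,
        ),
        CP: GroupPreset(
            distance_mean_cm=67.690,
            distance_sd_cm=28.589,
            baseline_rmssd_mean_ms=48.26,
            baseline_rmssd_sd_ms=26.68,
            task_rmssd_mean_ms=31.60,
            task_rmssd_sd_ms=16.11,
            baseline_rr_ms=60000.0 / 87.06,
            task_rr_ms=60000.0 / 91.68,
        ),
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; one seed drives all randomness."""

    n_asd: int = 22
    n_cp: int = 21
    presets: dict[str, GroupPreset] = field(default_factory=paper_presets)
    artifact_rate: float = 0.0
    approach_speed_cm_s: float = 50.0
    hold_duration_s: int = 10
    episode_order: tuple[ConditionKey, ...] | None = None
    seed: int = 0
    noise_cm: float = 10.0
    proximity_rate_hz: float = 1000.0
    baseline_duration_s: int = 70
    start_distance_cm: float = 500.0
    tail_s: int = 5
    caffeine_rate: float = 0.8
    smoking_rate: float = 0.15
    exercise_rate: float = 0.8
    missing_rr_rate: float = 0.0
    recording_start: datetime = _DEFAULT_START

    def __post_init__(self):
        if self.n_asd < 0 or self.n_cp < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if not 0.0 <= self.missing_rr_rate <= 1.0:
            raise ValueError("missing_rr_rate must lie in [0, 1]")
        for name in ("approach_speed_cm_s", "proximity_rate_hz", "start_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hold_duration_s < 1 or self.baseline_duration_s < 60:
            raise ValueError("hold must be >= 1 s and baseline >= 60 s")
        if self.noise_cm < 0:
            raise ValueError("noise_cm must be non-negative")
        if self.episode_order is not None:
            validate_episode_order(self.episode_order)
        if set(self.presets) != set(GROUPS):
            raise ValueError(f"presets must cover exactly the groups {GROUPS}")


@dataclass(frozen=True)
class TrueParams:
    """Planted ground truth of one session, for recovery testing."""

    stop_distance_cm: dict[ConditionKey, float]
    trigger_t_s: dict[ConditionKey, float]
    baseline_rmssd_ms: float
    task_rmssd_ms: float
    artifact_beats: np.ndarray
    task_start_s: float

    def __post_init__(self):
        for key, d in self.stop_distance_cm.items():
            if not 0 < d <= 500:
                raise ValueError(f"stop distance for {key} out of (0, 500] cm")


@dataclass
class Session:
    """One participant's recorded streams plus (for synthetic data) truth."""

    participant: str
    group: str
    rr: RRSeries | None
    proximity: ProximityTrace
    triggers: TriggerSet | None
    episode_order: tuple[ConditionKey, ...]
    truth: TrueParams | None = None


@dataclass
class Cohort:
    sessions: dict[str, Session]
    metadata: pd.DataFrame
    config: SimulationConfig


def _rr_values(
    rng: np.random.Generator,
    duration_s: float,
    mean_rr_ms: float,
    target_rmssd_ms: float,
    artifact_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw interval values spanning at least ``duration_s``, plus artifact indices."""
    sigma = target_rmssd_ms / math.sqrt(2.0)
    duration_ms = duration_s * 1000.0
    values = np.empty(0)
    while values.size == 0 or values.sum() < duration_ms:
        n_more = max(int((duration_ms - values.sum()) / mean_rr_ms * 1.2) + 8, 8)
        chunk = mean_rr_ms + rng.normal(0.0, sigma, n_more) if sigma > 0 else np.full(
            n_more, mean_rr_ms
        )
        values = np.concatenate([values, np.maximum(chunk, 1.0)])
    # keep beats up to and including the one that crosses duration
    n_keep = int(np.searchsorted(np.cumsum(values), duration_ms)) + 1
    values = values[:n_keep]
    if artifact_rate > 0:
        mask = rng.random(values.size) < artifact_rate
        values[mask] = rng.uniform(*_ARTIFACT_SPIKE_RANGE_MS, int(mask.sum()))
        artifact_idx = np.flatnonzero(mask)
    else:
        artifact_idx = np.empty(0, dtype=int)
    return values, artifact_idx


def simulate_rr_series(
    duration_s: float,
    mean_rr_ms: float,
    target_rmssd_ms: float,
    artifact_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    recording_start: datetime = _DEFAULT_START,
) -> RRSeries:
    """Simulate an RR stream whose expected RMSSD equals the target.

    Beats are generated until cumulative time reaches ``duration_s``; each
    beat is independently replaced by a long spike with probability
    ``artifact_rate``.
    """
    if duration_s <= 0:
        raise UserInputError("duration_s must be positive")
    if mean_rr_ms <= 0:
        raise UserInputError("mean_rr_ms must be positive")
    if target_rmssd_ms < 0:
        raise UserInputError("target_rmssd_ms must be non-negative")
    if not 0.0 <= artifact_rate <= 1.0:
        raise UserInputError("artifact_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values, _ = _rr_values(rng, duration_s, mean_rr_ms, target_rmssd_ms, artifact_rate)
    return RRSeries(values=values, recording_start=recording_start)


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lower: float, upper: float = math.inf
) -> float:
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_session(
    group_label: str,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    participant: str = "p01",
    eye_first: bool | None = None,
    recording_start: datetime | None = None,
) -> Session:
    """Simulate one session: proximity trace, triggers, RR stream, truth.

    The trace starts at 500 cm, holds a stationary baseline, then runs the
    eight approach-hold-return episodes of ``episode_order``.  Per-episode
    minima equal that condition's true stop distance (truncated-normal draw,
    floor 30 cm) plus uniform measurement noise bounded by ``noise_cm``.
    Approach durations are rounded up to whole seconds so each planted
    minimum falls exactly on a 1 Hz bin boundary.
    """
    if group_label not in GROUPS:
        raise UserInputError(f"group_label must be one of {GROUPS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if recording_start is None:
        recording_start = config.recording_start
    if config.episode_order is not None:
        order = tuple(config.episode_order)
    else:
        if eye_first is None:
            eye_first = bool(rng.random() < 0.5)
        order = block_episode_order(eye_first=eye_first)
    validate_episode_order(order)
    preset = config.presets[group_label]
    start_d = config.start_distance_cm

    knot_t: list[float] = [0.0, float(config.baseline_duration_s)]
    knot_d: list[float] = [start_d, start_d]
    stop_distance: dict[ConditionKey, float] = {}
    trigger_t: dict[ConditionKey, float] = {}
    cur_t = float(config.baseline_duration_s)
    for key in order:
        stop = _draw_truncnorm(
            rng, preset.distance_mean_cm, preset.distance_sd_cm,
            STOP_DISTANCE_FLOOR_CM, start_d,
        )
        leg = math.ceil((start_d - stop) / config.approach_speed_cm_s)
        arrival = cur_t + leg
        knot_t += [arrival, arrival + config.hold_duration_s, arrival + config.hold_duration_s + leg]
        knot_d += [stop, stop, start_d]
        stop_distance[key] = stop
        trigger_t[key] = arrival
        cur_t = arrival + config.hold_duration_s + leg
    total_s = cur_t + config.tail_s

    step_ms = 1000.0 / config.proximity_rate_hz
    t_ms = np.arange(0.0, total_s * 1000.0, step_ms)
    d = np.interp(t_ms / 1000.0, knot_t, knot_d)
    if config.noise_cm > 0:
        d = d + rng.uniform(-config.noise_cm, config.noise_cm, d.size)
    trace = ProximityTrace(t_ms=t_ms, distance_cm=np.maximum(d, 0.0), resolution=RAW)

    baseline_rmssd = _draw_truncnorm(
        rng, preset.baseline_rmssd_mean_ms, preset.baseline_rmssd_sd_ms, RMSSD_FLOOR_MS
    )
    task_rmssd = _draw_truncnorm(
        rng, preset.task_rmssd_mean_ms, preset.task_rmssd_sd_ms, RMSSD_FLOOR_MS
    )
    task_start = float(config.baseline_duration_s)
    v_base, _ = _rr_values(rng, task_start, preset.baseline_rr_ms, baseline_rmssd, 0.0)
    v_task, _ = _rr_values(
        rng, total_s - v_base.sum() / 1000.0, preset.task_rr_ms, task_rmssd, 0.0
    )
    values = np.concatenate([v_base, v_task])
    if config.artifact_rate > 0:
        mask = rng.random(values.size) < config.artifact_rate
        values[mask] = rng.uniform(*_ARTIFACT_SPIKE_RANGE_MS, int(mask.sum()))
        artifact_idx = np.flatnonzero(mask)
    else:
        artifact_idx = np.empty(0, dtype=int)
    rr = RRSeries(values=values, recording_start=recording_start)

    triggers = TriggerSet(
        triggers=tuple(Trigger(t_s=trigger_t[k], key=k) for k in order)
    )
    truth = TrueParams(
        stop_distance_cm=stop_distance,
        trigger_t_s=trigger_t,
        baseline_rmssd_ms=baseline_rmssd,
        task_rmssd_ms=task_rmssd,
        artifact_beats=artifact_idx,
        task_start_s=task_start,
    )
    return Session(
        participant=participant,
        group=group_label,
        rr=rr,
        proximity=trace,
        triggers=triggers,
        episode_order=order,
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate independent sessions for every participant plus metadata.

    All randomness descends from ``config.seed`` through spawned child
    streams, so identical configs produce identical cohorts.
    """
    if config.n_asd < 1 or config.n_cp < 1:
        raise UserInputError("each group needs at least one participant")
    n_total = config.n_asd + config.n_cp
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    labels = [(ASD, i + 1) for i in range(config.n_asd)] + [
        (CP, i + 1) for i in range(config.n_cp)
    ]
    sessions: dict[str, Session] = {}
    rows = []
    for k, ((group, num), child) in enumerate(zip(labels, children)):
        pid = f"{group.lower()}{num:02d}"
        rng = np.random.default_rng(child)
        eye_first = bool(rng.random() < 0.5)
        caffeine = int(rng.random() < config.caffeine_rate)
        smoking = int(rng.random() < config.smoking_rate)
        exercise = int(rng.random() < config.exercise_rate)
        missing_rr = bool(rng.random() < config.missing_rr_rate)
        session = simulate_session(
            group,
            config,
            seed=rng,
            participant=pid,
            eye_first=eye_first,
            recording_start=config.recording_start + timedelta(minutes=30 * k),
        )
        if missing_rr:
            session.rr = None
        sessions[pid] = session
        rows.append(
            {
                "participant": pid,
                "group": group,
                "eye_first": int(eye_first),
                "caffeine": caffeine,
                "smoking": smoking,
                "exercise": exercise,
                "has_rr": int(session.rr is not None),
            }
        )
    return Cohort(sessions=sessions, metadata=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# fixture serialisation (same dialects stream_io reads)

def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["recording_start"] = config.recording_start.isoformat()
    out["episode_order"] = (
        [str(k) for k in config.episode_order] if config.episode_order else None
    )
    out["presets"] = {g: dataclasses.asdict(p) for g, p in config.presets.items()}
    return out


def config_from_dict(data: Mapping) -> SimulationConfig:
    data = dict(data)
    if "recording_start" in data and isinstance(data["recording_start"], str):
        data["recording_start"] = datetime.fromisoformat(data["recording_start"])
    if data.get("episode_order"):
        data["episode_order"] = tuple(
            ConditionKey.from_string(s) for s in data["episode_order"]
        )
    if "presets" in data:
        data["presets"] = {g: GroupPreset(**p) for g, p in data["presets"].items()}
    return SimulationConfig(**data)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as plain-text fixtures readable by the ingest path.

    Layout: ``metadata.csv`` and ``config.yaml`` at the root, one directory
    per participant containing the RR export (timestamped filename), the
    proximity CSV, and the planted truth as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(directory / "metadata.csv", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cohort.config), fh, sort_keys=True)
    for pid, session in cohort.sessions.items():
        pdir = directory / pid
        pdir.mkdir(exist_ok=True)
        if session.rr is not None:
            write_rr_export(session.rr, pdir)
        write_proximity(session.proximity, pdir / "proximity.csv")
        if session.truth is not None:
            truth = {
                "stop_distance_cm": {str(k): v for k, v in session.truth.stop_distance_cm.items()},
                "trigger_t_s": {str(k): v for k, v in session.truth.trigger_t_s.items()},
                "baseline_rmssd_ms": session.truth.baseline_rmssd_ms,
                "task_rmssd_ms": session.truth.task_rmssd_ms,
                "task_start_s": session.truth.task_start_s,
                "artifact_beats": session.truth.artifact_beats.tolist(),
            }
            (pdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Read a fixture cohort written by :func:`write_cohort`.

    Triggers and truth are not reloaded; the pipeline re-derives triggers
    from the proximity trace exactly as it would for real recordings.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    if not meta_path.exists():
        raise UserInputError(f"no metadata.csv in {directory}")
    metadata = pd.read_csv(meta_path)
    config_path = directory / "config.yaml"
    config = (
        config_from_dict(yaml.safe_load(config_path.read_text()))
        if config_path.exists()
        else SimulationConfig()
    )
    sessions: dict[str, Session] = {}
    for row in metadata.itertuples():
        pid = str(row.participant)
        pdir = directory / pid
        rr = None
        rr_files = sorted(pdir.glob("*.txt"))
        if rr_files and getattr(row, "has_rr", 1):
            rr = read_rr_export(rr_files[0])
        trace = read_proximity(pdir / "proximity.csv")
        sessions[pid] = Session(
            participant=pid,
            group=str(row.group),
            rr=rr,
            proximity=trace,
            triggers=None,
            episode_order=block_episode_order(eye_first=bool(row.eye_first)),
            truth=None,
        )
    return Cohort(sessions=sessions, metadata=metadata, config=config)
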