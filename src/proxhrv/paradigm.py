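"""Behavioural measures of the eight-episode approach task.

A session consists of eight approach-hold-return episodes crossing eye
contact (yes/no) x attribution (self/other) x role (active/passive).  The
per-episode minimum of the proximity trace is the preferred interpersonal
distance for that condition; active and passive cells are pooled by
averaging for analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import UserInputError
from .hrv import HRVMeasure
from .stream_io import RESAMPLED_1HZ, ProximityTrace

logger = logging.getLogger(__name__)

EYE_LEVELS = ("yes", "no")
ATTRIBUTION_LEVELS = ("self", "other")
ROLE_LEVELS = ("active", "passive")

#: default episode-segmentation threshold, between stop distances and the
#: 500 cm reset point
DEFAULT_SEPARATION_CM = 300.0


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One cell of the eye-contact x attribution x role crossing."""

    eye_contact: str
    attribution: str
    role: str

    def __post_init__(self):
        if self.eye_contact not in EYE_LEVELS:
            raise ValueError(f"eye_contact must be one of {EYE_LEVELS}")
        if self.attribution not in ATTRIBUTION_LEVELS:
            raise ValueError(f"attribution must be one of {ATTRIBUTION_LEVELS}")
        if self.role not in ROLE_LEVELS:
            raise ValueError(f"role must be one of {ROLE_LEVELS}")

    def __str__(self) -> str:
        return f"{self.eye_contact}-{self.attribution}-{self.role}"

    @classmethod
    def from_string(cls, s: str) -> "ConditionKey":
        parts = s.split("-")
        if len(parts) != 3:
            raise ValueError(f"cannot parse condition key {s!r}")
        return cls(*parts)


def all_condition_keys() -> tuple[ConditionKey, ...]:
    """The full crossing, eight keys."""
    return tuple(
        ConditionKey(e, a, r)
        for e, a, r in itertools.product(EYE_LEVELS, ATTRIBUTION_LEVELS, ROLE_LEVELS)
    )


def block_episode_order(eye_first: bool = True) -> tuple[ConditionKey, ...]:
    """Episode order as run in a session: two eye-contact blocks of four.

    Within each block the sequence is active/self, active/other,
    passive/self, passive/other.  ``eye_first`` selects which block leads
    (the block order was randomised across participants).
    """
    blocks = ("yes", "no") if eye_first else ("no", "yes")
    within = [("active", "self"), ("active", "other"), ("passive", "self"), ("passive", "other")]
    return tuple(ConditionKey(e, a, r) for e in blocks for r, a in within)


def validate_episode_order(order: Sequence[ConditionKey]) -> None:
    if len(order) != 8:
        raise ValueError(f"episode order must have exactly 8 entries, got {len(order)}")
    if set(order) != set(all_condition_keys()):
        raise ValueError("episode order must cover the full 2x2x2 crossing exactly once")


@dataclass(frozen=True)
class Trigger:
    t_s: float
    key: ConditionKey


@dataclass(frozen=True)
class TriggerSet:
    """The eight labelled episode-minimum time points of a session."""

    triggers: tuple[Trigger, ...]

    def __post_init__(self):
        ts = [tr.t_s for tr in self.triggers]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("trigger times must be strictly increasing")
        keys = [tr.key for tr in self.triggers]
        if len(set(keys)) != len(keys):
            raise ValueError("trigger keys must be pairwise distinct")
        if len(keys) == 8 and set(keys) != set(all_condition_keys()):
            raise ValueError("an 8-trigger set must cover the full crossing")

    def __len__(self) -> int:
        return len(self.triggers)

    def __iter__(self):
        return iter(self.triggers)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([tr.t_s for tr in self.triggers])

    @property
    def keys(self) -> tuple[ConditionKey, ...]:
        return tuple(tr.key for tr in self.triggers)


PooledKey = tuple[str, str]  # (eye_contact, attribution)


@dataclass(frozen=True)
class DistanceTable:
    """Per-condition preferred distances (cm) for one participant.

    ``raw`` holds up to eight cells keyed by :class:`ConditionKey`.  The
    pooled view averages the active and passive cells of each eye-contact x
    attribution pair; a pooled cell whose raw cells are incomplete is NaN.
    """

    raw: Mapping[ConditionKey, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, value in self.raw.items():
            if not math.isnan(value) and value < 0:
                raise ValueError(f"negative distance for {key}")

    def pooled(self) -> dict[PooledKey, float]:
        out: dict[PooledKey, float] = {}
        for eye in EYE_LEVELS:
            for attribution in ATTRIBUTION_LEVELS:
                cells = [
                    self.raw.get(ConditionKey(eye, attribution, role), math.nan)
                    for role in ROLE_LEVELS
                ]
                if any(math.isnan(c) for c in cells):
                    logger.warning(
                        "pooled cell (%s, %s) marked missing: incomplete raw cells",
                        eye,
                        attribution,
                    )
                    out[(eye, attribution)] = math.nan
                else:
                    out[(eye, attribution)] = float(np.mean(cells))
        return out

    def mean_distance(self) -> float:
        """Grand mean over the available raw cells (NaN if none)."""
        vals = [v for v in self.raw.values() if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan


def detect_episode_minima(
    trace: ProximityTrace,
    episode_order: Sequence[ConditionKey] | None = None,
    n_expected: int = 8,
    separation_cm: float = DEFAULT_SEPARATION_CM,
) -> TriggerSet:
    """Locate the per-episode distance minima of a resampled trace.

    Episodes are the maximal runs of samples strictly below ``separation_cm``;
    within each run the earliest sample attaining the minimum is taken.  The
    run count must equal ``n_expected`` or an error names the count found.
    Condition labels are attached from ``episode_order`` (session run order).
    """
    if trace.resolution != RESAMPLED_1HZ:
        raise UserInputError("detect_episode_minima expects a 1 Hz resampled trace")
    if episode_order is None:
        episode_order = block_episode_order()
    if len(episode_order) != n_expected:
        raise UserInputError(
            f"episode order has {len(episode_order)} entries, expected {n_expected}"
        )
    d = trace.distance_cm
    below = d < separation_cm
    # run boundaries of the below-threshold mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    if len(starts) != n_expected:
        raise UserInputError(
            f"found {len(starts)} episodes below {separation_cm:g} cm, expected {n_expected}"
        )
    t0_s = float(trace.t_ms[0]) / 1000.0
    triggers = []
    for key, a, b in zip(episode_order, starts, stops):
        idx = a + int(np.argmin(d[a:b]))  # argmin returns the earliest on ties
        triggers.append(Trigger(t_s=t0_s + float(idx), key=key))
    return TriggerSet(triggers=tuple(triggers))


def extract_condition_distances(trace: ProximityTrace, triggers: TriggerSet) -> DistanceTable:
    """Read the trace value at each trigger time into a raw distance table."""
    if trace.resolution != RESAMPLED_1HZ:
        raise UserInputError("extract_condition_distances expects a 1 Hz resampled trace")
    t0_s = float(trace.t_ms[0]) / 1000.0
    raw: dict[ConditionKey, float] = {}
    for tr in triggers:
        idx = int(round(tr.t_s - t0_s))
        if idx < 0 or idx >= len(trace):
            raise UserInputError(
                f"trigger {tr.key} at t={tr.t_s:g} s lies outside the trace span"
            )
        raw[tr.key] = float(trace.distance_cm[idx])
    return DistanceTable(raw=raw)


def pool_active_passive(table: DistanceTable) -> dict[PooledKey, float]:
    """Average active and passive cells into the four pooled condition cells."""
    return table.pooled()


def standardize_hrv(
    task_hrv: Mapping[ConditionKey, HRVMeasure], baseline_hrv: HRVMeasure
) -> dict[ConditionKey, float]:
    """Per-person HRV standardisation: condition RMSSD / baseline RMSSD.

    An invalid or zero baseline propagates NaN to every condition (logged);
    an invalid condition measure yields NaN for that condition only.
    """
    if not baseline_hrv.valid or not baseline_hrv.rmssd > 0:
        logger.warning("baseline HRV invalid or zero; standardised HRV undefined")
        return {key: math.nan for key in task_hrv}
    out: dict[ConditionKey, float] = {}
    for key, measure in task_hrv.items():
        out[key] = measure.rmssd / baseline_hrv.rmssd if measure.valid else math.nan
    return out
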