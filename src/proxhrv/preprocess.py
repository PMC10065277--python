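"""Cleaning and synchronisation: per-second median resampling of the
proximity stream, RR artifact replacement, listwise missing-data policy,
and trigger alignment to local minima."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UserInputError
from .hrv import HRVMeasure
from .paradigm import Trigger, TriggerSet
from .stream_io import RAW, RESAMPLED_1HZ, ProximityTrace, TimestampedRR

logger = logging.getLogger(__name__)

#: replacement threshold for implausibly long intervals, ms (inclusive)
RR_THRESHOLD_MS = 1200.0
#: absolute Z-score bound for the second replacement rule
RR_ZSCORE_BOUND = 2.0
#: trigger snap radius, seconds
TRIGGER_SNAP_RADIUS_S = 5.0


@dataclass
class CleaningReport:
    """Audit trail of what cleaning changed and who was excluded."""

    n_replaced_threshold: int = 0
    n_replaced_zscore: int = 0
    replacement_value_ms: float = float("nan")
    participants_dropped: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_replaced_threshold < 0 or self.n_replaced_zscore < 0:
            raise ValueError("replacement counts must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def resample_proximity(trace: ProximityTrace) -> ProximityTrace:
    """Resample a raw trace to 1 Hz by taking the median of each second.

    Second bins are half-open ``[k, k+1)`` anchored at the first sample time.
    Bins with no samples are linearly interpolated from their neighbours and
    flagged in ``interpolated``.  Even-count bins use the mean-of-two-middle
    median.  An empty trace resamples to an empty trace.
    """
    if trace.resolution == RESAMPLED_1HZ:
        return trace
    if len(trace) == 0:
        return ProximityTrace(
            t_ms=np.empty(0), distance_cm=np.empty(0), resolution=RESAMPLED_1HZ,
            interpolated=np.empty(0, dtype=bool),
        )
    t0 = float(trace.t_ms[0])
    bins = np.floor((trace.t_ms - t0) / 1000.0).astype(int)
    n_bins = int(bins[-1]) + 1
    med = np.full(n_bins, np.nan)
    grouped = pd.Series(trace.distance_cm).groupby(bins).median()
    med[grouped.index.to_numpy()] = grouped.to_numpy()
    empty = np.isnan(med)
    if empty.any():
        filled = np.flatnonzero(~empty)
        med[empty] = np.interp(np.flatnonzero(empty), filled, med[filled])
        logger.info("interpolated %d empty second bin(s)", int(empty.sum()))
    return ProximityTrace(
        t_ms=t0 + np.arange(n_bins, dtype=float) * 1000.0,
        distance_cm=med,
        resolution=RESAMPLED_1HZ,
        interpolated=empty,
    )


def correct_artifacts(stream: TimestampedRR) -> tuple[TimestampedRR, CleaningReport]:
    """Replace artifactual beats with the raw-series median, single pass.

    A beat is flagged when its interval is >= 1200 ms, or when its absolute
    Z score on the raw (pre-replacement) series exceeds 2.  Mean, SD (sample,
    ddof=1) and the replacement median are all computed on the raw series.
    Timestamps and stream length are never altered.  A beat matching both
    rules is counted once, under the threshold rule.  A zero-SD series has
    no defined Z scores; the Z rule is skipped and logged.
    """
    if len(stream) == 0:
        raise UserInputError("cannot correct an empty RR stream")
    rr = stream.rr
    median = float(np.median(rr))
    over_threshold = rr >= RR_THRESHOLD_MS
    sd = float(np.std(rr, ddof=1)) if len(stream) > 1 else 0.0
    report = CleaningReport(replacement_value_ms=median)
    if sd > 0:
        z = (rr - np.mean(rr)) / sd
        over_z = np.abs(z) > RR_ZSCORE_BOUND
    else:
        over_z = np.zeros(len(stream), dtype=bool)
        logger.warning("RR series has zero variance; Z-score rule skipped")
        report.notes.append("zero-variance series: Z-score rule skipped")
    flagged = over_threshold | over_z
    report.n_replaced_threshold = int(over_threshold.sum())
    report.n_replaced_zscore = int((over_z & ~over_threshold).sum())
    corrected = np.where(flagged, median, rr)
    return (
        TimestampedRR(t=stream.t.copy(), rr=corrected, recording_start=stream.recording_start),
        report,
    )


def drop_incomplete(
    hrv_records: Mapping[str, Mapping[str, HRVMeasure | None]],
) -> tuple[dict[str, dict[str, HRVMeasure]], CleaningReport]:
    """Listwise exclusion of participants with an incomplete HRV record.

    ``hrv_records`` maps participant id -> named required windows.  A
    participant is kept only if every required window is present and valid.
    The report lists each dropped participant with the offending windows.
    Callers keep dropped participants in distance-only analyses.
    """
    kept: dict[str, dict[str, HRVMeasure]] = {}
    report = CleaningReport()
    for pid, windows in hrv_records.items():
        bad = [
            name
            for name, measure in windows.items()
            if measure is None or not measure.valid
        ]
        if bad:
            report.participants_dropped.append(
                {"participant": pid, "reason": f"invalid or missing HRV window(s): {sorted(bad)}"}
            )
            logger.info("dropping %s from HRV analyses: %s", pid, sorted(bad))
        else:
            kept[pid] = dict(windows)
    return kept, report


def _local_minima(d: np.ndarray) -> np.ndarray:
    """Indices of samples not exceeded by either neighbour (plateaus included)."""
    if d.size == 0:
        return np.empty(0, dtype=int)
    left = np.r_[True, d[1:] <= d[:-1]]
    right = np.r_[d[:-1] <= d[1:], True]
    return np.flatnonzero(left & right)


def align_triggers(
    triggers: TriggerSet,
    trace: ProximityTrace,
    overrides: Mapping[int, float] | None = None,
    snap_radius_s: float = TRIGGER_SNAP_RADIUS_S,
) -> TriggerSet:
    """Snap each trigger to the nearest local minimum within the radius.

    Operates on the 1 Hz trace; a trigger with no local minimum inside
    ``snap_radius_s`` is left unchanged.  ``overrides`` maps trigger index
    (0-based) to an exact time and is applied last.  Triggers that collide or
    lose their ordering after adjustment raise an error naming the collision.
    """
    if trace.resolution != RESAMPLED_1HZ:
        raise UserInputError("align_triggers expects a 1 Hz resampled trace")
    t0_s = float(trace.t_ms[0]) / 1000.0
    minima_t = t0_s + _local_minima(trace.distance_cm).astype(float)
    new_times = []
    for tr in triggers:
        if minima_t.size:
            gaps = np.abs(minima_t - tr.t_s)
            j = int(np.argmin(gaps))  # ties resolve to the earlier minimum
            new_times.append(float(minima_t[j]) if gaps[j] <= snap_radius_s else tr.t_s)
        else:
            new_times.append(tr.t_s)
    if overrides:
        for idx, t_s in overrides.items():
            if not 0 <= idx < len(new_times):
                raise UserInputError(f"override index {idx} out of range")
            new_times[idx] = float(t_s)
    for i, (a, b) in enumerate(zip(new_times, new_times[1:])):
        if b <= a:
            raise UserInputError(
                f"triggers {i} and {i + 1} collide after alignment (t={a:g} s, t={b:g} s)"
            )
    return TriggerSet(
        triggers=tuple(
            Trigger(t_s=t, key=tr.key) for t, tr in zip(new_times, triggers)
        )
    )


def read_trigger_overrides(path: str | Path) -> dict[int, float]:
    """Read a ``trigger_index,t_s`` override CSV."""
    df = pd.read_csv(path)
    for col in ("trigger_index", "t_s"):
        if col not in df.columns:
            raise UserInputError(f"override file missing column {col!r}")
    return {int(row.trigger_index): float(row.t_s) for row in df.itertuples()}
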