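"""Readers/writers for the two wearable stream formats.

RR export
    Plain text, one interbeat interval in milliseconds per line, recording
    start time encoded in the filename as ``YYYY-MM-DD_HH-MM-SS.txt``, e.g.::

        2019-11-03_10-15-00.txt
        ------------------------
        812
        805
        819.5

    Blank lines are tolerated and skipped.

Proximity trace
    Two-column CSV with header ``t_ms,distance_cm``; ``t_ms`` is milliseconds
    since trace start, ``distance_cm`` the measured separation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StreamFormatError

logger = logging.getLogger(__name__)

#: strftime pattern encoded in RR export filenames.
FILENAME_TIME_FORMAT = "%Y-%m-%d_%H-%M-%S"
_FILENAME_RE = re.compile(r"(\d{4}-\d{2}-\d{2}_\d{2}-\d{2}-\d{2})")

RAW = "raw"
RESAMPLED_1HZ = "1hz"


@dataclass(frozen=True)
class RRSeries:
    """An ordered stream of interbeat intervals (ms) with an absolute start time."""

    values: np.ndarray
    recording_start: datetime

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("RR values must be one-dimensional")
        if values.size and np.any(values <= 0):
            raise ValueError("RR intervals must be strictly positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TimestampedRR:
    """Beat-anchored RR stream: t[i] is seconds elapsed from recording start.

    The i-th timestamp is the cumulative sum of intervals 1..i, so the final
    timestamp equals the total recorded duration.
    """

    t: np.ndarray
    rr: np.ndarray
    recording_start: datetime | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if t.shape != rr.shape:
            raise ValueError("t and rr must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "rr", rr)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class ProximityTrace:
    """Distance samples (cm) over time (ms since trace start).

    ``resolution`` is ``"raw"`` for device-rate data and ``"1hz"`` after
    per-second median resampling.  ``interpolated`` marks 1 Hz samples that
    were filled from neighbours because their second bin was empty.
    """

    t_ms: np.ndarray
    distance_cm: np.ndarray
    resolution: str = RAW
    interpolated: np.ndarray | None = field(default=None)

    def __post_init__(self):
        t = np.asarray(self.t_ms, dtype=float)
        d = np.asarray(self.distance_cm, dtype=float)
        if t.shape != d.shape:
            raise ValueError("t_ms and distance_cm must have equal length")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("t_ms must be non-decreasing")
        if d.size and np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if self.resolution not in (RAW, RESAMPLED_1HZ):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "distance_cm", d)

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.t_ms[-1] - self.t_ms[0]) / 1000.0


def parse_start_time(filename: str | Path) -> datetime:
    """Extract the recording start time from an RR export filename."""
    stem = Path(filename).name
    m = _FILENAME_RE.search(stem)
    if m is None:
        raise StreamFormatError(
            f"cannot parse a start time from {stem!r}; expected a filename "
            f"containing a timestamp like 2019-11-03_10-15-00 "
            f"(pattern {FILENAME_TIME_FORMAT})"
        )
    return datetime.strptime(m.group(1), FILENAME_TIME_FORMAT)


def read_rr_export(path: str | Path, recording_start: datetime | None = None) -> RRSeries:
    """Read a one-interval-per-line RR export.

    Parameters
    ----------
    path
        Text file; its name must encode the start time unless
        ``recording_start`` is given explicitly.
    recording_start
        Overrides filename parsing (for exports with nonstandard names).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if recording_start is None:
        recording_start = parse_start_time(path)
    values: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise StreamFormatError(
                f"{path.name}: line {lineno}: {token!r} is not a number"
            ) from None
    if not values:
        raise StreamFormatError(f"{path.name}: file contains no RR intervals")
    return RRSeries(values=np.asarray(values), recording_start=recording_start)


def write_rr_export(series: RRSeries, directory: str | Path) -> Path:
    """Write ``series`` to ``directory`` using the filename time convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{series.recording_start.strftime(FILENAME_TIME_FORMAT)}.txt"
    path.write_text("\n".join(repr(float(v)) for v in series.values) + "\n")
    return path


def reconstruct_timestamps(series: RRSeries) -> TimestampedRR:
    """Rebuild per-beat timestamps from bare intervals.

    Each interval is appended to the time of the previous beat, so
    ``t[i] = sum(rr[0..i]) / 1000`` seconds after recording start; the first
    beat sits at ``rr[0]/1000``, and the final timestamp equals the total
    recorded duration.  An empty series yields an empty result.
    """
    if len(series) == 0:
        return TimestampedRR(
            t=np.empty(0), rr=np.empty(0), recording_start=series.recording_start
        )
    t = np.cumsum(series.values) / 1000.0
    return TimestampedRR(t=t, rr=series.values.copy(), recording_start=series.recording_start)


def read_proximity(path: str | Path) -> ProximityTrace:
    """Read a ``t_ms,distance_cm`` CSV proximity trace.

    Negative distances are clamped to zero with a logged warning; a missing
    column is an error; a header-only file yields an empty trace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_ms", "distance_cm"):
        if col not in df.columns:
            raise StreamFormatError(f"{path.name}: missing required column {col!r}")
    if df.empty:
        logger.warning("%s: proximity file has a header but no samples", path.name)
        return ProximityTrace(t_ms=np.empty(0), distance_cm=np.empty(0), resolution=RAW)
    d = df["distance_cm"].to_numpy(dtype=float)
    negative = d < 0
    if negative.any():
        logger.warning(
            "%s: clamped %d negative distance sample(s) to 0", path.name, int(negative.sum())
        )
        d = np.where(negative, 0.0, d)
    return ProximityTrace(t_ms=df["t_ms"].to_numpy(dtype=float), distance_cm=d, resolution=RAW)


def write_proximity(trace: ProximityTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees an exact float round trip through the text format
    pd.DataFrame({"t_ms": trace.t_ms, "distance_cm": trace.distance_cm}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path
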