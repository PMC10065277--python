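"""Time-domain HRV over analysis windows.

RMSSD is the root mean square of successive interbeat-interval differences,
with the denominator equal to the number of differences (N-1 for N beats).
Windows are half-open ``(start, end]`` so that a beat falling exactly on a
boundary belongs to exactly one of two adjacent windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .stream_io import TimestampedRR

logger = logging.getLogger(__name__)

#: default span of the pre-trigger ultra-short-term window, seconds
PRE_TRIGGER_SPAN_S = 10.0


@dataclass(frozen=True)
class HRVMeasure:
    """RMSSD (ms) and mean heart rate (bpm) over one time window.

    ``valid`` is False when fewer than two beats fall inside the window, in
    which case ``rmssd`` and ``mean_hr`` are NaN.
    """

    window_start: float
    window_end: float
    rmssd: float
    mean_hr: float
    n_beats: int
    valid: bool

    def __post_init__(self):
        if self.window_end <= self.window_start:
            raise ValueError("window_end must exceed window_start")
        if self.valid and self.n_beats < 2:
            raise ValueError("a valid measure needs at least 2 beats")


def rmssd(rr_values) -> float:
    """RMSSD in ms; NaN when fewer than two intervals are supplied."""
    rr = np.asarray(rr_values, dtype=float)
    if rr.size < 2:
        return math.nan
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def window_rmssd(stream: TimestampedRR, start_s: float, end_s: float) -> HRVMeasure:
    """RMSSD and mean HR for beats with timestamp in ``(start_s, end_s]``.

    Mean HR is ``60000 / mean(rr)`` over the selected beats (beat-weighted).
    Fewer than two beats in the window makes the measure invalid, not an error.
    """
    if end_s <= start_s:
        raise ValueError("window end must exceed window start")
    mask = (stream.t > start_s) & (stream.t <= end_s)
    rr = stream.rr[mask]
    n = int(rr.size)
    if n < 2:
        return HRVMeasure(
            window_start=float(start_s),
            window_end=float(end_s),
            rmssd=math.nan,
            mean_hr=math.nan,
            n_beats=n,
            valid=False,
        )
    return HRVMeasure(
        window_start=float(start_s),
        window_end=float(end_s),
        rmssd=rmssd(rr),
        mean_hr=float(60000.0 / np.mean(rr)),
        n_beats=n,
        valid=True,
    )


def pre_trigger_rmssd(
    stream: TimestampedRR, trigger_t: float, span_s: float = PRE_TRIGGER_SPAN_S
) -> HRVMeasure:
    """Ultra-short-term HRV in the ``span_s`` seconds before a trigger.

    Defined as ``window_rmssd(stream, trigger_t - span_s, trigger_t)``.  A
    trigger earlier than ``span_s`` after stream start yields an invalid
    measure and a logged warning.
    """
    if trigger_t - span_s < 0:
        logger.warning(
            "trigger at t=%.3f s is within the first %.0f s; pre-trigger window invalid",
            trigger_t,
            span_s,
        )
        return HRVMeasure(
            window_start=trigger_t - span_s,
            window_end=float(trigger_t),
            rmssd=math.nan,
            mean_hr=math.nan,
            n_beats=0,
            valid=False,
        )
    return window_rmssd(stream, trigger_t - span_s, trigger_t)
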