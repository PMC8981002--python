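"""Containers and CSV I/O for accelerometer traces and timestamped event logs.

Acceleration is expressed in g (1 g = 9.8 m/s^2) with gravity *included* in
the signal, so a stationary watch reads a vector magnitude of about 1 g.
Times are seconds from session start; a trace is uniformly sampled and its
timestamps are implied by ``t0 + k / rate``.

On-disk formats are plain CSV:

* trace files:     header ``t,ax,ay,az`` — time in seconds, axes in g;
* event logs:      header ``kind,direction,t_start,t_end``;
* detection logs:  header ``kind,t_impact,freefall_min_g,impact_peak_g,rest_fraction``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sampling rate (Hz) the detector operates at; traces recorded at other
#: rates are linearly resampled to this before detection.
WORKING_RATE_HZ = 100.0

#: Tolerance (s) for deciding that trace timestamps are uniformly spaced.
UNIFORM_SPACING_TOL_S = 1e-6

EVENT_KINDS = ("fall", "near_fall", "nonfall_segment")
DIRECTIONS = ("forward", "backward", "left", "right", "none")

FALL = "fall"
NEAR_FALL = "near_fall"
NONFALL_SEGMENT = "nonfall_segment"


class TraceParseError(ValueError):
    """A trace CSV violated the format contract (names the offending line)."""


class EventParseError(ValueError):
    """An event-log CSV contained an unknown token or an invalid interval."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled tri-axial acceleration series.

    Parameters
    ----------
    rate
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample, seconds from session start.
    samples
        Array of shape (n, 3): per-sample (ax, ay, az) in g, gravity included.
    """

    rate: float
    t0: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace samples must be finite")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Implied timestamps ``t0 + k / rate`` (strictly increasing)."""
        return self.t0 + np.arange(len(self)) / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (len(self) - 1) / self.rate


@dataclass(frozen=True, order=True)
class ReferenceEvent:
    """Ground-truth event from the reference log (video-adjudicated in the
    field; emitted by the simulator here).

    ``direction`` is ``"none"`` exactly for ``nonfall_segment`` entries;
    falls and near falls carry the direction of the induced push.
    """

    t_start: float
    t_end: float
    kind: str = "fall"
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise EventParseError(f"unknown event kind {self.kind!r}")
        if self.direction not in DIRECTIONS:
            raise EventParseError(f"unknown direction {self.direction!r}")
        if not (np.isfinite(self.t_start) and np.isfinite(self.t_end)):
            raise EventParseError("event times must be finite")
        if self.t_end < self.t_start:
            raise EventParseError(
                f"t_end {self.t_end} precedes t_start {self.t_start}")
        if (self.direction == "none") != (self.kind == NONFALL_SEGMENT):
            raise EventParseError(
                "direction must be 'none' iff kind is 'nonfall_segment' "
                f"(got kind={self.kind!r}, direction={self.direction!r})")


@dataclass(frozen=True)
class PhaseStats:
    """Per-candidate measurements for the three detection phases."""

    freefall_min_g: float   #: minimum magnitude inside the phase-1 window
    impact_peak_g: float    #: peak magnitude inside the phase-2 window
    rest_fraction: float    #: fraction of phase-3 samples inside the rest band

    def __post_init__(self) -> None:
        for name in ("freefall_min_g", "impact_peak_g", "rest_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class DetectionEvent:
    """Detector-emitted event: a fall or near fall with its phase statistics.

    ``t_impact`` is the onset of phase 2 (the first sample after the
    free-fall window), seconds from session start.
    """

    kind: str
    t_impact: float
    phase_stats: PhaseStats

    def __post_init__(self) -> None:
        if self.kind not in (FALL, NEAR_FALL):
            raise ValueError(f"detection kind must be fall/near_fall, got {self.kind!r}")
        if not np.isfinite(self.t_impact):
            raise ValueError("t_impact must be finite")


# ---------------------------------------------------------------------------
# signal reductions
# ---------------------------------------------------------------------------

def magnitude(trace: AccelTrace) -> np.ndarray:
    """Per-sample Euclidean norm of (ax, ay, az) in g.

    The three thresholds of the detector are applied to this scalar series;
    it is invariant under axis permutations and sign flips.
    """
    return np.linalg.norm(trace.samples, axis=1)


def resample(trace: AccelTrace, rate: float = WORKING_RATE_HZ) -> AccelTrace:
    """Linearly resample a trace to ``rate`` Hz (no-op if already there)."""
    if abs(trace.rate - rate) < 1e-9:
        return trace
    old_t = trace.times
    new_n = max(1, int(np.floor(trace.duration * rate)) + 1)
    new_t = trace.t0 + np.arange(new_n) / rate
    cols = [np.interp(new_t, old_t, trace.samples[:, k]) for k in range(3)]
    return AccelTrace(rate=rate, t0=trace.t0, samples=np.column_stack(cols))


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ["t", "ax", "ay", "az"]


def read_trace(path) -> AccelTrace:
    """Read a ``t,ax,ay,az`` CSV; the rate is inferred from the median
    timestamp spacing.

    Raises
    ------
    TraceParseError
        On a malformed row, non-monotone time, or non-uniform spacing,
        naming the first offending line (1-based, header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceParseError(f"{path}: unreadable CSV ({exc})") from exc
    if list(df.columns) != _TRACE_COLUMNS:
        raise TraceParseError(
            f"{path}: line 1: expected header 't,ax,ay,az', got "
            f"{','.join(map(str, df.columns))!r}")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no samples")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(num.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise TraceParseError(f"{path}: line {line}: malformed row {df.iloc[line - 2].tolist()}")
    t = num["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        nonmono = dt <= 0
        if nonmono.any():
            line = int(np.flatnonzero(nonmono)[0]) + 3
            raise TraceParseError(f"{path}: line {line}: non-monotone timestamp")
        spacing = float(np.median(dt))
        off = np.abs(dt - spacing) > UNIFORM_SPACING_TOL_S
        if off.any():
            line = int(np.flatnonzero(off)[0]) + 3
            raise TraceParseError(
                f"{path}: line {line}: non-uniform spacing "
                f"(expected {spacing:.6g} s)")
        rate = 1.0 / spacing
    else:
        rate = WORKING_RATE_HZ
    samples = num[["ax", "ay", "az"]].to_numpy(dtype=float)
    return AccelTrace(rate=rate, t0=float(t[0]), samples=samples)


def write_trace(trace: AccelTrace, path) -> None:
    """Write a trace so that ``read_trace`` round-trips it losslessly to
    better than 1e-9 g."""
    df = pd.DataFrame(
        np.column_stack([trace.times, trace.samples]), columns=_TRACE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# event-log CSV
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["kind", "direction", "t_start", "t_end"]


def read_events(path) -> list[ReferenceEvent]:
    """Read a reference-event log; rows need not be sorted on disk but the
    returned list is sorted by ``t_start``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"kind": str, "direction": str})
    if list(df.columns) != _EVENT_COLUMNS:
        raise EventParseError(
            f"{path}: expected header 'kind,direction,t_start,t_end', got "
            f"{','.join(map(str, df.columns))!r}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(ReferenceEvent(
                kind=str(row.kind), direction=str(row.direction),
                t_start=float(row.t_start), t_end=float(row.t_end)))
        except (EventParseError, ValueError) as exc:
            raise EventParseError(f"{path}: line {i + 2}: {exc}") from exc
    return sorted(events, key=lambda e: (e.t_start, e.t_end))


def write_events(events: Iterable[ReferenceEvent], path) -> None:
    """Write a reference-event log (lossless round-trip with read_events)."""
    rows = [(e.kind, e.direction, e.t_start, e.t_end) for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# detection-log CSV
# ---------------------------------------------------------------------------

_DETECTION_COLUMNS = [
    "kind", "t_impact", "freefall_min_g", "impact_peak_g", "rest_fraction"]


def read_detections(path) -> list[DetectionEvent]:
    """Read a detector output log, sorted by ``t_impact``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"kind": str})
    if list(df.columns) != _DETECTION_COLUMNS:
        raise EventParseError(
            f"{path}: expected header {','.join(_DETECTION_COLUMNS)!r}, got "
            f"{','.join(map(str, df.columns))!r}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(DetectionEvent(
                kind=str(row.kind), t_impact=float(row.t_impact),
                phase_stats=PhaseStats(float(row.freefall_min_g),
                                       float(row.impact_peak_g),
                                       float(row.rest_fraction))))
        except ValueError as exc:
            raise EventParseError(f"{path}: line {i + 2}: {exc}") from exc
    return sorted(out, key=lambda d: d.t_impact)


def write_detections(detections: Iterable[DetectionEvent], path) -> None:
    rows = [(d.kind, d.t_impact, d.phase_stats.freefall_min_g,
             d.phase_stats.impact_peak_g, d.phase_stats.rest_fraction)
            for d in detections]
    pd.DataFrame(rows, columns=_DETECTION_COLUMNS).to_csv(
        path, index=False, float_format="%.12g")
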