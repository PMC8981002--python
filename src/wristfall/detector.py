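"""Three-phase threshold fall detector and per-subject calibration.

The detector scans the scalar acceleration magnitude (g, gravity included)
of a wrist trace for the canonical fall signature:

* **phase 1 (free fall)** — the watch moves toward the ground and the
  magnitude drops well below the 1 g resting level for a short dwell;
* **phase 2 (impact)** — the watch hits the ground, producing a brief,
  very high positive acceleration peak;
* **phase 3 (rest)** — the watch lies almost immobile, the magnitude
  staying inside a narrow band around 1 g for a sustained interval.

A candidate that satisfies all three phase predicates at the full
thresholds is a *fall*.  A candidate whose statistics all clear the
thresholds relaxed by the near-fall margin (20% by default, each threshold
moved in its permissive direction) while at least one full-threshold
predicate fails is a *near fall* — the signature of a stumble caught by
recovery steps.  Anything else is ignored.

Numeric threshold defaults are conventional values for wrist-worn
threshold detectors; deployed devices tune them per watch model and wearer
(see :func:`calibrate_thresholds`), so every one is configurable.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import (
    FALL, NEAR_FALL, WORKING_RATE_HZ,
    AccelTrace, DetectionEvent, PhaseStats, ReferenceEvent,
    magnitude, resample,
)

logger = logging.getLogger(__name__)

NONE = "none"  #: classification outcome for candidates that are neither


class ConfigError(ValueError):
    """A threshold configuration violates its invariants."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and timing windows of the three-phase detector.

    Attributes
    ----------
    gravity_ref
        The 1 g reference level (g).
    freefall_max
        Phase-1 ceiling: the magnitude must dip below this (g).
    t1_min, t1_max
        Minimum required / maximum allowed free-fall dwell (s).
    impact_min
        Phase-2 floor: the peak must exceed this (g).
    t2_max
        How long after phase-1 end the impact peak may occur (s).
    rest_tol
        Half-width of the "almost immobile" band around ``gravity_ref`` (g).
    t3_min
        Duration of the post-impact rest window (s).
    rest_frac_min
        Fraction of phase-3 samples required inside the rest band.
    near_margin
        Fractional relaxation defining "close to" a threshold (0.20 = 20%).
    refractory
        Seconds during which no further event may be emitted after one.
    """

    gravity_ref: float = 1.0
    freefall_max: float = 0.6
    t1_min: float = 0.15
    t1_max: float = 0.5
    impact_min: float = 2.5
    t2_max: float = 0.2
    rest_tol: float = 0.25
    t3_min: float = 2.0
    rest_frac_min: float = 0.9
    near_margin: float = 0.20
    refractory: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.freefall_max < self.gravity_ref < self.impact_min):
            raise ConfigError(
                "need 0 < freefall_max < gravity_ref < impact_min, got "
                f"{self.freefall_max}, {self.gravity_ref}, {self.impact_min}")
        for name in ("t1_min", "t1_max", "t2_max", "t3_min", "rest_tol",
                     "refractory"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.t1_max < self.t1_min:
            raise ConfigError("t1_max must be >= t1_min")
        if not 0 < self.near_margin < 1:
            raise ConfigError("near_margin must be in (0, 1)")
        if not 0 < self.rest_frac_min <= 1:
            raise ConfigError("rest_frac_min must be in (0, 1]")

    # margin-relaxed levels (permissive direction of each predicate)
    @property
    def freefall_relaxed(self) -> float:
        """Phase-1 ceiling relaxed by the margin; also the candidate-opening
        level: the loosest dip that could still yield a near fall."""
        return self.freefall_max / (1.0 - self.near_margin)

    @property
    def impact_relaxed(self) -> float:
        return self.impact_min * (1.0 - self.near_margin)

    @property
    def rest_frac_relaxed(self) -> float:
        return self.rest_frac_min * (1.0 - self.near_margin)

    # flat key=value (de)serialization -------------------------------------
    def save(self, path) -> None:
        Path(path).write_text(
            "".join(f"{k}={v!r}\n" for k, v in asdict(self).items()))

    @classmethod
    def load(cls, path) -> "ThresholdConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = ThresholdConfig()


@dataclass(frozen=True)
class SubjectProfile:
    """Wearer morphology and watch placement (drives calibration and the
    ipsilateral/contralateral simulation effect)."""

    height_cm: float
    weight_kg: float
    watch_side: str = "left"

    def __post_init__(self) -> None:
        if not 100 <= self.height_cm <= 230:
            raise ValueError(f"height_cm out of range: {self.height_cm}")
        if not 30 <= self.weight_kg <= 200:
            raise ValueError(f"weight_kg out of range: {self.weight_kg}")
        if self.watch_side not in ("left", "right"):
            raise ValueError(f"watch_side must be left/right, got {self.watch_side!r}")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_candidate(stats: PhaseStats, config: ThresholdConfig = DEFAULT_CONFIG) -> str:
    """Classify one candidate's phase statistics as fall / near_fall / none.

    Fall: all three predicates pass at full thresholds (boundary equality
    counts as a pass).  Near fall: all three pass at the margin-relaxed
    thresholds while at least one fails at full strength — which is
    automatic in the fallthrough.  Otherwise none.
    """
    eps = 1e-9  # inclusive boundaries, robust to threshold-arithmetic round-off
    full = (stats.freefall_min_g <= config.freefall_max + eps
            and stats.impact_peak_g >= config.impact_min - eps
            and stats.rest_fraction >= config.rest_frac_min - eps)
    if full:
        return FALL
    relaxed = (stats.freefall_min_g <= config.freefall_relaxed + eps
               and stats.impact_peak_g >= config.impact_relaxed - eps
               and stats.rest_fraction >= config.rest_frac_relaxed - eps)
    return NEAR_FALL if relaxed else NONE


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _window_samples(config: ThresholdConfig, rate: float):
    """Phase windows in integer samples at the working rate."""
    l1_min = max(1, int(math.ceil(config.t1_min * rate - 1e-9)))
    l1_max = max(l1_min, int(round(config.t1_max * rate)))
    l2 = max(1, int(round(config.t2_max * rate)))
    l3 = max(1, int(round(config.t3_min * rate)))
    return l1_min, l1_max, l2, l3


def detect_events(trace: AccelTrace,
                  config: ThresholdConfig = DEFAULT_CONFIG) -> list[DetectionEvent]:
    """Scan a trace and emit fall / near-fall events in time order.

    Every sample whose magnitude lies below the candidate-opening level
    (``config.freefall_relaxed``) is considered as a potential phase-1
    start.  For each, the phase-1 window is the contiguous sub-level run
    capped at ``t1_max``; if its dwell reaches ``t1_min``, the phase-2 peak
    is sought within ``t2_max`` after the window and the phase-3 rest
    fraction measured over ``t3_min`` after the peak.  Candidates whose
    phase-3 window would run past the end of the trace are void, so a trace
    shorter than ``t1_min + t2_max + t3_min`` yields an empty list.

    Classified candidates are emitted greedily in time order subject to the
    refractory constraint: no two emitted events are closer than
    ``config.refractory`` seconds (measured at ``t_impact``).
    """
    if not isinstance(config, ThresholdConfig):
        raise ConfigError(f"not a ThresholdConfig: {config!r}")
    trace = resample(trace, WORKING_RATE_HZ)
    rate = trace.rate
    mag = magnitude(trace)
    n = len(mag)
    l1_min, l1_max, l2, l3 = _window_samples(config, rate)

    below = mag < config.freefall_relaxed
    starts = np.flatnonzero(below)
    if starts.size == 0:
        return []
    above = np.flatnonzero(~below)
    # first index >= start with magnitude back above the opening level
    if above.size:
        pos = np.searchsorted(above, starts)
        run_end = np.where(pos < above.size,
                           above[np.minimum(pos, above.size - 1)], n)
    else:
        run_end = np.full(starts.shape, n)
    j = np.minimum(run_end, starts + l1_max)
    dwell_ok = (j - starts) >= l1_min

    in_band = np.abs(mag - config.gravity_ref) <= config.rest_tol

    events: list[DetectionEvent] = []
    last_impact = -math.inf
    debug = logger.isEnabledFor(logging.DEBUG)
    for s, je in zip(starts[dwell_ok], j[dwell_ok]):
        s, je = int(s), int(je)
        k2_end = min(n, je + l2 + 1)
        if k2_end <= je:
            continue
        pk = je + int(np.argmax(mag[je:k2_end]))
        k3_start, k3_end = pk + 1, pk + 1 + l3
        if k3_end > n:
            continue  # phase-3 window truncated: candidate void
        stats = PhaseStats(
            freefall_min_g=float(np.min(mag[s:je])),
            impact_peak_g=float(mag[pk]),
            rest_fraction=float(np.mean(in_band[k3_start:k3_end])))
        kind = classify_candidate(stats, config)
        if debug:
            logger.debug(
                "candidate start=%.2fs dwell=%.2fs min=%.3fg peak=%.3fg "
                "rest=%.3f -> %s", trace.t0 + s / rate, (je - s) / rate,
                stats.freefall_min_g, stats.impact_peak_g,
                stats.rest_fraction, kind)
        if kind == NONE:
            continue
        t_impact = trace.t0 + je / rate
        if t_impact - last_impact < config.refractory:
            continue
        events.append(DetectionEvent(kind=kind, t_impact=t_impact,
                                     phase_stats=stats))
        last_impact = t_impact
    return events


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

#: Default multiplicative grid for per-subject threshold optimization.
CALIBRATION_GRID = (0.7, 0.85, 1.0, 1.15, 1.3)


def _falls_detected(config: ThresholdConfig,
                    calibration: Sequence[tuple[AccelTrace, ReferenceEvent]],
                    tolerance_s: float) -> int:
    hits = 0
    for trace, event in calibration:
        for det in detect_events(trace, config):
            if det.kind == FALL and (
                    event.t_start - tolerance_s <= det.t_impact
                    <= event.t_end + tolerance_s):
                hits += 1
                break
    return hits


def calibrate_thresholds(
        calibration: Sequence[tuple[AccelTrace, ReferenceEvent]],
        base: ThresholdConfig = DEFAULT_CONFIG,
        walking: AccelTrace | None = None,
        grid: Iterable[float] = CALIBRATION_GRID,
        tolerance_s: float = 10.0) -> ThresholdConfig:
    """Per-subject threshold optimization over labeled test falls.

    Grid search over multiplicative scalings of ``freefall_max``,
    ``impact_min`` and ``rest_tol``.  The returned config maximizes the
    number of calibration falls detected; ties are broken by fewest false
    alarms on the optional walking trace, then by proximity to ``base``
    (sum of squared scale deviations from 1), then lexicographically for
    determinism.  The identity scaling is always on the grid, so the
    detected count under the result is never below that under ``base``.

    An empty calibration set returns ``base`` unchanged with a warning.
    """
    if not calibration:
        warnings.warn("empty calibration set: returning base thresholds",
                      stacklevel=2)
        return base
    grid = tuple(grid)
    if 1.0 not in grid:
        grid = grid + (1.0,)

    best = None
    for sf, si, sr in itertools.product(sorted(grid), repeat=3):
        try:
            cand = base.replace(freefall_max=base.freefall_max * sf,
                                impact_min=base.impact_min * si,
                                rest_tol=base.rest_tol * sr)
        except ConfigError:
            continue
        hits = _falls_detected(cand, calibration, tolerance_s)
        false_alarms = 0
        if walking is not None:
            false_alarms = sum(
                1 for d in detect_events(walking, cand) if d.kind == FALL)
        dist = (sf - 1) ** 2 + (si - 1) ** 2 + (sr - 1) ** 2
        key = (-hits, false_alarms, dist, sf, si, sr)
        if best is None or key < best[0]:
            best = (key, cand)
    assert best is not None  # identity scaling always valid
    logger.info("calibration: %d/%d falls detected under selected thresholds",
                -best[0][0], len(calibration))
    return best[1]
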