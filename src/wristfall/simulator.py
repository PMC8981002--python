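"""Seeded generator of synthetic wrist-accelerometer sessions.

Emulates an induced-fall laboratory protocol: per participant, two rounds
of four directed falls (forward, right, left, backward — pushed while
standing), optional near falls in which the participant recovers with a
few steps, and free walking between events.  The generator produces a
single continuous trace per session plus the matching ground-truth event
log, so the detector can be evaluated blind against it.

Signatures are built as scalar magnitude profiles (flat free-fall dip,
half-sine impact spike, noisy 1 g rest plateau) projected onto a
direction-dependent unit axis vector, so the vector magnitude equals the
constructed profile exactly.  Side falls on the wrist opposite the watch
are attenuated (``contralateral_atten``), which is what makes ipsilateral
side falls easier to detect than contralateral ones — the directional
effect reported for wrist-worn detectors.

Shapes are deliberately stylized: the aim is a signal whose *phase
statistics* behave like the real protocol's, not biomechanical realism.
"""
from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .detector import SubjectProfile
from .io import (
    FALL, NEAR_FALL, NONFALL_SEGMENT,
    AccelTrace, ReferenceEvent,
)

#: Direction order of each induced-fall round.
ROUND_DIRECTIONS = ("forward", "right", "left", "backward")

#: Unit vectors the scalar magnitude profile is projected onto.
_DIRECTION_AXES = {
    "none":     (0.0, 0.0, 1.0),
    "forward":  (0.0, 0.70710678, 0.70710678),
    "backward": (0.0, -0.70710678, 0.70710678),
    "left":     (-0.70710678, 0.0, 0.70710678),
    "right":    (0.70710678, 0.0, 0.70710678),
}

# pre/post padding rendered around each signature so an isolated segment
# still contains a complete phase-3 window
_PRE_PAD_S = 0.5
_POST_PAD_S = 0.6


@dataclass(frozen=True)
class SimParams:
    """Signal-shape parameters of the generator (amplitudes in g, durations
    in seconds).

    ``contralateral_atten`` multiplies both the free-fall excursion and the
    impact peak when a side fall occurs opposite the watch wrist.
    ``near_fall_scale`` maps a fall signature to a sub-threshold near-fall
    signature (dip level and peak multiplied directly).  ``device_scale``
    is a per-device amplitude multiplier standing in for watch-model and
    operating-system sampling differences.
    """

    rate: float = 100.0
    freefall_depth: float = 0.3
    freefall_dur: float = 0.3
    impact_peak: float = 3.2
    impact_dur: float = 0.05
    rest_dur: float = 3.0
    rest_noise_sd: float = 0.02
    walk_amp: float = 0.3
    walk_freq: float = 2.0
    walk_noise_sd: float = 0.05
    contralateral_atten: float = 0.75
    near_fall_scale: float = 0.85
    device_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.contralateral_atten <= 1:
            raise ValueError("contralateral_atten must be in (0, 1]")
        if not 0 < self.near_fall_scale <= 1:
            raise ValueError("near_fall_scale must be in (0, 1]")
        for name in ("rate", "freefall_depth", "freefall_dur", "impact_peak",
                     "impact_dur", "rest_dur", "walk_amp", "walk_freq",
                     "device_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rest_noise_sd", "walk_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_PARAMS = SimParams()


@dataclass(frozen=True)
class ProtocolSpec:
    """Session structure: rounds of four directed falls with free walking
    in between, plus optional near falls and pre-round test falls."""

    rounds: int = 2
    inter_fall_walk_s: float = 20.0
    near_falls: int = 0
    test_falls: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.inter_fall_walk_s < 0:
            raise ValueError("inter_fall_walk_s must be >= 0")
        if self.near_falls < 0 or self.test_falls < 0:
            raise ValueError("near_falls/test_falls must be >= 0")


DEFAULT_PROTOCOL = ProtocolSpec()


@dataclass(frozen=True)
class StudySubject:
    """One simulated participant: profile, session trace, reference log."""

    profile: SubjectProfile
    trace: AccelTrace
    events: tuple[ReferenceEvent, ...] = field(repr=False)


# ---------------------------------------------------------------------------
# low-level profile builders (scalar magnitude, working in g)
# ---------------------------------------------------------------------------

def _resolve_rng(params: SimParams, rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(params.seed)
    return rng


def _project(mag: np.ndarray, direction: str) -> np.ndarray:
    axis = np.asarray(_DIRECTION_AXES[direction])
    return np.clip(mag, 1e-3, None)[:, None] * axis[None, :]


def _quiet(n: int, params: SimParams, rng) -> np.ndarray:
    if n <= 0:
        return np.empty(0)
    return 1.0 + rng.normal(0.0, params.rest_noise_sd, n)


def _walk_profile(n: int, params: SimParams, rng) -> np.ndarray:
    if n <= 0:
        return np.empty(0)
    t = np.arange(n) / params.rate
    phase = rng.uniform(0, 2 * np.pi)
    osc = params.walk_amp * np.sin(2 * np.pi * params.walk_freq * t + phase)
    return 1.0 + osc + rng.normal(0.0, params.walk_noise_sd, n)


def _attenuation(profile: SubjectProfile, direction: str,
                 params: SimParams) -> float:
    """Contralateral side falls reach the watch wrist attenuated."""
    if direction in ("left", "right") and direction != profile.watch_side:
        return params.contralateral_atten
    return 1.0


def _fall_profile(profile: SubjectProfile, direction: str, params: SimParams,
                  rng, scale: float = 1.0) -> np.ndarray:
    """Scalar magnitude of a fall signature head: pre-pad + dip + impact.

    ``scale`` < 1 multiplies the dip level and impact peak directly,
    turning the head into the body of a near-fall signature.
    """
    rate = params.rate
    atten = _attenuation(profile, direction, params) * params.device_scale
    dip_jit = float(np.clip(1.0 + 0.10 * rng.standard_normal(), 0.7, 1.3))
    peak_jit = float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.85, 1.15))

    excursion = (1.0 - params.freefall_depth) * atten * dip_jit
    dip_level = max(0.02, (1.0 - excursion) * scale)
    peak = max(1.05, params.impact_peak * atten * peak_jit * scale)

    n_pre = int(round(_PRE_PAD_S * rate))
    n_dip = max(2, int(round(params.freefall_dur * rate)))
    # odd sample count so the half-sine attains its nominal peak exactly
    n_imp = max(3, int(round(params.impact_dur * rate)) + 1) | 1

    pre = _quiet(n_pre, params, rng)
    dip = dip_level + rng.normal(0.0, params.rest_noise_sd, n_dip)
    dip = np.clip(dip, 0.02, None)
    imp = 1.0 + (peak - 1.0) * np.sin(np.pi * np.linspace(0.0, 1.0, n_imp))
    return np.concatenate([pre, dip, imp])


def simulate_fall_signature(profile: SubjectProfile, direction: str,
                            params: SimParams = DEFAULT_PARAMS,
                            rng=None) -> AccelTrace:
    """One complete fall signature: padding + dip + impact + rest plateau."""
    rng = _resolve_rng(params, rng)
    head = _fall_profile(profile, direction, params, rng)
    rest = _quiet(int(round(params.rest_dur * params.rate)), params, rng)
    post = _quiet(int(round(_POST_PAD_S * params.rate)), params, rng)
    mag = np.concatenate([head, rest, post])
    return AccelTrace(rate=params.rate, t0=0.0,
                      samples=_project(mag, direction))


def simulate_near_fall_signature(profile: SubjectProfile, direction: str,
                                 params: SimParams = DEFAULT_PARAMS,
                                 rng=None) -> AccelTrace:
    """A near fall: scaled dip and impact followed by ~2 s of recovery
    steps instead of a rest plateau.

    At the default detector thresholds the scaled dip and peak still pass
    at full strength while the recovery-step oscillation holds the phase-3
    rest fraction inside the 20% margin band, so the candidate classifies
    as a near fall rather than a fall.
    """
    rng = _resolve_rng(params, rng)
    rate = params.rate
    head = _fall_profile(profile, direction, params, rng,
                         scale=params.near_fall_scale)
    # recovery steps: quiet stance with two brief step impulses
    n_rec = int(round(2.0 * rate))
    rec = _quiet(n_rec, params, rng)
    t_rec = np.arange(n_rec) / rate
    bump_amp = 2.0 * params.walk_amp * params.device_scale
    for t_bump in (0.4, 1.2):
        inside = (t_rec >= t_bump) & (t_rec < t_bump + 0.25)
        rec[inside] += bump_amp * np.sin(
            np.pi * (t_rec[inside] - t_bump) / 0.25)
    post = _quiet(int(round(_POST_PAD_S * rate)), params, rng)
    mag = np.concatenate([head, rec, post])
    return AccelTrace(rate=rate, t0=0.0, samples=_project(mag, direction))


def simulate_walk_segment(duration_s: float,
                          params: SimParams = DEFAULT_PARAMS,
                          rng=None) -> AccelTrace:
    """Free walking: 1 g baseline with a step-frequency oscillation."""
    rng = _resolve_rng(params, rng)
    n = max(1, int(round(duration_s * params.rate)))
    return AccelTrace(rate=params.rate, t0=0.0,
                      samples=_project(_walk_profile(n, params, rng), "none"))


# ---------------------------------------------------------------------------
# sessions and studies
# ---------------------------------------------------------------------------

def simulate_session(profile: SubjectProfile,
                     protocol: ProtocolSpec = DEFAULT_PROTOCOL,
                     params: SimParams = DEFAULT_PARAMS,
                     rng=None) -> tuple[AccelTrace, list[ReferenceEvent]]:
    """One participant session: walking interleaved with induced events.

    The reference log carries one ``fall`` entry per induced fall
    (``rounds`` x 4, in the fixed direction order per round), one
    ``near_fall`` entry per requested near fall, and one
    ``nonfall_segment`` entry per walking interval.  Deterministic given
    the rng state / seed.
    """
    rng = _resolve_rng(params, rng)
    rate = params.rate
    chunks: list[np.ndarray] = []
    events: list[ReferenceEvent] = []
    t = 0.0

    def add(trace: AccelTrace, kind: str | None, direction: str = "none"):
        nonlocal t
        dur = len(trace) / rate
        if kind is not None:
            events.append(ReferenceEvent(kind=kind, direction=direction,
                                         t_start=t, t_end=t + dur))
        chunks.append(trace.samples)
        t += dur

    def add_walk():
        if protocol.inter_fall_walk_s > 0:
            add(simulate_walk_segment(protocol.inter_fall_walk_s, params, rng),
                NONFALL_SEGMENT)

    add_walk()
    dir_cycle = list(ROUND_DIRECTIONS)
    for k in range(protocol.test_falls):
        d = dir_cycle[k % 4]
        add(simulate_fall_signature(profile, d, params, rng), FALL, d)
        add_walk()
    for _ in range(protocol.rounds):
        for d in ROUND_DIRECTIONS:
            add(simulate_fall_signature(profile, d, params, rng), FALL, d)
            add_walk()
    for _ in range(protocol.near_falls):
        d = str(rng.choice(ROUND_DIRECTIONS))
        add(simulate_near_fall_signature(profile, d, params, rng), NEAR_FALL, d)
        add_walk()

    if not chunks:
        chunks.append(_project(_quiet(1, params, rng), "none"))
    trace = AccelTrace(rate=rate, t0=0.0, samples=np.concatenate(chunks))
    return trace, events


def simulate_two_watch_session(profile: SubjectProfile,
                               protocol: ProtocolSpec = DEFAULT_PROTOCOL,
                               params: SimParams = DEFAULT_PARAMS,
                               seed: int | None = None):
    """Render the same session once per wrist.

    Both renders share the seed, hence the schedule and jitter draws; the
    traces differ only through the contralateral attenuation, emulating a
    participant wearing a watch on each wrist.  Returns
    ((trace_left, trace_right), events) with the shared reference log.
    """
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    left = SubjectProfile(profile.height_cm, profile.weight_kg, "left")
    right = SubjectProfile(profile.height_cm, profile.weight_kg, "right")
    trace_l, events = simulate_session(
        left, protocol, params, np.random.default_rng(seed))
    trace_r, _ = simulate_session(
        right, protocol, params, np.random.default_rng(seed))
    return (trace_l, trace_r), events


# sampling ranges for subject morphology (cm, kg)
HEIGHT_RANGE_CM = (153.0, 184.0)
WEIGHT_RANGE_KG = (47.0, 110.0)


def simulate_study(n_subjects: int,
                   protocol: ProtocolSpec = DEFAULT_PROTOCOL,
                   params: SimParams = DEFAULT_PARAMS,
                   rng=None) -> list[StudySubject]:
    """Simulate a cohort: profiles drawn uniformly inside realistic
    morphology ranges, watch side alternating left/right, one session
    each.  Deterministic given the rng state / seed."""
    rng = _resolve_rng(params, rng)
    out: list[StudySubject] = []
    for i in range(n_subjects):
        prof = SubjectProfile(
            height_cm=float(rng.uniform(*HEIGHT_RANGE_CM)),
            weight_kg=float(rng.uniform(*WEIGHT_RANGE_KG)),
            watch_side="left" if i % 2 == 0 else "right")
        child = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
        trace, events = simulate_session(prof, protocol, params, child)
        out.append(StudySubject(profile=prof, trace=trace,
                                events=tuple(events)))
    return out
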