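# Methods

## Detection model

The detector operates on the per-sample Euclidean norm of the tri-axial
acceleration, in g with gravity included. The working sampling rate is
100 Hz (one sample every 0.01 s, the collection interval of the on-watch
app class this models); traces at other rates are linearly resampled
before detection. Orientation is deliberately discarded: thresholding the
magnitude makes the detector invariant to how the watch sits on the
wrist, which is also why the simulator only needs to control the
magnitude profile.

A candidate opens at every sample whose magnitude lies below the
*candidate-opening level* `freefall_max / (1 − near_margin)` (0.75 g at
defaults) — the loosest dip that could still yield a near fall. Its
phase-1 window is the contiguous sub-level run capped at `t1_max`; the
candidate proceeds only if the dwell reaches `t1_min`. The phase-2 peak
is the maximum within `t2_max` after the window; the phase-3 rest
fraction is the share of samples within `gravity_ref ± rest_tol` over the
`t3_min` window after the peak. A candidate whose phase-3 window would
run past the end of the trace is void, so traces shorter than
`t1_min + t2_max + t3_min` produce nothing.

Classification uses exactly three scalar statistics (phase-1 minimum,
phase-2 peak, phase-3 rest fraction):

* **fall** — all three pass at full thresholds;
* **near fall** — all three pass with each threshold relaxed by
  `near_margin` in its permissive direction (`freefall_max` divided by
  `1 − m`; `impact_min` and `rest_frac_min` multiplied by `1 − m`) while
  at least one full-strength predicate fails;
* **none** — otherwise.

The timing conditions (`t1_min ≤ dwell ≤ t1_max`, peak within `t2_max`)
are structural candidate gates, not margin-relaxed predicates: "close to
a threshold" is defined on the three amplitude/fraction statistics only.
The one-sided reading of the near-fall margin ("any single statistic
close, the others arbitrary") was rejected because ordinary walking
constantly produces dips close to the free-fall ceiling, which would
flood the log with near-fall alarms; requiring *all* phases at relaxed
strength matches the near-zero false-alarm behaviour such detectors show
in practice.

Classified candidates are emitted greedily in time order; an event
suppresses further emissions for `refractory` seconds (measured between
impact onsets). With `refractory > t3_min` (defaults: 3 s > 2 s) emitted
events cannot overlap. Because every below-level sample is tried as a
start, the scan is equivalent to a brute-force per-index search; the test
suite checks that equivalence against an independently written oracle.

### Thresholds

Only the structure of the three phases (sub-1 g dip, very high brief
peak, near-immobility) is canonical for this detector class; deployed
numeric values are proprietary and tuned per watch model and wearer.
Defaults are conventional values from the threshold-detector literature:

| parameter | default | unit | role |
|---|---|---|---|
| `freefall_max` | 0.6 | g | phase-1 ceiling |
| `t1_min`, `t1_max` | 0.15, 0.5 | s | free-fall dwell bounds |
| `impact_min` | 2.5 | g | phase-2 floor |
| `t2_max` | 0.2 | s | impact search window |
| `rest_tol` | 0.25 | g | half-width of the rest band |
| `t3_min` | 2.0 | s | rest window |
| `rest_frac_min` | 0.9 | — | rest-band occupancy |
| `near_margin` | 0.20 | — | "close to threshold" relaxation |
| `refractory` | 3.0 | s | post-event suppression |

Per-wearer personalization (body height/weight, watch model) is realized
purely behaviourally through `calibrate_thresholds`: a grid search over
multiplicative scalings ×{0.7, 0.85, 1.0, 1.15, 1.3} of `freefall_max`,
`impact_min` and `rest_tol`, maximizing detected calibration falls, with
ties broken by fewest false alarms on an optional walking trace, then by
proximity to the base configuration (sum of squared scale deviations),
then lexicographically. No closed-form morphology formula is used — none
is established.

## Synthetic protocol generator

`simulate_session` emulates a supervised induced-fall assessment: a
leading walking interval, then per round one pushed fall in each of the
four directions (forward, right, left, backward) separated by 20 s of
free walking; optionally near falls (push answered by recovery steps) and
pre-round practice falls. `simulate_study` draws participant profiles
(height 153–184 cm, weight 47–110 kg, uniform; watch side alternating)
and renders one session each. Everything is driven by a seeded
`numpy.random.Generator`; identical seeds give bit-identical traces.

Signatures are scalar magnitude profiles projected onto a fixed
direction-dependent unit vector (the detector only sees the magnitude, so
axis composition is cosmetic):

* **fall** — 0.5 s quiet pre-pad; a flat dip at
  `1 − (1 − freefall_depth) · atten · jitter` for `freefall_dur`; a
  half-sine impact spike peaking at `impact_peak · atten · jitter`
  (odd sample count so the nominal peak is attained exactly); a
  `rest_dur` plateau at 1 g with `rest_noise_sd` noise. Jitters are ~10%
  (dip) and ~5% (peak), clipped at ±3 sd.
* **near fall** — dip level and peak multiplied directly by
  `near_fall_scale` (0.85), and the rest plateau replaced by 2 s of
  recovery stepping: quiet stance with two 0.25 s step impulses of
  amplitude `2 · walk_amp`. At defaults the scaled dip (≈ 0.26 g) and
  peak (≈ 2.7 g) still pass the full thresholds while the stepping holds
  the rest fraction near 0.81 — inside the [0.72, 0.90) margin band — so
  the discriminating phase is T3 and the event robustly classifies as a
  near fall. The direct scaling convention is what makes the two
  boundary cases behave sensibly: at scale 1.0 the signature is a fall
  with recovery steps; at scale 0.5 the peak (1.6 g) misses even the
  relaxed 2.0 g threshold and nothing is detected.
* **walking** — `1 + walk_amp · sin(2π · walk_freq · t + φ)` plus noise.
  Walking dips only to ≈ 0.65 g with no subsequent impact, so candidates
  opened during walking always classify as none: simulated
  activities-of-daily-living background produces zero fall detections.

`contralateral_atten` (0.75) multiplies the dip excursion and impact peak
when a side fall occurs on the wrist opposite the watch. It is the single
mechanism behind the directional effect: ipsilateral side falls keep a
≈ 3.2 g peak (always above 2.5 g), contralateral ones drop to ≈ 2.4 g and
only jitter occasionally carries them over the fall threshold (most
register as near falls instead). The value was chosen so the effect is
present but the pooled sensitivity stays in the realistic 0.7–0.95 range
of wrist-worn threshold detectors; it is a tunable model parameter, not a
measured quantity. `device_scale` similarly scales amplitudes per watch
model; no claim is made of reproducing any specific model's sensitivity.

A two-watch variant renders the same schedule (same seed, hence same
jitter draws) once per wrist, so the two traces differ only through the
attenuation — a participant wearing a watch on each arm.

What the generator does **not** emulate: biomechanical limb dynamics,
orientation changes, sensor saturation and dropout, soft falls without a
free-fall phase, and real activities of daily living beyond sinusoidal
walking (sitting down hard, clapping, hammering — the classic
false-positive generators). Passing the end-to-end tests therefore shows
the pipeline is correct and the directional mechanism behaves as
designed; it does not certify field accuracy on real wrist data.

## Evaluation

Matching is greedy, one-to-one and time-ordered: each detection of the
analysed kind takes the nearest unmatched reference event of that kind
within ±10 s (distance to the event's interval). Ten seconds is far below
the ≥ 20 s inter-fall spacing of the protocol and far above the signature
duration, so results are insensitive to the exact value. Negative
instances must be explicit: every reference entry that is not of the
analysed kind (walking segments, plus events of the other class) counts
as a true negative unless an unmatched detection lands inside it. This
makes TN — and hence specificity and accuracy — well-defined; real-world
logs must declare their negatives the same way.

Interval methods: Clopper-Pearson for sensitivity/specificity/accuracy
(beta quantiles; the suite verifies agreement with a binomial-CDF
bisection oracle to 1e-6 for all n ≤ 200); the log method for likelihood
ratios; Wald-on-logit for PPV/NPV, chosen as the least-surprising default
since no single convention dominates for predictive values. LR+ is
flagged undefined when FP = 0, LR− when TN = 0 (and either CI when a
required cell is empty) rather than returning infinities. The normal
quantile is computed exactly (`norm.ppf`), not rounded to 1.96; on large
likelihood-ratio bounds this differs from calculator output in the second
decimal.

Stratified analysis takes a caller-built mapping of stratum label →
(detections, references) — direction, watch-relative side, device — and
compares per-stratum sensitivities with uncorrected 2×2 chi-square tests
at α = 0.05, deliberately without multiplicity adjustment (matching the
study-reporting convention this mirrors). Per-stratum tables typically
have no negatives, so their specificity is flagged undefined; sensitivity
is the quantity of interest.

## Numerical choices

* Threshold comparisons are inclusive, with a 1e-9 slack absorbing the
  float round-off of margin arithmetic (0.6/0.8 ≠ 0.75 exactly in
  binary).
* Phase windows are converted to integer sample counts by rounding
  (`t1_min` by ceiling, so a 0.15 s dwell at 100 Hz needs 15 samples).
* Candidate opening uses a strict `<` against the opening level; with the
  default configuration the opening level (0.75 g) exactly touches the
  lower edge of the rest band (1 − 0.25 g), so a trace confined to the
  rest band can never open a candidate. This separation
  (`freefall_max/(1−m) ≤ gravity_ref − rest_tol` and
  `impact_min·(1−m) ≥ gravity_ref + rest_tol`) is the regime in which the
  "in-band signal ⇒ no events" guarantee holds; pathological
  configurations violating it are accepted but not covered by the
  guarantee.
* Trace CSVs are written at 12 significant digits, giving round-trips
  lossless to well under 1e-9 g; a single-row trace cannot encode its
  sampling rate and is read back at the 100 Hz working rate.
* Calibration ties are broken deterministically (proximity, then
  lexicographic scale order), so calibration is reproducible.

## Problem sizes

The default validation scale — 22 participants × 8 induced falls, ten
independent seeds for the study-level checks, interval-oracle sweeps to
n = 200 at 1e-6 — keeps the full suite around ten seconds on one CPU
while exercising every code path at the size the emulated protocol
actually uses.

## Known limitations

* Numeric thresholds are field conventions, not disclosed device values;
  absolute sensitivities from the simulator characterize the simulator,
  not any particular product.
* The near-fall margin semantics (all phases relaxed, at least one full
  failure) is one defensible reading of "close to the thresholds";
  one-sided readings would need a different false-alarm story.
* Greedy nearest-first matching is not a globally optimal assignment; at
  protocol spacings the two coincide (property-tested), but dense event
  streams could differ.
* The chi-square comparison is asymptotic and uncorrected; small strata
  with expected cells near zero raise errors instead of silently
  degrading.
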