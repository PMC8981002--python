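"""Blinded comparison of detections against a reference log, and the full
diagnostic-accuracy battery.

Detections are matched to reference events one-to-one within a time
tolerance (greedy, nearest first), yielding a 2x2 confusion table per
event class.  From the table the battery computes sensitivity,
specificity, predictive values, likelihood ratios and accuracy with
confidence intervals:

* proportions (sensitivity, specificity, accuracy): exact Clopper-Pearson
  intervals from beta-distribution quantiles;
* likelihood ratios: the log method,
  ``exp(ln LR ± z * se(ln LR))`` with
  ``se(ln LR+) = sqrt(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))``
  and the analogous form for LR−;
* PPV/NPV: Wald intervals on the logit scale (no canonical choice exists
  for these in the tabulation convention reproduced here; flagged as such).

Two tabulation-convention rates are exposed alongside the standard ones:
``fp_rate_table = FP / (TP+FP)`` (= 1 − PPV) and
``fn_rate_table = FN / (FN+TN)`` (= 1 − NPV), the margins some clinical
tables print next to the off-diagonal cells; the conventional
1 − specificity false-positive rate is ``fp_rate_conventional``.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import FALL, NEAR_FALL, DetectionEvent, ReferenceEvent


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts for one event class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_condition_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_condition_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_test_pos(self) -> int:
        return self.tp + self.fp

    @property
    def n_test_neg(self) -> int:
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of test and condition (FP <-> FN).

        Under transposition sensitivity <-> PPV and specificity <-> NPV
        while accuracy is unchanged — the arithmetic behind a transposed
        results table.
        """
        return ConfusionTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)

    def scaled(self, k: int) -> "ConfusionTable":
        return ConfusionTable(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a confidence interval; ``defined`` is False
    when a zero denominator (or zero cell in the CI formula) makes the
    quantity or its interval unavailable."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    defined: bool = True
    note: str = ""


@dataclass(frozen=True)
class DiagnosticReport:
    """Full diagnostic-accuracy battery for one confusion table.

    Proportions are stored as fractions in [0, 1]; multiply by 100 for the
    percent convention of printed tables.
    """

    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    fp_rate_table: Estimate
    fn_rate_table: Estimate
    fp_rate_conventional: Estimate
    conf_level: float
    table: ConfusionTable


# ---------------------------------------------------------------------------
# interval methods
# ---------------------------------------------------------------------------

def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles.

    The lower bound is 0 when ``x == 0`` and the upper bound is 1 when
    ``x == n``.
    """
    if not 0 < conf_level < 1:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = (1.0 - conf_level) / 2.0
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha, x + 1, n - x))
    return lo, hi


def _logit_interval(x: int, n: int, conf_level: float) -> tuple[float, float] | None:
    """Wald interval on the logit scale; None when a cell is empty."""
    if x == 0 or x == n:
        return None
    z = sps.norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    logit = np.log(x / (n - x))
    se = np.sqrt(1.0 / x + 1.0 / (n - x))
    lo, hi = logit - z * se, logit + z * se
    return float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi)))


def lr_ci_log_method(ct: ConfusionTable,
                     conf_level: float = 0.95) -> tuple[Estimate, Estimate]:
    """Log-method confidence intervals for LR+ and LR−.

    Each interval needs the four counts in its standard-error formula to
    be positive; otherwise the corresponding estimate is flagged
    undefined.  As ``conf_level`` approaches 0 the interval collapses to
    the point estimate.
    """
    if not 0 < conf_level < 1:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    z = float(sps.norm.ppf(1.0 - (1.0 - conf_level) / 2.0))
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn

    if fp > 0 and tp > 0 and ct.n_condition_pos > 0 and ct.n_condition_neg > 0:
        lr = (tp / ct.n_condition_pos) / (fp / ct.n_condition_neg)
        se = np.sqrt(1 / tp - 1 / ct.n_condition_pos
                     + 1 / fp - 1 / ct.n_condition_neg)
        pos = Estimate(value=float(lr), ci_low=float(lr * np.exp(-z * se)),
                       ci_high=float(lr * np.exp(z * se)))
    else:
        pos = Estimate(value=None, defined=False, note="no false positives"
                       if fp == 0 else "zero count in LR+ formula")

    if tn > 0 and fn > 0 and ct.n_condition_pos > 0 and ct.n_condition_neg > 0:
        lr = (fn / ct.n_condition_pos) / (tn / ct.n_condition_neg)
        se = np.sqrt(1 / fn - 1 / ct.n_condition_pos
                     + 1 / tn - 1 / ct.n_condition_neg)
        neg = Estimate(value=float(lr), ci_low=float(lr * np.exp(-z * se)),
                       ci_high=float(lr * np.exp(z * se)))
    else:
        neg = Estimate(value=None, defined=False,
                       note="zero count in LR- formula")
    return pos, neg


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------

def _proportion(x: int, n: int, conf_level: float) -> Estimate:
    if n == 0:
        return Estimate(value=None, defined=False, note="zero denominator")
    lo, hi = clopper_pearson(x, n, conf_level)
    return Estimate(value=x / n, ci_low=lo, ci_high=hi)


def _predictive_value(x: int, n: int, conf_level: float) -> Estimate:
    if n == 0:
        return Estimate(value=None, defined=False, note="zero denominator")
    ci = _logit_interval(x, n, conf_level)
    if ci is None:
        return Estimate(value=x / n, defined=True,
                        note="CI unavailable (empty cell)")
    return Estimate(value=x / n, ci_low=ci[0], ci_high=ci[1])


def diagnostic_stats(ct: ConfusionTable,
                     conf_level: float = 0.95) -> DiagnosticReport:
    """Compute the full battery for one confusion table.

    A zero denominator flags only the affected statistic as undefined;
    everything else is still returned.
    """
    if not 0 < conf_level < 1:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    sens = _proportion(ct.tp, ct.n_condition_pos, conf_level)
    spec = _proportion(ct.tn, ct.n_condition_neg, conf_level)
    acc = _proportion(ct.tp + ct.tn, ct.total, conf_level) if ct.total else \
        Estimate(value=None, defined=False, note="empty table")
    ppv = _predictive_value(ct.tp, ct.n_test_pos, conf_level)
    npv = _predictive_value(ct.tn, ct.n_test_neg, conf_level)
    lr_pos, lr_neg = lr_ci_log_method(ct, conf_level)
    # LR point estimates remain defined in some cases where the CI is not
    if not lr_neg.defined and spec.defined and spec.value and sens.defined:
        lr_neg = Estimate(value=(1 - sens.value) / spec.value, defined=True,
                          note="CI unavailable (zero cell)")

    def rate(x, n):
        if n == 0:
            return Estimate(value=None, defined=False, note="zero denominator")
        return Estimate(value=x / n)

    return DiagnosticReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        lr_pos=lr_pos, lr_neg=lr_neg,
        fp_rate_table=rate(ct.fp, ct.n_test_pos),
        fn_rate_table=rate(ct.fn, ct.n_test_neg),
        fp_rate_conventional=rate(ct.fp, ct.n_condition_neg),
        conf_level=conf_level, table=ct)


# ---------------------------------------------------------------------------
# event matching
# ---------------------------------------------------------------------------

def _interval_distance(t: float, ev: ReferenceEvent) -> float:
    if ev.t_start <= t <= ev.t_end:
        return 0.0
    return min(abs(t - ev.t_start), abs(t - ev.t_end))


def match_events(detected: Sequence[DetectionEvent],
                 reference: Sequence[ReferenceEvent],
                 kind: str = FALL,
                 tolerance_s: float = 10.0) -> ConfusionTable:
    """Greedy one-to-one matching of detections against the reference log.

    Detections of the selected ``kind`` are processed in time order; each
    is matched to the nearest unmatched reference event of that kind
    within ``tolerance_s`` (distance to the event interval).  Matched
    pairs are TP, leftover detections FP, leftover reference events of the
    kind FN.  Negative instances — reference entries that are *not* of the
    kind (nonfall segments plus events of the other class) — count as TN
    unless an unmatched detection falls inside their interval.
    """
    if kind not in (FALL, NEAR_FALL):
        raise ValueError(f"kind must be fall/near_fall, got {kind!r}")
    if not tolerance_s > 0:
        raise ValueError(f"tolerance_s must be > 0, got {tolerance_s}")
    det_times = [d.t_impact for d in detected]
    if any(b < a for a, b in zip(det_times, det_times[1:])):
        raise ValueError("detections must be sorted by t_impact")
    ref_times = [r.t_start for r in reference]
    if any(b < a for a, b in zip(ref_times, ref_times[1:])):
        raise ValueError("reference events must be sorted by t_start")

    dets = [d for d in detected if d.kind == kind]
    refs = [r for r in reference if r.kind == kind]
    negatives = [r for r in reference if r.kind != kind]

    matched = [False] * len(refs)
    false_pos: list[DetectionEvent] = []
    tp = 0
    for d in dets:
        best_i, best_dist = None, tolerance_s
        for i, r in enumerate(refs):
            if matched[i]:
                continue
            dist = _interval_distance(d.t_impact, r)
            if dist < best_dist or (best_i is None and dist <= tolerance_s):
                best_i, best_dist = i, dist
        if best_i is not None and best_dist <= tolerance_s:
            matched[best_i] = True
            tp += 1
        else:
            false_pos.append(d)

    fn = matched.count(False)
    fp = len(false_pos)
    tn = sum(
        1 for neg in negatives
        if not any(neg.t_start <= d.t_impact <= neg.t_end for d in false_pos))
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# group comparison and stratified reporting
# ---------------------------------------------------------------------------

def compare_sensitivities(ct_a: ConfusionTable,
                          ct_b: ConfusionTable) -> tuple[float, float]:
    """2x2 chi-square (no continuity correction) comparing detected vs
    missed between two groups.  Raises if any expected cell count is 0."""
    if ct_a.n_condition_pos == 0 or ct_b.n_condition_pos == 0:
        raise ValueError("both groups need condition-positive events")
    table = np.array([[ct_a.tp, ct_a.fn], [ct_b.tp, ct_b.fn]])
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class StratifiedResult:
    """Per-stratum confusion tables and reports plus pairwise chi-square
    sensitivity comparisons (no multiplicity adjustment)."""

    tables: dict[str, ConfusionTable]
    reports: dict[str, DiagnosticReport]
    comparisons: dict[tuple[str, str], tuple[float, float]]
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, (_, p) in self.comparisons.items()
                if p < self.alpha]


def stratified_report(
        groups: Mapping[str, tuple[Sequence[DetectionEvent],
                                   Sequence[ReferenceEvent]]],
        kind: str = FALL,
        tolerance_s: float = 10.0,
        conf_level: float = 0.95,
        alpha: float = 0.05) -> StratifiedResult:
    """Evaluate each stratum separately and compare sensitivities pairwise.

    ``groups`` maps a stratum label to its (detections, reference events);
    the caller assigns events to strata (direction, watch-relative side,
    device, ...).  Strata with no reference events of ``kind`` are omitted
    with a warning.  Pairs whose chi-square is degenerate (an expected
    cell of zero) are skipped.
    """
    tables: dict[str, ConfusionTable] = {}
    reports: dict[str, DiagnosticReport] = {}
    for label, (dets, refs) in groups.items():
        ct = match_events(dets, refs, kind=kind, tolerance_s=tolerance_s)
        if ct.n_condition_pos == 0:
            warnings.warn(f"stratum {label!r} has no {kind} reference events;"
                          " omitted", stacklevel=2)
            continue
        tables[label] = ct
        reports[label] = diagnostic_stats(ct, conf_level)
    comparisons: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(sorted(tables), 2):
        try:
            comparisons[(a, b)] = compare_sensitivities(tables[a], tables[b])
        except ValueError:
            warnings.warn(f"chi-square degenerate for strata {a!r} vs {b!r};"
                          " skipped", stacklevel=2)
    return StratifiedResult(tables=tables, reports=reports,
                            comparisons=comparisons, alpha=alpha)


def side_strata(subjects_results) -> dict[str, tuple[list[DetectionEvent],
                                                     list[ReferenceEvent]]]:
    """Build ipsilateral/contralateral strata from per-subject results.

    ``subjects_results`` iterates (profile, detections, reference_events).
    Side-fall reference events go to the stratum given by the watch wrist;
    detections are assigned to the stratum of the nearest side-fall
    reference event within 10 s (others are dropped — they cannot be
    attributed to a side).  Forward/backward events are excluded.
    """
    out = {"ipsilateral": ([], []), "contralateral": ([], [])}
    for profile, dets, refs in subjects_results:
        side_refs = [r for r in refs if r.direction in ("left", "right")]
        for r in side_refs:
            label = ("ipsilateral" if r.direction == profile.watch_side
                     else "contralateral")
            out[label][1].append(r)
        for d in dets:
            cands = [(abs(d.t_impact - 0.5 * (r.t_start + r.t_end)), r)
                     for r in side_refs]
            if not cands:
                continue
            dist, nearest = min(cands, key=lambda c: c[0])
            if _interval_distance(d.t_impact, nearest) <= 10.0:
                label = ("ipsilateral"
                         if nearest.direction == profile.watch_side
                         else "contralateral")
                out[label][0].append(d)
    return {k: (sorted(v[0], key=lambda d: d.t_impact),
                sorted(v[1], key=lambda r: (r.t_start, r.t_end)))
            for k, v in out.items()}
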