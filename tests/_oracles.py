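"""Independent reference implementations used only to cross-check the
package: a per-sample brute-force detector, a binomial-CDF bisection for
the exact interval, and an exhaustive event-matching assignment search.

These deliberately share no code with the package internals.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom

from wristfall import AccelTrace, ThresholdConfig, magnitude, resample


def brute_force_detect(trace: AccelTrace,
                       config: ThresholdConfig) -> list[tuple[str, float]]:
    """Test every sample index as a candidate phase-1 start; emit greedily
    in time order under the refractory constraint.  Returns (kind, t_impact)
    pairs."""
    trace = resample(trace)
    rate = trace.rate
    mag = [float(v) for v in magnitude(trace)]
    n = len(mag)
    l1_min = max(1, math.ceil(config.t1_min * rate - 1e-9))
    l1_max = max(l1_min, round(config.t1_max * rate))
    l2 = max(1, round(config.t2_max * rate))
    l3 = max(1, round(config.t3_min * rate))
    open_level = config.freefall_max / (1.0 - config.near_margin)

    out: list[tuple[str, float]] = []
    last = -math.inf
    for s in range(n):
        if not mag[s] < open_level:
            continue
        j = s
        while j < n and mag[j] < open_level and j - s < l1_max:
            j += 1
        if j - s < l1_min:
            continue
        k2 = min(n, j + l2 + 1)
        if k2 <= j:
            continue
        pk = max(range(j, k2), key=lambda i: mag[i])  # first max, like argmax
        if pk + 1 + l3 > n:
            continue
        p1_min = min(mag[s:j])
        peak = mag[pk]
        rest = sum(1 for v in mag[pk + 1:pk + 1 + l3]
                   if abs(v - config.gravity_ref) <= config.rest_tol) / l3

        m = config.near_margin
        eps = 1e-9  # boundaries inclusive up to round-off, per the contract
        if (p1_min <= config.freefall_max + eps
                and peak >= config.impact_min - eps
                and rest >= config.rest_frac_min - eps):
            kind = "fall"
        elif (p1_min <= config.freefall_max / (1 - m) + eps
              and peak >= config.impact_min * (1 - m) - eps
              and rest >= config.rest_frac_min * (1 - m) - eps):
            kind = "near_fall"
        else:
            continue
        t_impact = trace.t0 + j / rate
        if t_impact - last < config.refractory:
            continue
        out.append((kind, t_impact))
        last = t_impact
    return out


def cp_bisect(x: int, n: int, conf_level: float = 0.95,
              tol: float = 1e-9) -> tuple[float, float]:
    """Exact binomial interval by bisection on the binomial CDF."""
    alpha = (1.0 - conf_level) / 2.0

    def solve(f, lo, hi):
        # f is monotone increasing with a sign change on [lo, hi]
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lower = 0.0 if x == 0 else solve(
        lambda p: binom.sf(x - 1, n, p) - alpha, 0.0, 1.0)
    upper = 1.0 if x == n else solve(
        lambda p: alpha - binom.cdf(x, n, p), 0.0, 1.0)
    return lower, upper


def cp_bisect_all(n: int, conf_level: float = 0.95,
                  iters: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bisection for every x in 0..n at once."""
    alpha = (1.0 - conf_level) / 2.0
    x = np.arange(n + 1)

    lo, hi = np.zeros(n + 1), np.ones(n + 1)
    for _ in range(iters):  # lower bound: P(X >= x | p) increasing in p
        mid = 0.5 * (lo + hi)
        too_low = binom.sf(x - 1, n, mid) < alpha
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    lower = np.where(x == 0, 0.0, 0.5 * (lo + hi))

    lo, hi = np.zeros(n + 1), np.ones(n + 1)
    for _ in range(iters):  # upper bound: P(X <= x | p) decreasing in p
        mid = 0.5 * (lo + hi)
        too_low = binom.cdf(x, n, mid) > alpha
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    upper = np.where(x == n, 1.0, 0.5 * (lo + hi))
    return lower, upper


def best_assignment_tp(det_times, ref_intervals, tolerance):
    """Maximum number of one-to-one detection/reference pairings within the
    tolerance, by exhaustive recursion (small instances only)."""

    def dist(t, iv):
        a, b = iv
        return 0.0 if a <= t <= b else min(abs(t - a), abs(t - b))

    def rec(i, used):
        if i == len(det_times):
            return 0
        best = rec(i + 1, used)  # detection i unmatched
        for j, iv in enumerate(ref_intervals):
            if j not in used and dist(det_times[i], iv) <= tolerance:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
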