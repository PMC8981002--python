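"""Event matching, the diagnostic battery, and its interval methods."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wristfall as wf
from _oracles import best_assignment_tp, cp_bisect

FALL_CT = wf.ConfusionTable(tp=174, fp=3, fn=52, tn=265)


def _det(t, kind="fall"):
    return wf.DetectionEvent(kind=kind, t_impact=t,
                             phase_stats=wf.PhaseStats(0.3, 3.0, 0.95))


def _ref(t0, t1, kind="fall", direction="forward"):
    if kind == "nonfall_segment":
        direction = "none"
    return wf.ReferenceEvent(kind=kind, direction=direction,
                             t_start=t0, t_end=t1)


# ---------------------------------------------------------------------------
# match_events
# ---------------------------------------------------------------------------

def test_match_absent_detector_counts_all_misses():
    refs = [_ref(10 * k, 10 * k + 1) for k in range(8)]
    refs += [_ref(100.0, 120.0, "nonfall_segment"), _ref(130.0, 150.0, "nonfall_segment")]
    ct = wf.match_events([], sorted(refs, key=lambda r: r.t_start))
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 0, 8, 2)


def test_match_within_tolerance_is_tp():
    ct = wf.match_events([_det(14.0)], [_ref(10.0, 10.5)], tolerance_s=10.0)
    assert (ct.tp, ct.fn, ct.fp) == (1, 0, 0)


def test_match_outside_tolerance_is_fp():
    refs = [_ref(100.0, 100.5), _ref(200.0, 200.5)]
    ct = wf.match_events([_det(60.0)], refs, tolerance_s=10.0)
    assert (ct.fp, ct.fn, ct.tp) == (1, 2, 0)


def test_fp_inside_nonfall_segment_spoils_tn():
    refs = [_ref(0.0, 50.0, "nonfall_segment"), _ref(60.0, 61.0)]
    ct = wf.match_events([_det(25.0)], refs, tolerance_s=5.0)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (0, 1, 1, 0)


def test_match_rejects_bad_inputs():
    with pytest.raises(ValueError, match="sorted"):
        wf.match_events([_det(5.0), _det(1.0)], [])
    with pytest.raises(ValueError, match="sorted"):
        wf.match_events([], [_ref(9.0, 9.5), _ref(1.0, 1.5)])
    with pytest.raises(ValueError, match="tolerance"):
        wf.match_events([], [], tolerance_s=0.0)


@given(seed=st.integers(0, 2**16), n_det=st.integers(0, 5),
       n_ref=st.integers(0, 5))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_match_conservation_and_assignment_optimality(seed, n_det, n_ref):
    """tp + fn equals the reference count; greedy nearest-first matching on
    well-separated protocol-like events equals the optimal assignment."""
    rng = np.random.default_rng(seed)
    # events spaced >> tolerance, like falls in the protocol
    starts = np.cumsum(rng.uniform(25, 60, n_ref))
    refs = [_ref(s, s + 1.0) for s in starts]
    span = float(starts[-1]) + 30 if n_ref else 60.0
    det_times = sorted(rng.uniform(0, span) for _ in range(n_det))
    ct = wf.match_events([_det(t) for t in det_times], refs, tolerance_s=10.0)
    assert ct.tp + ct.fn == n_ref
    assert ct.tp + ct.fp == n_det
    assert ct.tp == best_assignment_tp(
        det_times, [(r.t_start, r.t_end) for r in refs], 10.0)


def test_near_fall_analysis_counts_falls_as_negatives():
    refs = sorted([_ref(10.0, 11.0, "fall"),
                   _ref(40.0, 42.0, "near_fall", "left"),
                   _ref(60.0, 80.0, "nonfall_segment")],
                  key=lambda r: r.t_start)
    dets = [_det(41.0, "near_fall")]
    ct = wf.match_events(dets, refs, kind="near_fall", tolerance_s=10.0)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 0, 0, 2)


# ---------------------------------------------------------------------------
# clopper_pearson
# ---------------------------------------------------------------------------

def test_clopper_pearson_boundaries():
    lo, hi = wf.clopper_pearson(0, 50)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = wf.clopper_pearson(343, 343)
    assert hi == 1.0
    assert lo == pytest.approx(0.9893, abs=5e-5)


def test_clopper_pearson_against_bisection_spot_checks():
    for x, n in [(174, 226), (1, 10), (37, 40), (200, 400)]:
        lo, hi = wf.clopper_pearson(x, n)
        blo, bhi = cp_bisect(x, n)
        assert lo == pytest.approx(blo, abs=1e-6)
        assert hi == pytest.approx(bhi, abs=1e-6)


def test_clopper_pearson_against_statsmodels():
    from statsmodels.stats.proportion import proportion_confint
    for x, n in [(174, 226), (265, 268), (0, 20), (20, 20), (5, 9)]:
        assert wf.clopper_pearson(x, n) == pytest.approx(
            proportion_confint(x, n, alpha=0.05, method="beta"), abs=1e-10)


def test_clopper_pearson_domain_errors():
    with pytest.raises(ValueError):
        wf.clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        wf.clopper_pearson(-1, 4)
    with pytest.raises(ValueError):
        wf.clopper_pearson(1, 4, conf_level=1.0)


# ---------------------------------------------------------------------------
# diagnostic battery
# ---------------------------------------------------------------------------

def test_battery_on_fall_counts():
    rep = wf.diagnostic_stats(FALL_CT)
    assert rep.sensitivity.value == pytest.approx(174 / 226)
    assert rep.specificity.value == pytest.approx(265 / 268)
    assert rep.ppv.value == pytest.approx(174 / 177)
    assert rep.npv.value == pytest.approx(265 / 317)
    assert rep.accuracy.value == pytest.approx(439 / 494)
    assert rep.lr_pos.value == pytest.approx(68.78, abs=0.005)
    assert rep.lr_neg.value == pytest.approx(0.23, abs=0.005)
    assert rep.fp_rate_table.value == pytest.approx(3 / 177)
    assert rep.fn_rate_table.value == pytest.approx(52 / 317)
    assert rep.fp_rate_conventional.value == pytest.approx(3 / 268)
    # every defined CI brackets its point estimate
    for est in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy, rep.lr_pos, rep.lr_neg):
        assert est.ci_low <= est.value <= est.ci_high


def test_battery_flags_undefined_lr_without_false_positives():
    rep = wf.diagnostic_stats(wf.ConfusionTable(tp=206, fp=0, fn=43, tn=343))
    assert not rep.lr_pos.defined
    assert rep.specificity.value == 1.0
    assert rep.ppv.value == 1.0
    assert rep.lr_neg.value == pytest.approx((1 - 206 / 249) / 1.0)


def test_perfect_detector_all_proportions_one():
    rep = wf.diagnostic_stats(wf.ConfusionTable(tp=7, fp=0, fn=0, tn=5))
    for est in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy):
        assert est.value == 1.0


@given(tp=st.integers(1, 80), fp=st.integers(1, 80), fn=st.integers(1, 80),
       tn=st.integers(1, 80), k=st.integers(2, 5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_point_estimates_scale_invariant_cis_narrow(tp, fp, fn, tn, k):
    small = wf.diagnostic_stats(wf.ConfusionTable(tp, fp, fn, tn))
    big = wf.diagnostic_stats(wf.ConfusionTable(tp, fp, fn, tn).scaled(k))
    for attr in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                 "lr_pos", "lr_neg"):
        a, b = getattr(small, attr), getattr(big, attr)
        assert b.value == pytest.approx(a.value)
        assert (b.ci_high - b.ci_low) <= (a.ci_high - a.ci_low) + 1e-12


def test_transposition_swaps_sensitivity_ppv_and_specificity_npv():
    rep = wf.diagnostic_stats(FALL_CT)
    rep_t = wf.diagnostic_stats(FALL_CT.transpose())
    assert rep_t.sensitivity.value == pytest.approx(rep.ppv.value)
    assert rep_t.ppv.value == pytest.approx(rep.sensitivity.value)
    assert rep_t.specificity.value == pytest.approx(rep.npv.value)
    assert rep_t.npv.value == pytest.approx(rep.specificity.value)
    assert rep_t.accuracy.value == pytest.approx(rep.accuracy.value)


def test_lr_interval_collapses_as_confidence_vanishes():
    pos, neg = wf.lr_ci_log_method(FALL_CT, conf_level=1e-9)
    assert pos.ci_low == pytest.approx(pos.value, rel=1e-6)
    assert pos.ci_high == pytest.approx(pos.value, rel=1e-6)
    assert neg.ci_low == pytest.approx(neg.value, rel=1e-6)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_chi_square_identical_groups():
    ct = wf.ConfusionTable(tp=40, fp=0, fn=10, tn=0)
    stat, p = wf.compare_sensitivities(ct, ct)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_matches_hand_computation():
    a = wf.ConfusionTable(tp=90, fp=0, fn=10, tn=0)
    b = wf.ConfusionTable(tp=50, fp=0, fn=50, tn=0)
    stat, p = wf.compare_sensitivities(a, b)
    # direct Sum (O-E)^2 / E on the 2x2 with fixed margins
    obs = np.array([[90, 10], [50, 50]])
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())
    assert p < 0.05
    # symmetric in group order
    stat_ba, p_ba = wf.compare_sensitivities(b, a)
    assert stat_ba == pytest.approx(stat) and p_ba == pytest.approx(p)


def test_chi_square_degenerate_expected_cell_errors():
    a = wf.ConfusionTable(tp=10, fp=0, fn=0, tn=0)
    with pytest.raises(ValueError):
        wf.compare_sensitivities(a, a)


# ---------------------------------------------------------------------------
# stratified reporting
# ---------------------------------------------------------------------------

def _stratum(n_ref, n_hit, offset=0.0):
    refs = [_ref(offset + 30.0 * k, offset + 30.0 * k + 1) for k in range(n_ref)]
    dets = [_det(r.t_start + 0.5) for r in refs[:n_hit]]
    return dets, refs


def test_single_stratum_equals_pooled_report():
    dets, refs = _stratum(6, 4)
    res = wf.stratified_report({"all": (dets, refs)})
    pooled = wf.match_events(dets, refs)
    assert res.tables["all"] == pooled
    assert res.comparisons == {}


def test_identical_strata_compare_as_equal():
    res = wf.stratified_report({"a": _stratum(10, 6), "b": _stratum(10, 6)})
    (stat, p) = res.comparisons[("a", "b")]
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    assert res.significant_pairs() == []


def test_empty_stratum_omitted_with_warning():
    with pytest.warns(UserWarning, match="omitted"):
        res = wf.stratified_report({"a": _stratum(5, 5), "empty": ([], [])})
    assert set(res.tables) == {"a"}


def test_simulated_side_effect_is_directional(profile):
    study = wf.simulate_study(8, rng=np.random.default_rng(12))
    results = [(s.profile, wf.detect_events(s.trace), list(s.events))
               for s in study]
    res = wf.stratified_report(wf.side_strata(results))
    ipsi = res.reports["ipsilateral"].sensitivity.value
    contra = res.reports["contralateral"].sensitivity.value
    assert ipsi >= contra
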