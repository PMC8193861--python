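"""Detection calling: forced examples, boundary behavior, oracle equivalence."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryomir.detection import (
    CATEGORIES,
    DetectionThresholds,
    call_detection,
    classify_array,
)
from embryomir.errors import ConfigurationError, IntegrityError, UsageError
from embryomir.qpcr_io import AssayMeasurement
from embryomir.simulate import SimConfig, simulate_array_screen

TH = DetectionThresholds()


def m(mid, ct, drn, sample="s"):
    return AssayMeasurement(mid, sample, ct, drn)


# ------------------------------------------------------------- naive oracle
# An independent, deliberately naive transcription of the screen's printed
# set expressions, kept free of the package's control flow.


def naive_category(ct_c, drn_c, ct_b, drn_b, th=TH):
    def det(ct, drn):
        return ct is not None and ct < th.ct_max and drn > th.drn_min

    def ct_gt(ct, lim):  # censored counts as greater than any limit
        return ct is None or ct > lim

    dc, db = det(ct_c, drn_c), det(ct_b, drn_b)
    if dc and db:
        if ct_c - ct_b < th.delta_ct_margin:
            return "both_elevated"
        if ct_c - ct_b > th.delta_ct_margin:
            return "both_lower"
        return "both_other"
    if dc and not db:
        if ct_gt(ct_b, th.ct_max) and drn_b < th.drn_trace:
            return "conditioned_exclusive_strict"
        return "conditioned_exclusive"
    if db and not dc:
        return "blank_exclusive"
    return "undetected"


# ------------------------------------------------------------- forced examples


def test_strict_exclusive_forced():
    call = call_detection(m("a", 28.0, 1.2), m("a", None, 0.05))
    assert call.category == "conditioned_exclusive_strict"
    assert call.detected_conditioned and not call.detected_blank


def test_ct_boundary_is_strict_inequality():
    # conditioned Ct exactly 35 is NOT detected ("less than 35" as printed)
    call = call_detection(m("a", 35.0, 0.9), m("a", 30.0, 0.9))
    assert not call.detected_conditioned
    assert call.category == "blank_exclusive"


def test_delta_ct_exact_tie_goes_to_both_other():
    call = call_detection(m("a", 30.0, 1.0), m("a", 25.0, 1.0))
    assert call.category == "both_other"


def test_mismatched_target_and_missing_drn_rejected():
    with pytest.raises(UsageError):
        call_detection(m("a", 20, 1.0), m("b", 20, 1.0))
    with pytest.raises(UsageError):
        call_detection(m("a", 20, None), m("a", 20, 1.0))


def test_full_grid_matches_naive_oracle():
    """All 400 (Ct, dRn) combinations per sample agree with the printed criteria."""
    cts = [20.0, 34.9, 35.0, 36.0, None]
    drns = [0.05, 0.3, 0.49, 0.6]
    for ct_c, drn_c, ct_b, drn_b in itertools.product(cts, drns, cts, drns):
        got = call_detection(m("x", ct_c, drn_c), m("x", ct_b, drn_b)).category
        assert got == naive_category(ct_c, drn_c, ct_b, drn_b), (
            ct_c, drn_c, ct_b, drn_b,
        )


# ------------------------------------------------------------- classify_array


def test_empty_inputs_all_zero():
    s = classify_array([], [])
    assert s.n_screened == 0
    assert all(v == 0 for v in s.counts.values())
    assert s.short_list == ()


def test_planted_categories_recovered_exactly():
    planted = {
        "conditioned_exclusive_strict": 50,
        "blank_exclusive": 10,
        "both_elevated": 40,
        "undetected": 541,
    }
    screen = simulate_array_screen(SimConfig(seed=4), n_targets=641,
                                   planted_counts=planted)
    s = classify_array(screen.array_conditioned, screen.array_blank)
    for cat, n in planted.items():
        assert s.counts[cat] == n
    assert s.n_screened == 641
    assert len(s.short_list) == 50


def test_partition_property_on_random_tables():
    rng_screen = simulate_array_screen(SimConfig(seed=9), n_targets=200,
                                       planted_counts={"undetected": 120,
                                                       "both_elevated": 50,
                                                       "conditioned_exclusive": 30})
    s = classify_array(rng_screen.array_conditioned, rng_screen.array_blank)
    assert sum(s.counts.values()) == s.n_screened == 200
    det_cond_cats = {"conditioned_exclusive", "conditioned_exclusive_strict",
                     "both_elevated", "both_lower", "both_other"}
    assert s.n_detected_conditioned == sum(s.counts[c] for c in det_cond_cats)
    assert set(s.short_list) <= {c.mirna_id for c in s.calls
                                 if "conditioned_exclusive" in c.category}


def test_strict_join_rejects_mismatched_targets():
    cond = [m("a", 20.0, 1.0, "c")]
    blank = [m("b", 20.0, 1.0, "b")]
    with pytest.raises(IntegrityError):
        classify_array(cond, blank, join="strict")
    # default mode treats the missing partner as censored
    s = classify_array(cond, blank)
    assert s.n_screened == 2


def test_excluded_despite_elevation_reported():
    cond = [m("a", 25.0, 1.2, "c"), m("b", 24.0, 1.2, "c")]
    blank = [m("a", 28.0, 1.2, "b"), m("b", None, 0.02, "b")]
    s = classify_array(cond, blank)
    assert s.excluded_despite_elevation == ("a",)


# ------------------------------------------------------------- properties


ct_strategy = st.one_of(st.none(), st.floats(min_value=10.0, max_value=39.9))
drn_strategy = st.floats(min_value=0.0, max_value=2.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(ct_c=ct_strategy, drn_c=drn_strategy, ct_b=ct_strategy, drn_b=drn_strategy)
def test_single_call_equals_oracle_random(ct_c, drn_c, ct_b, drn_b):
    got = call_detection(m("x", ct_c, drn_c), m("x", ct_b, drn_b)).category
    assert got == naive_category(ct_c, drn_c, ct_b, drn_b)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(ct_b=ct_strategy, drn_b=drn_strategy,
       trace_lo=st.floats(min_value=0.01, max_value=0.1),
       trace_hi=st.floats(min_value=0.1, max_value=0.49))
def test_short_list_monotone_in_trace_threshold(ct_b, drn_b, trace_lo, trace_hi):
    """Raising drn_trace can only grow the short list."""
    cond = [m("x", 25.0, 1.2, "c")]
    blank = [m("x", ct_b, drn_b, "b")]
    lo = classify_array(cond, blank, DetectionThresholds(drn_trace=min(trace_lo, trace_hi)))
    hi = classify_array(cond, blank, DetectionThresholds(drn_trace=max(trace_lo, trace_hi)))
    assert set(lo.short_list) <= set(hi.short_list)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(ct_c=ct_strategy, drn_c=drn_strategy,
       ct_max_lo=st.floats(min_value=20.0, max_value=35.0),
       ct_max_hi=st.floats(min_value=20.0, max_value=35.0))
def test_detected_set_monotone_in_ct_max(ct_c, drn_c, ct_max_lo, ct_max_hi):
    """Lowering ct_max can only shrink the detected set."""
    lo, hi = sorted([ct_max_lo, ct_max_hi])
    cond = [m("x", ct_c, drn_c, "c")]
    blank = [m("x", None, 0.0, "b")]
    s_lo = classify_array(cond, blank, DetectionThresholds(ct_max=lo))
    s_hi = classify_array(cond, blank, DetectionThresholds(ct_max=hi))
    assert s_lo.n_detected_conditioned <= s_hi.n_detected_conditioned


# ------------------------------------------------------------- literal mode


def test_literal_mode_matches_canonical_away_from_boundaries():
    screen = simulate_array_screen(SimConfig(seed=13), n_targets=300,
                                   planted_counts={"undetected": 150,
                                                   "conditioned_exclusive_strict": 50,
                                                   "conditioned_exclusive": 50,
                                                   "both_elevated": 50})
    a = classify_array(screen.array_conditioned, screen.array_blank, mode="canonical")
    b = classify_array(screen.array_conditioned, screen.array_blank, mode="literal")
    assert a.counts == b.counts


def test_literal_mode_boundary_row_falls_to_both_other():
    # blank detected; conditioned observed at exactly ct_max with drn == drn_min:
    # the printed intersection (Ct_cond > 35 AND dRn_cond < 0.5) fails literally
    call = call_detection(m("x", 35.0, 0.5), m("x", 28.0, 1.0), mode="literal")
    assert call.category == "both_other"
    call_canon = call_detection(m("x", 35.0, 0.5), m("x", 28.0, 1.0))
    assert call_canon.category == "blank_exclusive"


def test_threshold_invariants():
    with pytest.raises(ConfigurationError):
        DetectionThresholds(ct_max=45.0)
    with pytest.raises(ConfigurationError):
        DetectionThresholds(drn_trace=0.6)
    with pytest.raises(ConfigurationError):
        DetectionThresholds(delta_ct_margin=0.0)
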