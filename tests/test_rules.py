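"""Rule-engine unit and property tests.

Hand-checked example values are frozen from independent enumeration: side
sequences are worked out by hand, and the crossings bound is re-derived in
``binom_cdf`` from factorials alone (no scipy) where it matters.
"""

import math
from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spcrules import (
    ChartSpec,
    ConfigurationError,
    InvalidSeriesError,
    RULE_IDS,
    anhoej_signal,
    apply_ruleset,
    count_crossings,
    crossings_limit,
    longest_run,
    run_limit,
    useful_count,
    we_rule1,
    we_rule2,
    we_rule3,
    we_rule4,
)
from spcrules.rules import rule_signals


def binom_cdf(k, n, p=0.5):
    """Independent binomial CDF from math.comb only."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k + 1))


# --- counting primitives ----------------------------------------------------

@pytest.mark.parametrize(
    "values, centre, expected",
    [([1, 2, -1], 0, 3), ([1, 0, -1], 0, 2), ([0, 0], 0, 0)],
)
def test_useful_count_excludes_on_centre_points(values, centre, expected):
    assert useful_count(values, centre) == expected


@pytest.mark.parametrize(
    "values, centre, expected",
    [
        ([-1, -2, -0.5, 1, 2, 1, 1, -1], 0, 4),
        ([1, -1, 1, -1], 0, 1),
        ([1, 0, 1, -1], 0, 2),
        ([0.0, 0.0, 0.0], 0, 0),
    ],
)
def test_longest_run_drops_on_centre_points(values, centre, expected):
    assert longest_run(values, centre) == expected


@pytest.mark.parametrize(
    "values, centre, expected",
    [([1, -1, 1, -1], 0, 3), ([2, 1, 3], 0, 0), ([1, 0, -1], 0, 1)],
)
def test_count_crossings_ignores_on_centre_points(values, centre, expected):
    assert count_crossings(values, centre) == expected


def test_empty_or_nonfinite_series_rejected():
    for fn in (useful_count, longest_run, count_crossings):
        with pytest.raises(InvalidSeriesError):
            fn([], 0)
        with pytest.raises(InvalidSeriesError):
            fn([1.0, float("nan")], 0)


# --- critical values --------------------------------------------------------

@pytest.mark.parametrize("n, expected", [(24, 8), (16, 7), (10, 6), (1, 3)])
def test_run_limit_rounds_log2_formula(n, expected):
    assert run_limit(n) == expected


@pytest.mark.parametrize("n, expected", [(24, 8), (10, 2), (20, 6)])
def test_crossings_limit_is_lower_binomial_quantile(n, expected):
    k = crossings_limit(n)
    assert k == expected
    # independent check: smallest k with binomial(n-1, 0.5) CDF >= 0.05
    assert binom_cdf(k, n - 1) >= 0.05
    assert k == 0 or binom_cdf(k - 1, n - 1) < 0.05


def test_limit_preconditions():
    with pytest.raises(InvalidSeriesError):
        run_limit(0)
    with pytest.raises(InvalidSeriesError):
        crossings_limit(1)


def test_limits_non_decreasing_in_n():
    rl = [run_limit(n) for n in range(1, 401)]
    cl = [crossings_limit(n) for n in range(2, 401)]
    assert all(a <= b for a, b in zip(rl, rl[1:]))
    assert all(a <= b for a, b in zip(cl, cl[1:]))


# --- Western Electric zone rules --------------------------------------------

UNIT = ChartSpec(0.0, 1.0)


@pytest.mark.parametrize(
    "values, expected, indices",
    [
        ([0.5, 3.2, -1], True, [1]),
        ([2.9, -2.9], False, []),
        ([3.0], False, []),  # exactly on the limit: "beyond" is strict
        ([-3.5, 3.5], True, [0, 1]),
    ],
)
def test_we1_points_beyond_three_sigma(values, expected, indices):
    res = we_rule1(values, UNIT)
    assert res.signal is expected
    assert res.evidence["indices"] == indices


@pytest.mark.parametrize(
    "values, expected",
    [
        ([2.5, 0.1, 2.6], True),
        ([2.5, -2.5, 0.2], False),  # beyond-2 points on opposite sides
        ([2.5, 2.5], False),  # no full window of three
        ([0.0, 2.1, 2.1, 0.0], True),
        ([-2.5, 0.0, -2.5], True),
    ],
)
def test_we2_two_of_three_beyond_two_sigma_same_side(values, expected):
    assert we_rule2(values, UNIT).signal is expected


@pytest.mark.parametrize(
    "values, expected",
    [
        ([1.5, 1.2, 0.5, 1.3, 1.1], True),
        ([1.5, 1.2, -0.5, 0.3, 1.1], False),
        ([1.5, 1.5, 1.5, 1.5], False),  # no full window of five
        ([-1.5, -1.2, -0.5, -1.3, -1.1], True),
    ],
)
def test_we3_four_of_five_beyond_one_sigma_same_side(values, expected):
    assert we_rule3(values, UNIT).signal is expected


def test_we4_eight_successive_same_side():
    assert we_rule4([0.5] * 8, UNIT).signal
    assert not we_rule4([0.5] * 7 + [-0.5], UNIT).signal
    assert not we_rule4([0.5, -0.5] * 10, UNIT).signal
    # on-centre points neither break nor contribute (same as the runs rule)
    res = we_rule4([0.5, 0.5, 0.5, 0.0, 0.5, 0.5, 0.5, 0.5, 0.5], UNIT)
    assert res.signal
    assert res.evidence["longest_run"] == 8
    assert res.evidence["indices"] == [0, 1, 2, 4, 5, 6, 7, 8]


# --- Anhoej rules -----------------------------------------------------------

def test_anhoej_long_run_signals_at_n24():
    # 24 useful points, longest run 9 > limit 8
    values = [1.0] * 9 + [-1.0, 1.0] * 7 + [-1.0]
    assert useful_count(values, 0) == 24
    signal, results = anhoej_signal(values, 0)
    assert signal
    assert results["anhoej_runs"].signal
    assert results["anhoej_runs"].evidence == {
        "longest_run": 9, "limit": 8, "n_useful": 24, "skipped": False,
    }


def test_anhoej_no_signal_exactly_at_limits_n24():
    # 9 runs of lengths 8,2,2,... -> longest run 8, crossings 8: neither strict
    # inequality is met, so the chart shows random variation.
    values = []
    side = 1.0
    for length in [8] + [2] * 8:
        values += [side] * length
        side = -side
    assert useful_count(values, 0) == 24
    signal, results = anhoej_signal(values, 0)
    assert not signal
    assert results["anhoej_runs"].evidence["longest_run"] == 8
    assert results["anhoej_crossings"].evidence["crossings"] == 8


def test_anhoej_alternating_series_is_maximally_random():
    signal, results = anhoej_signal([1.0, -1.0] * 5, 0)
    assert not signal
    assert results["anhoej_crossings"].evidence["crossings"] == 9


def test_anhoej_crossings_skipped_below_two_useful_points():
    signal, results = anhoej_signal([1.0, 0.0], 0)
    assert results["anhoej_crossings"].evidence["skipped"]
    assert not signal


# --- rule sets --------------------------------------------------------------

def test_apply_ruleset_respects_membership():
    spike = [0.0, 0.0, 4.0, 0.1, -0.1]  # triggers we1 only
    assert not apply_ruleset(spike, UNIT, "anhoej").signal
    assert apply_ruleset(spike, UNIT, ("we1", "anhoej_runs")).signal
    report = apply_ruleset(spike, UNIT, "anhoej+we1")
    assert report.signal and report.triggered == ["we1"]


def test_unknown_ruleset_rejected():
    with pytest.raises(ConfigurationError):
        apply_ruleset([1.0], UNIT, "nelson")
    with pytest.raises(ConfigurationError):
        apply_ruleset([1.0], UNIT, ())


def test_chart_spec_validation_and_limits():
    with pytest.raises(ConfigurationError):
        ChartSpec(0.0, 0.0)
    with pytest.raises(ConfigurationError):
        ChartSpec(0.0, -1.0)
    spec = ChartSpec(10.0, 2.0)
    assert spec.limits == (4.0, 6.0, 8.0, 12.0, 14.0, 16.0)
    assert list(spec.limits) == sorted(spec.limits)


# --- properties -------------------------------------------------------------

# exact quarter-grid values keep every arithmetic transformation lossless,
# so invariance can be asserted exactly rather than within a tolerance
quarter_values = st.lists(
    st.integers(-40, 40).map(lambda q: q / 4.0), min_size=1, max_size=30
)


@given(quarter_values, st.integers(-50, 50), st.integers(-3, 3))
def test_signals_invariant_under_translation_and_scaling(values, shift, log2_scale):
    scale = 2.0 ** log2_scale
    base = rule_signals(np.array(values), UNIT)
    moved = rule_signals(
        np.array(values) * scale + shift, ChartSpec(float(shift), scale)
    )
    assert base == moved


@given(quarter_values)
def test_signals_invariant_under_reflection(values):
    x = np.array(values)
    assert rule_signals(x, UNIT) == rule_signals(-x, UNIT)


@given(quarter_values)
def test_runs_and_crossings_identity(values):
    """Sum of run lengths equals n_useful; runs = crossings + 1."""
    sides = [1 if v > 0 else -1 for v in values if v != 0]
    run_lengths = [len(list(g)) for _, g in groupby(sides)]
    assert sum(run_lengths) == useful_count(values, 0)
    assert longest_run(values, 0) == (max(run_lengths) if run_lengths else 0)
    if sides:
        assert len(run_lengths) == count_crossings(values, 0) + 1


@given(
    quarter_values,
    st.sets(st.sampled_from(RULE_IDS), min_size=1),
    st.sets(st.sampled_from(RULE_IDS)),
)
def test_ruleset_signal_is_monotone_in_membership(values, subset, extra):
    superset = subset | extra
    if apply_ruleset(values, UNIT, tuple(subset)).signal:
        assert apply_ruleset(values, UNIT, tuple(superset)).signal


@given(quarter_values)
def test_fast_path_agrees_with_reported_rules(values):
    fast = rule_signals(np.array(values), UNIT)
    report = apply_ruleset(values, UNIT, tuple(RULE_IDS))
    assert fast == {rid: report.results[rid].signal for rid in RULE_IDS}
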