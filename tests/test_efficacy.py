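"""Kaplan–Meier, log-rank, %ILS and BBB locomotor comparisons."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bnct.efficacy import (
    AnimalRecord,
    bbb_group_compare,
    format_p,
    km_estimate,
    logrank_test,
    median_survival,
    percent_ils,
    prepare_bbb_matrix,
    survival_summary,
)
from conftest import km_oracle


def _animal(subject_id, group, survival, event=1, series=None):
    return AnimalRecord(
        subject_id=subject_id,
        group=group,
        survival_days=survival,
        event=event,
        bbb_series=series or {},
    )


def test_km_three_deaths():
    curve = km_estimate([1, 2, 3], [1, 1, 1])
    assert curve.event_times.tolist() == [1, 2, 3]
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
    assert curve.at_risk.tolist() == [3, 2, 1]


def test_km_all_censored_stays_at_one():
    curve = km_estimate([5, 8, 13], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(100.0) == 1.0


def test_km_single_subject_drops_to_zero():
    curve = km_estimate([7], [1])
    assert curve.survival_at(6.9) == 1.0
    assert curve.survival_at(7.0) == 0.0


def test_km_empty_errors():
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_km_matches_oracle_with_ties_and_censoring():
    times = [13, 14, 14, 15, 15, 15, 16, 16]
    events = [1, 1, 0, 1, 1, 1, 1, 0]
    curve = km_estimate(times, events)
    t_oracle, s_oracle = km_oracle(np.array(times), np.array(events))
    assert curve.event_times == pytest.approx(t_oracle)
    assert curve.survival == pytest.approx(s_oracle, rel=1e-12)


@given(extra=st.floats(min_value=20, max_value=100))
def test_late_censored_subject_adds_no_drop_and_lifts_survival(extra):
    """A subject censored after the last event introduces no new step; it
    enlarges every risk set, so S can only move up at each event time."""
    base = km_estimate([13, 14, 15, 16], [1, 1, 1, 1])
    extended = km_estimate([13, 14, 15, 16, extra], [1, 1, 1, 1, 0])
    assert extended.event_times.tolist() == base.event_times.tolist()
    for t in (13, 14, 15, 16):
        assert extended.survival_at(t) >= base.survival_at(t) - 1e-12


def test_median_all_deaths_same_day():
    med = median_survival(km_estimate([15] * 8, [1] * 8))
    assert med.median == 15 and med.defined


def test_median_first_time_survival_drops_below_half():
    med = median_survival(km_estimate([13, 14, 14, 15, 15, 15, 16, 16], [1] * 8))
    assert med.median == 15


def test_median_undefined_under_heavy_censoring():
    with pytest.warns(UserWarning):
        med = median_survival(km_estimate([10, 20, 30], [0, 0, 0]))
    assert not med.defined and math.isinf(med.median)


def test_logrank_identical_groups_null():
    a = [_animal(f"a{i}", "A", t) for i, t in enumerate([5, 8, 13])]
    b = [_animal(f"b{i}", "B", t) for i, t in enumerate([5, 8, 13])]
    res = logrank_test(a, b)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_separated_groups_significant_and_symmetric():
    a = ([1, 2, 3], [1, 1, 1])
    b = ([10, 11, 12], [1, 1, 1])
    res = logrank_test(a, b)
    assert res.p < 0.05
    assert logrank_test(b, a).chi2 == pytest.approx(res.chi2, rel=1e-12)


def test_logrank_no_events_flagged():
    a = ([5, 6], [0, 0])
    b = ([7, 8], [0, 0])
    with pytest.warns(UserWarning):
        res = logrank_test(a, b)
    assert not res.defined


@pytest.mark.parametrize(
    "treated, untreated, expected",
    [(32.5, 15, 116.7), (15.5, 15, 3.3), (20, 20, 0.0)],
)
def test_percent_ils(treated, untreated, expected):
    assert percent_ils(treated, untreated) == expected


def test_percent_ils_requires_positive_reference():
    with pytest.raises(ValueError):
        percent_ils(10, 0)


@given(
    k=st.floats(min_value=0.1, max_value=50),
    mst=st.tuples(
        st.floats(min_value=1, max_value=100), st.floats(min_value=1, max_value=100)
    ),
)
def test_percent_ils_scale_invariant(k, mst):
    treated, untreated = mst
    assert percent_ils(k * treated, k * untreated, ndigits=None) == pytest.approx(
        percent_ils(treated, untreated, ndigits=None), rel=1e-9, abs=1e-9
    )


def test_bbb_matrix_zeroes_after_death():
    rec = _animal("r1", "untreated", 10, series={d: max(21 - d, 6) for d in range(11)})
    healthy = _animal(
        "r2", "normal", 14, event=0, series={d: 21 for d in range(15)}
    )
    matrix = prepare_bbb_matrix([rec, healthy], start_day=7, end_day=14)
    assert matrix.days.tolist() == list(range(7, 15))
    dead_row = matrix.scores[0]
    assert dead_row[matrix.days > 10].tolist() == [0, 0, 0, 0]
    assert dead_row[matrix.days <= 10].tolist() == [14, 13, 12, 11]
    assert (matrix.scores[1] == 21).all()


def test_bbb_matrix_missing_day_policies():
    rec = _animal("r1", "g", 10, series={7: 20, 9: 18, 10: 5})
    with pytest.raises(ValueError):
        prepare_bbb_matrix([rec], start_day=7, end_day=10)
    matrix = prepare_bbb_matrix([rec], start_day=7, end_day=10, missing="carry_forward")
    assert matrix.scores[0].tolist() == [20, 20, 18, 5]


def test_bbb_matrix_empty_grid():
    rec = _animal("r1", "g", 5, series={0: 21})
    matrix = prepare_bbb_matrix([rec], start_day=3, end_day=2)
    assert matrix.scores.shape == (1, 0)


def test_bbb_scores_stay_in_range():
    with pytest.raises(ValueError):
        _animal("r", "g", 5, series={0: 22})
    with pytest.raises(ValueError):
        _animal("r", "g", 5, series={6: 10})  # score after death day


def test_manova_identical_groups_is_null():
    series = [{0: 21, 1: 20, 2: 18}, {0: 21, 1: 19, 2: 17}, {0: 20, 1: 19, 2: 16}]
    records = [
        _animal(f"a{i}", "A", 10, series=s) for i, s in enumerate(series)
    ] + [_animal(f"b{i}", "B", 10, series=s) for i, s in enumerate(series)]
    matrix = prepare_bbb_matrix(records, start_day=0, end_day=2)
    res = bbb_group_compare(matrix)
    assert res.wilks_lambda == pytest.approx(1.0, abs=1e-9)
    assert res.p == pytest.approx(1.0, abs=1e-9)


def test_manova_univariate_equals_anova_f():
    a_scores = [14, 12, 16]
    b_scores = [20, 19, 21]
    records = [
        _animal(f"a{i}", "A", 10, series={5: s}) for i, s in enumerate(a_scores)
    ] + [_animal(f"b{i}", "B", 10, series={5: s}) for i, s in enumerate(b_scores)]
    matrix = prepare_bbb_matrix(records, start_day=5, end_day=5)
    res = bbb_group_compare(matrix)
    f_oracle, p_oracle = stats.f_oneway(a_scores, b_scores)
    assert res.f_value == pytest.approx(f_oracle, rel=1e-9)
    assert res.p == pytest.approx(p_oracle, rel=1e-9)


def test_manova_thins_when_days_exceed_error_df():
    rng = np.random.default_rng(5)
    records = []
    for g, base in (("A", 18), ("B", 10)):
        for i in range(3):
            series = {
                d: int(np.clip(base + rng.integers(-2, 3), 0, 21)) for d in range(10)
            }
            records.append(_animal(f"{g}{i}", g, 20, series=series))
    matrix = prepare_bbb_matrix(records, start_day=0, end_day=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = bbb_group_compare(matrix)
    assert res.thinned
    assert len(res.days_used) <= 4  # error df = 6 subjects - 2 groups


def test_survival_summary_reference_first_and_ils():
    records = [_animal(f"u{i}", "untreated", t) for i, t in enumerate([14, 15, 15, 16])]
    records += [_animal(f"t{i}", "BNCT", t) for i, t in enumerate([30, 32, 33, 35])]
    rows = survival_summary(records, "untreated")
    assert rows[0].group == "untreated" and rows[0].pct_ils is None
    bnct = rows[1]
    # S first reaches 0.5 at the second-smallest time of the even split
    assert bnct.median == 32.0
    assert bnct.pct_ils == percent_ils(32.0, 15.0)
    assert bnct.p_vs_reference < 0.05


def test_survival_summary_requires_reference():
    with pytest.raises(ValueError):
        survival_summary([_animal("a", "A", 10)], "untreated")


def test_p_value_formatting_mirrors_reporting_convention():
    assert format_p(3e-5) == "< 0.0001"
    assert format_p(0.224) == "0.224"
    assert format_p(float("nan")) == "NA"


def test_km_brute_force_small_cohorts():
    """Exhaustive check of the product-limit estimate against the
    first-principles oracle over small cohorts with ties and censoring."""
    for n in range(1, 5):
        for times in itertools.combinations_with_replacement([1, 2, 3], n):
            for events in itertools.product([0, 1], repeat=n):
                t = np.array(times, dtype=float)
                e = np.array(events, dtype=int)
                curve = km_estimate(t, e)
                ot, os_ = km_oracle(t, e)
                assert curve.event_times == pytest.approx(ot)
                assert curve.survival == pytest.approx(os_, rel=1e-12, abs=1e-12)
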