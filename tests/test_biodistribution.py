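"""Uptake normalisation, organ summaries, ratios and timing selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bnct.biodistribution import (
    BoronMeasurement,
    CellUptakeRecord,
    TimecourseSummary,
    cellular_boron_concentration,
    compare_printed_ratios,
    concentration_dependence_test,
    retention_summary,
    select_irradiation_time,
    summarize_timecourse,
    tissue_ratios,
)
from bnct.reference import PRINTED_RATIOS, reference_summaries


def _measurements(tissue, time_h, values):
    return [
        BoronMeasurement(subject_id=f"s{i}", tissue=tissue, time_h=time_h, conc=v)
        for i, v in enumerate(values)
    ]


@pytest.mark.parametrize(
    "mass, count, expected",
    [(0.019, 1_000_000, 19.0), (0.0, 12345, 0.0), (1.0, 1_000_000_000, 1.0)],
)
def test_cellular_concentration_normalisation(mass, count, expected):
    assert cellular_boron_concentration(mass, count) == pytest.approx(expected)


def test_cellular_concentration_rejects_zero_cells():
    with pytest.raises(ValueError):
        cellular_boron_concentration(1.0, 0)


def test_summarize_timecourse_sample_sd():
    rows = summarize_timecourse(_measurements("tumor", 2.5, [1.0, 3.0]))
    (row,) = rows
    assert row.n == 2
    assert row.mean == pytest.approx(2.0)
    assert row.sd == pytest.approx(math.sqrt(2), abs=1e-12)


def test_summarize_timecourse_degenerate_and_identical():
    (single,) = summarize_timecourse(_measurements("blood", 6.0, [4.2]))
    assert single.sd == 0.0 and single.sd_degenerate
    (flat,) = summarize_timecourse(_measurements("blood", 6.0, [4.2] * 5))
    assert flat.sd == 0.0 and not flat.sd_degenerate


def test_summarize_timecourse_empty_errors():
    with pytest.raises(ValueError):
        summarize_timecourse([])


@given(perm=st.permutations(list(range(6))))
def test_summarize_timecourse_permutation_invariant(perm):
    values = [26.1, 31.0, 22.4, 28.8, 25.3, 27.7]
    base = summarize_timecourse(_measurements("tumor", 2.5, values))
    shuffled = summarize_timecourse(
        _measurements("tumor", 2.5, [values[i] for i in perm])
    )
    assert base[0].mean == pytest.approx(shuffled[0].mean)
    assert base[0].sd == pytest.approx(shuffled[0].sd)


@pytest.mark.parametrize(
    "model, time_h, expected",
    [
        ("F98", 2.5, (5.0, 4.0, 1.3)),
        ("F98", 6.0, (4.1, 3.5, 1.2)),
        ("9L", 24.0, (3.0, 3.2, 1.0)),
    ],
)
def test_table_mode_reproduces_printed_ratios(model, time_h, expected):
    r = tissue_ratios(reference_summaries(model), time_h, mode="table")
    assert (r.t_sc, r.t_bl, r.bl_sc) == expected


def test_known_unreconstructable_cells_are_flagged_not_matched():
    """Some printed ratio cells derive from unrounded source data and cannot
    be rebuilt from the printed means; they must be flagged, not forced."""
    f98 = compare_printed_ratios(reference_summaries("F98"), PRINTED_RATIOS["F98"])
    nine_l = compare_printed_ratios(reference_summaries("9L"), PRINTED_RATIOS["9L"])
    f98_mis = {
        (row.time_h, row.ratio) for row in f98.itertuples() if row.mismatch
    }
    nine_l_mis = {
        (row.time_h, row.ratio) for row in nine_l.itertuples() if row.mismatch
    }
    assert (24.0, "T/SC") in f98_mis
    assert (2.5, "T/SC") in nine_l_mis
    # the cells the reconstruction must match are not flagged
    assert (2.5, "T/SC") not in f98_mis and (2.5, "T/Bl") not in f98_mis
    assert (6.0, "T/SC") not in f98_mis
    assert (24.0, "T/SC") not in nine_l_mis


def test_all_tissues_equal_gives_unit_ratios():
    rows = []
    for tissue in ("tumor", "spinal cord", "blood"):
        rows += _measurements(tissue, 2.5, [7.0, 7.0])
    r = tissue_ratios(summarize_timecourse(rows), 2.5)
    assert (r.t_sc, r.t_bl, r.bl_sc) == (1.0, 1.0, 1.0)


def test_tissue_ratios_errors():
    summaries = summarize_timecourse(_measurements("tumor", 2.5, [5.0]))
    with pytest.raises(ValueError):
        tissue_ratios(summaries, 2.5)  # spinal cord and blood missing
    with pytest.raises(ValueError):
        tissue_ratios(reference_summaries("F98"), 12.0)  # no such time


@given(scale=st.floats(min_value=0.01, max_value=100))
def test_ratio_scale_equivariance_and_consistency(scale):
    rows = []
    for tissue, values in [
        ("tumor", [24.0, 29.0]),
        ("spinal cord", [5.0, 5.6]),
        ("blood", [6.3, 7.1]),
    ]:
        rows += _measurements(tissue, 2.5, [v * scale for v in values])
    r = tissue_ratios(summarize_timecourse(rows), 2.5)
    base = tissue_ratios(
        summarize_timecourse(
            _measurements("tumor", 2.5, [24.0, 29.0])
            + _measurements("spinal cord", 2.5, [5.0, 5.6])
            + _measurements("blood", 2.5, [6.3, 7.1])
        ),
        2.5,
    )
    # scaling every concentration leaves the ratios unchanged
    assert r.t_sc == pytest.approx(base.t_sc, rel=1e-9)
    assert r.t_bl == pytest.approx(base.t_bl, rel=1e-9)
    # and T/Bl x Bl/SC == T/SC holds to machine precision on raw values
    assert r.t_bl * r.bl_sc == pytest.approx(r.t_sc, rel=1e-12)


@pytest.mark.parametrize("model", ["F98", "9L"])
def test_irradiation_time_selected_from_published_timecourse(model):
    assert select_irradiation_time(reference_summaries(model)) == 2.5


def test_irradiation_time_tie_breaks_to_earliest():
    flat = [
        TimecourseSummary(tissue, t, 4, mean, 0.5)
        for t in (2.5, 6.0, 24.0)
        for tissue, mean in [("tumor", 20.0), ("spinal cord", 5.0), ("blood", 6.0)]
    ]
    assert select_irradiation_time(flat) == 2.5


def test_irradiation_time_requires_complete_timepoint():
    with pytest.raises(ValueError):
        select_irradiation_time(
            [TimecourseSummary("tumor", 2.5, 4, 20.0, 1.0)]
        )


def _uptake_group(cell_line, level, concs, washout=False):
    return [
        CellUptakeRecord(
            cell_line=cell_line,
            exposure_conc=level,
            exposure_h=2.5,
            boron_mass=c * 1e6 / 1e9,
            cell_count=1_000_000,
            replicate=i + 1,
            washout=washout,
        )
        for i, c in enumerate(concs)
    ]


def test_identical_groups_give_null_t_test():
    records = _uptake_group("F98", 5, [10.0, 12.0, 14.0]) + _uptake_group(
        "F98", 10, [10.0, 12.0, 14.0]
    )
    table, _ = concentration_dependence_test(records)
    row = table[table["comparison"] == "level"].iloc[0]
    assert row["t"] == pytest.approx(0.0, abs=1e-12)
    assert row["p"] == pytest.approx(1.0)


def test_pooled_t_matches_hand_formula():
    """n=3 groups built to have exactly the published level means and SDs;
    the pooled two-sample t is checked against the closed-form oracle."""
    m1, s1, m2, s2 = 42.3, 2.6, 33.1, 1.6
    a, b = [m1 - s1, m1, m1 + s1], [m2 - s2, m2, m2 + s2]
    records = _uptake_group("F98", 10, a) + _uptake_group("9L", 10, b)
    table, _ = concentration_dependence_test(records)
    row = table[table["comparison"] == "cell_line"].iloc[0]
    sp = math.sqrt((s1**2 + s2**2) / 2)  # equal n pooled SD
    t_hand = (m1 - m2) / (sp * math.sqrt(2 / 3))
    assert abs(row["t"]) == pytest.approx(abs(t_hand), rel=1e-9)
    assert t_hand == pytest.approx(5.22, abs=0.01)
    assert row["p"] == pytest.approx(0.0064, abs=0.001)


def test_separated_groups_p_shrinks_with_jitter():
    eps = 1e-6
    records = _uptake_group("F98", 5, [0.0, eps, 2 * eps]) + _uptake_group(
        "F98", 10, [1.0, 1.0 + eps, 1.0 + 2 * eps]
    )
    table, monotone = concentration_dependence_test(records)
    assert table.iloc[0]["p"] < 1e-6
    assert monotone["F98"]


def test_monotonicity_verdict_and_welch_flag():
    records = (
        _uptake_group("F98", 5, [19.0, 18.0, 20.0])
        + _uptake_group("F98", 10, [42.0, 43.0, 41.0])
        + _uptake_group("F98", 20, [26.0, 36.0, 28.0])  # dips back down, wider spread
    )
    _, monotone = concentration_dependence_test(records)
    assert monotone == {"F98": False}
    pooled, _ = concentration_dependence_test(records, equal_var=True)
    welch, _ = concentration_dependence_test(records, equal_var=False)
    assert not np.allclose(pooled["p"].values, welch["p"].values)


def test_too_few_replicates_error():
    records = _uptake_group("F98", 5, [19.0]) + _uptake_group("F98", 10, [42.0, 43.0])
    with pytest.raises(ValueError):
        concentration_dependence_test(records)


def test_washout_records_are_summary_only():
    exposed = _uptake_group("F98", 5, [19.0, 20.0, 21.0])
    retained = _uptake_group("F98", 5, [9.0, 10.0, 11.0], washout=True)
    table, _ = concentration_dependence_test(exposed + retained + _uptake_group("F98", 10, [40.0, 41.0, 42.0]))
    # washout values never enter the comparisons
    assert table[table["comparison"] == "level"].iloc[0]["mean_a"] == pytest.approx(20.0)
    summary = retention_summary(exposed + retained)
    assert len(summary) == 1
    assert summary.iloc[0]["mean"] == pytest.approx(10.0)
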