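"""Ratio tables, OLS regression vs normal equations, Welch t-test, totals."""

import numpy as np
import pytest

from igtscan.datasets import load_nuclear_repeat_table
from igtscan.transfer_stats import (
    fit_regression,
    group_t_test,
    ratio_table,
    round_half_up,
    species_totals,
)

from oracles import ols_normal_equations


def test_ratio_examples():
    rows, n_flagged = ratio_table(
        [("A. thaliana", 23.58, 119.67), ("C. papaya", 316.53, 369.78), ("x", 1, 1)]
    )
    assert rows[0].percent == 19.70 and rows[0].below_threshold_flag
    assert rows[1].percent == 85.60 and not rows[1].below_threshold_flag
    assert rows[2].percent == 100.00
    assert n_flagged == 1


def test_ratio_reproduces_published_table():
    """All 22 published nuclear repeat/genome percentages to 2 decimals,
    and exactly the 4 footnoted species flagged below 20%."""
    table = load_nuclear_repeat_table()
    rows, n_flagged = ratio_table(
        list(zip(table.species, table.repeat_mb, table.genome_mb))
    )
    assert len(rows) == 22
    for row, reported in zip(rows, table.reported_pct):
        assert row.percent == pytest.approx(reported, abs=0.005)
    assert n_flagged == 4
    flagged = {r.species_id for r in rows if r.below_threshold_flag}
    assert flagged == {"A. thaliana", "S. polyrhiza", "M. polymorpha", "P. patens"}


def test_ratio_rejects_bad_denominator():
    with pytest.raises(ValueError, match="positive"):
        ratio_table([("x", 1.0, 0.0)])


def test_round_half_up():
    assert round_half_up(19.705) == 19.71
    assert round_half_up(19.704) == 19.70


def test_regression_exact_line_and_degenerate():
    res = fit_regression([(x, 2 * x + 1) for x in range(10)])
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)
    flat = fit_regression([(0, 5.0), (1, 5.0), (2, 5.0)])
    assert flat.r_squared == 0.0 and flat.degenerate_response
    with pytest.raises(ValueError, match="degenerate predictor"):
        fit_regression([(1.0, 2.0), (1.0, 3.0)])


def test_regression_matches_normal_equations():
    rng = np.random.default_rng(8)
    pts = [(x, 3 * x + rng.normal()) for x in np.linspace(0, 10, 20)]
    res = fit_regression(pts)
    slope, intercept, r2 = ols_normal_equations(pts)
    assert res.slope == pytest.approx(slope, abs=1e-9)
    assert res.intercept == pytest.approx(intercept, abs=1e-9)
    assert res.r_squared == pytest.approx(r2, abs=1e-9)


def test_r2_decreases_with_noise_in_expectation():
    rng = np.random.default_rng(5)
    x = np.linspace(0, 10, 30)
    mean_r2 = []
    for sigma in (0.0, 1.0, 4.0, 16.0):
        r2s = [
            fit_regression(list(zip(x, 3 * x + rng.normal(scale=sigma, size=30) if sigma else 3 * x))).r_squared
            for _ in range(20)
        ]
        mean_r2.append(np.mean(r2s))
    assert mean_r2[0] == pytest.approx(1.0)
    assert mean_r2 == sorted(mean_r2, reverse=True)


def test_t_test_degenerate_and_forced_separation():
    same = group_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert same.t_statistic == 0.0 and same.p_value == 1.0
    res = group_t_test([0, 0, 0, 0], [10, 10, 10, 10.0001])
    assert res.p_value < 0.01
    assert res.significance_marker == "**"


def test_t_test_welch_vs_student_switch():
    a = [1.0, 2.0, 3.0, 4.0]
    b = [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]
    welch = group_t_test(a, b, welch=True)
    student = group_t_test(a, b, welch=False)
    assert welch.t_statistic != student.t_statistic
    with pytest.raises(ValueError):
        group_t_test([1.0], b)


def test_species_totals_union(small_trio):
    from igtscan import scan_transfers

    segs = scan_transfers(small_trio.mitochondrial, small_trio.nuclear)
    df = species_totals(segs)
    row = df[(df.species_id == "fix01") & (df.segment_class == "numt")]
    assert len(row) == 1
    total = int(row.total_bp.iloc[0])
    truth = sum(
        t.recipient_end - t.recipient_start
        for t in small_trio.truth
        if t.event_type in ("numt", "gene_copy")
    )
    assert total == pytest.approx(truth, rel=0.05)
    assert row.whisker_low.iloc[0] == pytest.approx(total * 0.95)
    assert row.whisker_high.iloc[0] == pytest.approx(total * 1.05)


def test_species_totals_counts_overlaps_once():
    from igtscan.homology_search import HSP, SegmentClass, TransferSegment
    from igtscan import Compartment

    def seg(t0, t1):
        h = HSP("q", "nuc", 0, t1 - t0, t0, t1, "+", t1 - t0, t1 - t0, t1 - t0, 0.0)
        return TransferSegment(
            Compartment.MITOCHONDRIAL, Compartment.NUCLEAR, "sp", h,
            SegmentClass.NUMT, sequence="A" * (t1 - t0),
        )

    df = species_totals([seg(0, 100), seg(200, 400), seg(350, 500)])
    assert int(df.total_bp.iloc[0]) == 100 + 300
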