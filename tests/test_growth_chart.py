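"""Operator agreement and weekly percentile chart construction."""

import numpy as np
import pandas as pd
import pytest

from uhtape import bland_altman, mean_of_operators, simulate_phase1, weekly_percentiles
from uhtape.growth_chart import GrowthChart


def _pairs(diffs, base=25.0):
    return pd.DataFrame(
        {
            "uh_op1_cm": [base + d for d in diffs],
            "uh_op2_cm": [base] * len(diffs),
        }
    )


@pytest.mark.parametrize(
    "a,b,expected", [(20.0, 22.0, 21.0), (18.4, 21.1, 19.75), (27.3, 27.3, 27.3)]
)
def test_mean_of_operators(a, b, expected):
    assert mean_of_operators(a, b) == pytest.approx(expected)


def test_mean_of_operators_refuses_missing_readings():
    with pytest.raises(ValueError):
        mean_of_operators(20.0, None)
    with pytest.raises(ValueError):
        mean_of_operators(float("nan"), 20.0)


def test_bland_altman_identical_pairs():
    res = bland_altman(_pairs([0.0, 0.0, 0.0]))
    assert res.bias == 0.0 and res.sd_diff == 0.0
    assert (res.loa_low, res.loa_high) == (0.0, 0.0)


def test_bland_altman_hand_computed_limits():
    # differences (-1, 0, 1): bias 0, sample SD 1, limits +/- 1.96
    res = bland_altman(_pairs([-1.0, 0.0, 1.0]))
    assert res.bias == pytest.approx(0.0)
    assert res.sd_diff == pytest.approx(1.0)
    assert res.loa_low == pytest.approx(-1.96)
    assert res.loa_high == pytest.approx(1.96)


def test_bland_altman_symmetric_under_operator_swap():
    df = simulate_phase1(n_per_week=50, seed=2)
    fwd = bland_altman(df)
    swapped = bland_altman(df.rename(columns={"uh_op1_cm": "uh_op2_cm", "uh_op2_cm": "uh_op1_cm"}))
    assert swapped.bias == pytest.approx(-fwd.bias)
    assert swapped.sd_diff == pytest.approx(fwd.sd_diff)
    assert swapped.loa_low == pytest.approx(-fwd.loa_high)


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError):
        bland_altman(_pairs([1.0]))


def test_weekly_percentiles_constant_week():
    df = pd.DataFrame(
        {
            "ga_days": np.repeat(np.arange(24, 37) * 7, 4),
            "uh_op1_cm": 30.0,
            "uh_op2_cm": 30.0,
        }
    )
    chart = weekly_percentiles(df)
    assert (chart.table[["mean_cm", "p10_cm", "p50_cm", "p90_cm"]] == 30.0).all().all()
    assert (chart.table["sd_cm"] == 0.0).all()


def test_weekly_percentiles_linear_interpolation_oracle():
    # values 1..100 in one week: p50 = 50.5, p10 = 10.9, p90 = 90.1
    df = pd.DataFrame(
        {
            "ga_days": [24 * 7] * 100,
            "uh_op1_cm": np.arange(1.0, 101.0),
            "uh_op2_cm": np.arange(1.0, 101.0),
        }
    )
    chart = weekly_percentiles(df, week_range=(24, 24))
    row = chart.table.iloc[0]
    assert row["p50_cm"] == pytest.approx(50.5)
    assert row["p10_cm"] == pytest.approx(10.9)
    assert row["p90_cm"] == pytest.approx(90.1)
    assert row["n"] == 100


def test_weekly_percentiles_uses_mean_of_operators():
    df = pd.DataFrame(
        {"ga_days": [24 * 7, 24 * 7], "uh_op1_cm": [20.0, 24.0], "uh_op2_cm": [22.0, 26.0]}
    )
    chart = weekly_percentiles(df, week_range=(24, 24))
    assert chart.table.iloc[0]["mean_cm"] == pytest.approx(23.0)  # mean of 21, 25


def test_empty_week_is_named_in_error():
    df = simulate_phase1(n_per_week=5, week_range=(24, 30), seed=3)
    with pytest.raises(ValueError, match="week 31"):
        weekly_percentiles(df, week_range=(24, 36))


def test_quantiles_monotone_within_and_across_weeks(default_chart):
    t = default_chart.table
    assert (t["p10_cm"] <= t["p50_cm"]).all()
    assert (t["p50_cm"] <= t["p90_cm"]).all()
    # monotone growth with n=200/week: medians should rise across weeks
    assert t["p50_cm"].is_monotonic_increasing


def test_percentile_recovery_against_generating_normal():
    # week 30 under defaults: median 28.0, p10/p90 = 28 -/+ 1.2816 * sd
    df = simulate_phase1(n_per_week=1000, seed=31)
    chart = weekly_percentiles(df)
    row = chart.table[chart.table["week"] == 30].iloc[0]
    sd = np.hypot(2.0, 0.9 / np.sqrt(2.0))  # between-woman + averaged-operator noise
    assert row["p50_cm"] == pytest.approx(28.0, abs=0.3)
    assert row["p10_cm"] == pytest.approx(28.0 - 1.2816 * sd, abs=0.35)
    assert row["p90_cm"] == pytest.approx(28.0 + 1.2816 * sd, abs=0.35)


def test_chart_rejects_percentile_crossing_and_gaps():
    good = pd.DataFrame(
        {
            "week": [24, 25],
            "n": [5, 5],
            "mean_cm": [22.0, 23.0],
            "sd_cm": [1.0, 1.0],
            "p10_cm": [21.0, 22.0],
            "p50_cm": [22.0, 23.0],
            "p90_cm": [23.0, 24.0],
        }
    )
    GrowthChart(site="x", table=good)
    crossed = good.assign(p10_cm=[23.5, 22.0])
    with pytest.raises(ValueError, match="crossing"):
        GrowthChart(site="x", table=crossed)
    gapped = good.assign(week=[24, 26])
    with pytest.raises(ValueError, match="contiguous"):
        GrowthChart(site="x", table=gapped)


def test_chart_roundtrips_through_csv(tmp_path, default_chart):
    path = tmp_path / "chart.csv"
    default_chart.to_csv(path)
    back = GrowthChart.from_csv(path, site=default_chart.site)
    pd.testing.assert_frame_equal(back.table, default_chart.table)
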