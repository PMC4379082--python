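"""Cross-tabulation, dichotomization, sensitivity/specificity, ROC, projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uhtape import (
    ConfusionCounts,
    Endpoint,
    TapeSpec,
    crosstab,
    dichotomize,
    paper_data,
    predictive_projection,
    roc_curve,
    sens_spec,
    simulate_phase2,
    trapezoid_auc,
)
from uhtape.accuracy import CrossTab, binomial_interval
from uhtape.synthetic_cohort import GA_BANDS_3


def _ct(rows):
    """CrossTab from a 3x3 list: rows low/mid/high, columns early/preterm/term."""
    return CrossTab(
        site="x",
        tape="t",
        counts=pd.DataFrame(rows, index=["low", "mid", "high"], columns=list(GA_BANDS_3)),
    )


def shoelace_area_under(points):
    """Independent oracle: close the curve onto the x-axis and apply the
    shoelace polygon-area formula."""
    pts = sorted(points)
    poly = pts + [(1.0, 0.0), (0.0, 0.0)]
    s = 0.0
    for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


# --- crosstab -------------------------------------------------------------


def test_crosstab_single_subject():
    tape = TapeSpec(name="t", lower_cm=20.0, upper_cm=34.0)
    cohort = pd.DataFrame(
        {"subject_id": [1], "ga_days": [200], "uh_cm": [25.0], "ga_band": ["24.0-35.6"]}
    )
    ct = crosstab(cohort, tape)
    assert ct.counts.loc["mid", "24.0-35.6"] == 1
    assert ct.total == 1


def test_crosstab_conserves_subjects_and_counts_exclusions():
    tape = TapeSpec(name="t", lower_cm=22.6, upper_cm=33.4)
    cohort = simulate_phase2(seed=4)
    cohort.loc[cohort.index[:3], "uh_cm"] = np.nan
    ct = crosstab(cohort, tape)
    assert ct.total + ct.n_excluded == 250
    assert ct.n_excluded == 3


def test_crosstab_rejects_empty_cohort():
    tape = TapeSpec(name="t", lower_cm=20.0, upper_cm=34.0)
    with pytest.raises(ValueError):
        crosstab(pd.DataFrame(columns=["uh_cm", "ga_band"]), tape)


# --- dichotomize ----------------------------------------------------------


def test_dichotomize_reproduces_published_argentina_2x2():
    ct = paper_data.load_fixture("Argentina", "10-90")
    cc = dichotomize(ct, Endpoint.PRETERM_24_356)
    assert (cc.tp, cc.fn, cc.fp, cc.tn) == (126, 12, 104, 42)


def test_dichotomize_all_zero_noncase_columns():
    cc = dichotomize(_ct([[0, 3, 0], [0, 5, 0], [0, 2, 0]]), Endpoint.PRETERM_24_356)
    assert (cc.fp, cc.tn) == (0, 0)
    assert (cc.tp, cc.fn) == (5, 5)


def test_endpoint_20_equals_24_plus_band20_positives_when_low_row_empty():
    # brute force over the 9 cells: with an empty low row, the 20.0-35.6
    # endpoint adds only the band-20 mid counts to the true positives
    rows = [[0, 0, 0], [7, 11, 3], [2, 5, 13]]
    cc24 = dichotomize(_ct(rows), Endpoint.PRETERM_24_356)
    cc20 = dichotomize(_ct(rows), Endpoint.PRETERM_20_356)
    assert cc20.tp == cc24.tp + rows[1][0]


@settings(derandomize=True, max_examples=100)
@given(cells=st.lists(st.integers(min_value=0, max_value=50), min_size=9, max_size=9))
def test_dichotomize_conserves_totals(cells):
    ct = _ct(np.array(cells).reshape(3, 3))
    for endpoint in Endpoint:
        cc = dichotomize(ct, endpoint)
        assert cc.total == ct.total
        assert cc.cases == sum(
            int(ct.counts[b].sum()) for b in endpoint.case_bands
        )


# --- sens_spec and intervals ---------------------------------------------


def test_sensitivity_point_estimates_match_published_cells():
    se, _ = sens_spec(ConfusionCounts(tp=126, fp=0, fn=12, tn=1))
    assert round(100 * se.estimate, 1) == 91.3
    se, _ = sens_spec(ConfusionCounts(tp=154, fp=0, fn=23, tn=1))
    assert round(100 * se.estimate, 1) == 87.0


def test_wald_interval_matches_published_ci():
    _, lo, hi = binomial_interval(154, 177, "wald")
    assert (round(100 * lo, 1), round(100 * hi, 1)) == (82.1, 92.0)


def test_wald_interval_clipping_at_certainty():
    p, lo, hi = binomial_interval(20, 20, "wald")
    assert (p, lo, hi) == (1.0, 1.0, 1.0)
    _, lo_raw, hi_raw = binomial_interval(137, 139, "wald", clip=False)
    assert hi_raw > 1.0 - 1e-12  # printed-style unclipped upper limit


def test_clopper_pearson_option_brackets_wald():
    p, lo, hi = binomial_interval(90, 100, "clopper-pearson")
    assert lo == pytest.approx(0.8238, abs=5e-4)
    assert hi == pytest.approx(0.9510, abs=5e-4)
    with pytest.raises(ValueError):
        binomial_interval(1, 2, "bayes")


def test_sens_spec_requires_cases_and_noncases():
    with pytest.raises(ValueError):
        sens_spec(ConfusionCounts(tp=5, fp=0, fn=0, tn=0))


# --- ROC ------------------------------------------------------------------


def test_perfect_tape_gives_auc_one():
    pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
    assert trapezoid_auc(pts) == 1.0


def test_roc_from_argentina_fixtures_matches_published_auc():
    tabs = [paper_data.load_fixture("Argentina", t) for t in paper_data.TAPES]
    curve = roc_curve(tabs, Endpoint.PRETERM_20_356)
    assert round(curve.auc, 2) == 0.69
    assert curve.points[0] == (0.0, 0.0) and curve.points[-1] == (1.0, 1.0)
    assert all(0 <= x <= 1 and 0 <= y <= 1 for x, y in curve.points)
    assert curve.auc_ci_low <= curve.auc <= curve.auc_ci_high


def test_roc_refuses_mixed_sites():
    tabs = [paper_data.load_fixture("Argentina", "10-90"), paper_data.load_fixture("India", "50-50")]
    with pytest.raises(ValueError):
        roc_curve(tabs, Endpoint.PRETERM_24_356)


@settings(derandomize=True, max_examples=200)
@given(
    xs=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6, unique=True),
    ys=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=6, max_size=6),
)
def test_trapezoid_auc_equals_shoelace_oracle(xs, ys):
    pts = [(0.0, 0.0)] + sorted(zip(sorted(xs), ys)) + [(1.0, 1.0)]
    assert trapezoid_auc(pts) == pytest.approx(shoelace_area_under(pts), abs=1e-12)


# --- projections ----------------------------------------------------------


def test_projection_reproduces_published_worked_example():
    proj = predictive_projection(0.777, 0.886, 0.20)
    assert proj.rounded() == {
        "classified_positive_pct": 25,
        "tp_pct": 16,
        "fp_pct": 9,
        "tn_pct": 71,
        "fn_pct": 4,
    }


def test_projection_perfect_test():
    proj = predictive_projection(1.0, 1.0, 0.2)
    assert proj.classified_positive_pct == pytest.approx(20.0)
    assert proj.fp_pct == 0.0 and proj.fn_pct == 0.0


@settings(derandomize=True, max_examples=100)
@given(
    sens=st.floats(min_value=0.0, max_value=1.0),
    spec=st.floats(min_value=0.0, max_value=1.0),
    prev=st.floats(min_value=0.0, max_value=1.0),
)
def test_projection_cells_sum_to_100(sens, spec, prev):
    proj = predictive_projection(sens, spec, prev)
    total = proj.tp_pct + proj.fp_pct + proj.tn_pct + proj.fn_pct
    assert total == pytest.approx(100.0, abs=1e-9)
    assert proj.classified_positive_pct == pytest.approx(proj.tp_pct + proj.fp_pct)


def test_projection_rejects_out_of_range():
    with pytest.raises(ValueError):
        predictive_projection(1.2, 0.5, 0.1)
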