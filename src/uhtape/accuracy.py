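"""Diagnostic accuracy of tri-zone tapes against ultrasound-dated GA.

The evaluation reduces each site x tape cross-tab (3 zones x 3 GA bands)
to a 2x2 table for one of two endpoints, estimates sensitivity and
specificity with binomial confidence intervals, assembles the three tape
variants into an empirical ROC curve per site, and projects predictive
values at an assumed preterm prevalence.

Endpoints
---------
``preterm_24_356``
    Cases are pregnancies of 24.0-35.6 weeks; a positive test is a
    reading in the mid (red) zone.
``preterm_20_356``
    Cases are pregnancies of 20.0-35.6 weeks; a positive test is a
    reading in the mid or low (red or yellow) zone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import BAND_EARLY, BAND_PRETERM, BAND_TERM, GA_BANDS_3
from .tape_design import TapeSpec, Zone, classify_uh

Z95 = 1.96

ZONE_LABELS = ("low", "mid", "high")
CI_METHODS = ("wald", "clopper-pearson")


@dataclass
class CrossTab:
    """Zone x GA-band count table for one site and tape.

    ``counts`` is a 3x3 DataFrame indexed by zone (low/mid/high) with the
    three GA bands as columns.  ``n_excluded`` tallies subjects dropped
    for missing measurements; per-tape denominators are always taken from
    this table's own column sums.
    """

    site: str
    tape: str
    counts: pd.DataFrame = field(repr=False)
    n_excluded: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        c = self.counts
        if list(c.index) != list(ZONE_LABELS) or list(c.columns) != list(GA_BANDS_3):
            raise ValueError(
                f"counts must be indexed by {ZONE_LABELS} x {GA_BANDS_3}, "
                f"got {list(c.index)} x {list(c.columns)}"
            )
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def band_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


class Endpoint(enum.Enum):
    """Target GA range and the zones read as a positive test for it."""

    PRETERM_24_356 = "24.0-35.6"
    PRETERM_20_356 = "20.0-35.6"

    @property
    def case_bands(self) -> tuple[str, ...]:
        if self is Endpoint.PRETERM_24_356:
            return (BAND_PRETERM,)
        return (BAND_EARLY, BAND_PRETERM)

    @property
    def positive_zones(self) -> tuple[Zone, ...]:
        if self is Endpoint.PRETERM_24_356:
            return (Zone.MID,)
        return (Zone.MID, Zone.LOW)

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def non_cases(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.cases + self.non_cases


@dataclass(frozen=True)
class AccuracyEstimate:
    """A proportion with its 95% CI (clipped to [0, 1]) and raw counts."""

    kind: str
    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


def crosstab(
    cohort: pd.DataFrame,
    tape: TapeSpec,
    site: str = "",
    boundary: str = "upper-open",
) -> CrossTab:
    """Classify a phase-2 cohort with one tape and tabulate zone x GA band.

    Subjects with a missing ``uh_cm`` are excluded from the table and
    counted in ``n_excluded``, so counted + excluded equals the cohort
    size.
    """
    if cohort.empty:
        raise ValueError("cannot cross-tabulate an empty cohort")
    ok = cohort["uh_cm"].notna()
    counts = pd.DataFrame(0, index=list(ZONE_LABELS), columns=list(GA_BANDS_3))
    for _, row in cohort[ok].iterrows():
        zone = classify_uh(tape, row["uh_cm"], boundary=boundary)
        counts.loc[zone.label, row["ga_band"]] += 1
    return CrossTab(
        site=site or getattr(tape, "site", ""),
        tape=tape.name,
        counts=counts,
        n_excluded=int((~ok).sum()),
    )


def dichotomize(ct: CrossTab, endpoint: Endpoint) -> ConfusionCounts:
    """Reduce a 3x3 cross-tab to the endpoint's 2x2 confusion counts."""
    pos_rows = [z.label for z in endpoint.positive_zones]
    case_cols = list(endpoint.case_bands)
    noncase_cols = [b for b in GA_BANDS_3 if b not in case_cols]
    c = ct.counts
    tp = int(c.loc[pos_rows, case_cols].to_numpy().sum())
    fp = int(c.loc[pos_rows, noncase_cols].to_numpy().sum())
    fn = int(c.loc[:, case_cols].to_numpy().sum()) - tp
    tn = int(c.loc[:, noncase_cols].to_numpy().sum()) - fp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_interval(
    numerator: int,
    denominator: int,
    method: str = "wald",
    clip: bool = True,
) -> tuple[float, float, float]:
    """(estimate, ci_low, ci_high) for a binomial proportion.

    Wald (normal approximation, p +/- 1.96*sqrt(p(1-p)/n)) is the default;
    Clopper-Pearson (exact beta) is available as an option.  ``clip``
    restricts the Wald limits to [0, 1]; the unclipped form matches how
    such intervals are commonly printed.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    if method == "wald":
        se = np.sqrt(p * (1.0 - p) / denominator)
        lo, hi = p - Z95 * se, p + Z95 * se
        if clip:
            lo, hi = max(lo, 0.0), min(hi, 1.0)
    elif method == "clopper-pearson":
        lo = 0.0 if numerator == 0 else stats.beta.ppf(0.025, numerator, denominator - numerator + 1)
        hi = 1.0 if numerator == denominator else stats.beta.ppf(
            0.975, numerator + 1, denominator - numerator
        )
    else:
        raise ValueError(f"ci method must be one of {CI_METHODS}")
    return p, float(lo), float(hi)


def sens_spec(
    cc: ConfusionCounts,
    ci_method: str = "wald",
) -> tuple[AccuracyEstimate, AccuracyEstimate]:
    """Sensitivity and specificity with 95% CIs from a 2x2 table."""
    if cc.cases < 1 or cc.non_cases < 1:
        raise ValueError("need at least one case and one non-case")
    se, se_lo, se_hi = binomial_interval(cc.tp, cc.cases, ci_method)
    sp, sp_lo, sp_hi = binomial_interval(cc.tn, cc.non_cases, ci_method)
    return (
        AccuracyEstimate("sensitivity", se, se_lo, se_hi, cc.tp, cc.cases),
        AccuracyEstimate("specificity", sp, sp_lo, sp_hi, cc.tn, cc.non_cases),
    )


@dataclass
class ROCCurve:
    """Empirical ROC over discrete tape operating points for one site."""

    endpoint: Endpoint
    site: str
    points: list  # (fpr, tpr) incl. (0,0) and (1,1), sorted by fpr then tpr
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    tapes: list = field(default_factory=list)


def trapezoid_auc(points: list[tuple[float, float]]) -> float:
    """Area under piecewise-linear ROC points sorted by (fpr, tpr).

    Duplicate-fpr points contribute zero-width trapezoids, i.e. vertical
    segments are traversed in sorted order.
    """
    pts = sorted(points)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, x))


def hanley_mcneil_se(auc: float, n_cases: float, n_non_cases: float) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_cases - 1.0) * (q1 - auc**2)
        + (n_non_cases - 1.0) * (q2 - auc**2)
    ) / (n_cases * n_non_cases)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(tabs: list[CrossTab], endpoint: Endpoint) -> ROCCurve:
    """ROC over one site's tape set, (0,0)/(1,1)-augmented, trapezoidal AUC.

    Each tape contributes one operating point (1 - specificity,
    sensitivity) on its own denominators.  The AUC CI uses the
    Hanley-McNeil standard error with the mean per-tape case and non-case
    counts (the per-tape denominators may differ when measurements are
    missing).
    """
    if not tabs:
        raise ValueError("need at least one cross-tab")
    sites = {t.site for t in tabs}
    if len(sites) > 1:
        raise ValueError(f"cross-tabs must share a site, got {sorted(sites)}")
    pts, tapes, n_cases, n_non = [], [], [], []
    for ct in tabs:
        cc = dichotomize(ct, endpoint)
        se, sp = sens_spec(cc)
        pts.append((1.0 - sp.estimate, se.estimate))
        tapes.append(ct.tape)
        n_cases.append(cc.cases)
        n_non.append(cc.non_cases)
    points = sorted(pts + [(0.0, 0.0), (1.0, 1.0)])
    auc = trapezoid_auc(points)
    se_auc = hanley_mcneil_se(auc, float(np.mean(n_cases)), float(np.mean(n_non)))
    return ROCCurve(
        endpoint=endpoint,
        site=sites.pop(),
        points=points,
        auc=auc,
        auc_ci_low=max(auc - Z95 * se_auc, 0.0),
        auc_ci_high=min(auc + Z95 * se_auc, 1.0),
        tapes=tapes,
    )


@dataclass(frozen=True)
class ProjectionResult:
    """Population-level yield of the test at an assumed prevalence (percent)."""

    prevalence: float
    classified_positive_pct: float
    tp_pct: float
    fp_pct: float
    tn_pct: float
    fn_pct: float

    def rounded(self) -> dict:
        return {
            "classified_positive_pct": round(self.classified_positive_pct),
            "tp_pct": round(self.tp_pct),
            "fp_pct": round(self.fp_pct),
            "tn_pct": round(self.tn_pct),
            "fn_pct": round(self.fn_pct),
        }


def predictive_projection(
    sensitivity: float, specificity: float, prevalence: float
) -> ProjectionResult:
    """Expected classification mix when screening at a given prevalence.

    All four cell percentages sum to 100 before rounding;
    classified-positive is TP + FP.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    tp = prevalence * sensitivity
    fn = prevalence * (1.0 - sensitivity)
    fp = (1.0 - prevalence) * (1.0 - specificity)
    tn = (1.0 - prevalence) * specificity
    return ProjectionResult(
        prevalence=prevalence,
        classified_positive_pct=100.0 * (tp + fp),
        tp_pct=100.0 * tp,
        fp_pct=100.0 * fp,
        tn_pct=100.0 * tn,
        fn_pct=100.0 * fn,
    )


# ---------------------------------------------------------------------------
# Reproduction of the published evaluation from the embedded cross-tabs
# ---------------------------------------------------------------------------


@dataclass
class ReproductionReport:
    """Cell-by-cell comparison of recomputed vs published accuracy results."""

    accuracy: pd.DataFrame = field(repr=False)  # sens/spec cells with CIs
    auc: pd.DataFrame = field(repr=False)
    projection: pd.DataFrame = field(repr=False)

    @property
    def mismatches(self) -> pd.DataFrame:
        frames = [
            df[~df["matched"]].assign(section=name)
            for name, df in (
                ("accuracy", self.accuracy),
                ("auc", self.auc),
                ("projection", self.projection),
            )
        ]
        return pd.concat(frames, ignore_index=True)

    @property
    def all_matched(self) -> bool:
        return self.mismatches.empty

    def summary(self) -> str:
        lines = []
        for name, df in (
            ("accuracy", self.accuracy),
            ("auc", self.auc),
            ("projection", self.projection),
        ):
            lines.append(f"{name}: {int(df['matched'].sum())}/{len(df)} cells matched")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        pd.concat(
            [
                self.accuracy.assign(section="accuracy"),
                self.auc.assign(section="auc"),
                self.projection.assign(section="projection"),
            ],
            ignore_index=True,
        ).to_csv(path, index=False)

    def to_markdown(self) -> str:
        parts = [self.summary(), "", self.accuracy.to_markdown(index=False)]
        parts += ["", self.auc.to_markdown(index=False)]
        parts += ["", self.projection.to_markdown(index=False)]
        return "\n".join(parts)


PROJECTION_PREVALENCE = 0.20
PROJECTION_SITE, PROJECTION_TAPE = "India", "90-10"


def reproduce_paper() -> ReproductionReport:
    """Recompute every published accuracy cell from the embedded cross-tabs.

    Sensitivity/specificity cells (and their Wald CIs, unclipped as
    printed) are compared at one decimal on the percent scale; AUCs at
    two decimals; the 20%-prevalence projection at integer percent.
    """
    from . import paper_data

    paper_data.validate_fixtures()
    published = paper_data.published_accuracy()
    acc_rows = []
    roc_inputs: dict[tuple[str, Endpoint], list[CrossTab]] = {}
    for site in paper_data.SITES:
        for tape in paper_data.TAPES:
            ct = paper_data.load_fixture(site, tape)
            for endpoint in Endpoint:
                cc = dichotomize(ct, endpoint)
                roc_inputs.setdefault((site, endpoint), []).append(ct)
                for stat, num, den in (
                    ("sensitivity", cc.tp, cc.cases),
                    ("specificity", cc.tn, cc.non_cases),
                ):
                    p, lo, hi = binomial_interval(num, den, "wald", clip=False)
                    exp = published[
                        (published["site"] == site)
                        & (published["tape"] == tape)
                        & (published["endpoint"] == endpoint.label)
                        & (published["statistic"] == stat)
                    ].iloc[0]
                    got = (round(100 * p, 1), round(100 * lo, 1), round(100 * hi, 1))
                    want = (exp["estimate_pct"], exp["ci_low_pct"], exp["ci_high_pct"])
                    acc_rows.append(
                        {
                            "site": site,
                            "tape": tape,
                            "endpoint": endpoint.label,
                            "statistic": stat,
                            "computed_pct": got[0],
                            "published_pct": want[0],
                            "computed_ci": (got[1], got[2]),
                            "published_ci": (want[1], want[2]),
                            "matched": got == tuple(want),
                        }
                    )
    published_auc = paper_data.published_auc()
    auc_rows = []
    for (site, endpoint), tabs in roc_inputs.items():
        curve = roc_curve(tabs, endpoint)
        want = float(
            published_auc[
                (published_auc["site"] == site)
                & (published_auc["endpoint"] == endpoint.label)
            ].iloc[0]["auc"]
        )
        got = round(curve.auc, 2)
        auc_rows.append(
            {
                "site": site,
                "endpoint": endpoint.label,
                "computed_auc": got,
                "published_auc": want,
                "matched": got == want,
            }
        )
    # prevalence projection from the recomputed accuracy of one tape
    ct = paper_data.load_fixture(PROJECTION_SITE, PROJECTION_TAPE)
    se, sp = sens_spec(dichotomize(ct, Endpoint.PRETERM_20_356))
    proj = predictive_projection(se.estimate, sp.estimate, PROJECTION_PREVALENCE)
    proj_rows = [
        {"quantity": k, "computed_pct": v, "published_pct": w, "matched": v == w}
        for (k, v), w in zip(
            proj.rounded().items(), paper_data.PUBLISHED_PROJECTION_PCT
        )
    ]
    return ReproductionReport(
        accuracy=pd.DataFrame(acc_rows),
        auc=pd.DataFrame(auc_rows),
        projection=pd.DataFrame(proj_rows),
    )
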