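"""Phase-1 analysis: operator agreement and weekly uterine-height percentiles.

Paired measurements (two independent operators per woman) are first
checked for agreement with a Bland–Altman analysis; the per-woman mean of
the two readings then feeds a per-completed-week summary table (n, mean,
SD, P10, P50, P90) — the growth chart from which tape boundaries are cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHART_COLUMNS = ["week", "n", "mean_cm", "sd_cm", "p10_cm", "p50_cm", "p90_cm"]

#: numpy quantile methods accepted for percentile estimation; "linear"
#: (interpolation between order statistics) is the default.
QUANTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint")


def mean_of_operators(uh_op1_cm: float, uh_op2_cm: float) -> float:
    """Per-woman uterine height: the arithmetic mean of the two readings.

    Missing readings are not imputed — both must be present.
    """
    if uh_op1_cm is None or uh_op2_cm is None:
        raise ValueError("both operator readings are required; no imputation")
    a, b = float(uh_op1_cm), float(uh_op2_cm)
    if np.isnan(a) or np.isnan(b):
        raise ValueError("both operator readings are required; no imputation")
    return (a + b) / 2.0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between the two operators (cm)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(pairs: pd.DataFrame) -> BlandAltmanResult:
    """Agreement between operators on op1 − op2 differences.

    ``pairs`` needs columns ``uh_op1_cm`` and ``uh_op2_cm``.  Limits of
    agreement are bias ± 1.96 × sample SD of the differences.  Swapping
    the operators flips the sign of the bias and limits but not their
    magnitude.
    """
    d = (pairs["uh_op1_cm"] - pairs["uh_op2_cm"]).to_numpy(dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs (SD undefined)")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=n
    )


@dataclass
class GrowthChart:
    """Per-completed-week uterine-height summary for one site."""

    site: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(CHART_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"growth chart table missing columns {sorted(missing)}")
        weeks = t["week"].to_numpy()
        if not (np.diff(weeks) == 1).all():
            raise ValueError("growth chart weeks must be contiguous and sorted")
        bad = t[(t["p10_cm"] > t["p50_cm"]) | (t["p50_cm"] > t["p90_cm"])]
        if not bad.empty:
            raise ValueError(
                f"percentile crossing at weeks {bad['week'].tolist()}: "
                "require p10 <= p50 <= p90"
            )

    @property
    def weeks(self) -> list[int]:
        return [int(w) for w in self.table["week"]]

    def percentile(self, week: int, p: int) -> float:
        """UH percentile value (cm) at a completed week; p in {10, 50, 90}."""
        row = self.table[self.table["week"] == week]
        if row.empty:
            raise KeyError(f"week {week} not in chart (has {self.weeks})")
        col = {10: "p10_cm", 50: "p50_cm", 90: "p90_cm"}.get(p)
        if col is None:
            raise ValueError(f"percentile must be 10, 50 or 90, got {p}")
        return float(row.iloc[0][col])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"site": self.site, "rows": self.table.to_dict(orient="records")}, indent=2
        )

    @classmethod
    def from_csv(cls, path, site: str = "") -> "GrowthChart":
        return cls(site=site, table=pd.read_csv(path))


def weekly_percentiles(
    pairs: pd.DataFrame,
    site: str = "",
    week_range: tuple[int, int] = (24, 36),
    quantile_method: str = "linear",
) -> GrowthChart:
    """Build a growth chart from phase-1 paired measurements.

    ``pairs`` needs columns ``ga_days``, ``uh_op1_cm``, ``uh_op2_cm``.
    Each woman contributes her mean-of-operators UH to the completed week
    floor(ga_days / 7); every week in ``week_range`` (inclusive) must hold
    at least two women.
    """
    if quantile_method not in QUANTILE_METHODS:
        raise ValueError(f"quantile_method must be one of {QUANTILE_METHODS}")
    mean_uh = (pairs["uh_op1_cm"] + pairs["uh_op2_cm"]).to_numpy(dtype=float) / 2.0
    week = (pairs["ga_days"].to_numpy(dtype=int) // 7).astype(int)
    lo, hi = week_range
    rows = []
    for w in range(lo, hi + 1):
        vals = mean_uh[week == w]
        if vals.size < 2:
            raise ValueError(f"week {w}: need >= 2 subjects, found {vals.size}")
        p10, p50, p90 = np.percentile(vals, [10, 50, 90], method=quantile_method)
        rows.append(
            {
                "week": w,
                "n": int(vals.size),
                "mean_cm": float(vals.mean()),
                "sd_cm": float(vals.std(ddof=1)),
                "p10_cm": float(p10),
                "p50_cm": float(p50),
                "p90_cm": float(p90),
            }
        )
    return GrowthChart(site=site, table=pd.DataFrame(rows, columns=CHART_COLUMNS))
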