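"""Synthetic phase-1 and phase-2 cohorts for the tape evaluation pipeline.

The study's raw measurements were never deposited, so this module
generates cohorts with the statistical structure the analysis assumes:

* uterine height (UH) grows roughly linearly with gestational age (GA),
  about 1 cm per week, around a per-woman level with a few cm of
  between-woman spread;
* two independent operators read the same woman with small measurement
  error, sized so that 95% of inter-operator differences fall within
  about 2–3 cm;
* phase 2 samples women by a stratified GA plan (heavier at the band
  edges) rather than by the natural GA distribution.

GA is handled internally in days.  Bands are half-open: with the "w.d"
notation, 23.6 weeks means 23 weeks 6 days, so the early band is
[140, 168) days, the preterm band [168, 252) and the term band [252, 287).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# three-band convention used by the accuracy analysis
BAND_EARLY = "20.0-23.6"
BAND_PRETERM = "24.0-35.6"
BAND_TERM = "36.0-40.6"
GA_BANDS_3 = (BAND_EARLY, BAND_PRETERM, BAND_TERM)

GA_MIN_DAYS = 140  # 20.0 weeks
GA_MAX_DAYS = 287  # exclusive; last eligible day is 40 weeks 6 days
_BAND_EDGES_3 = ((140, 168, BAND_EARLY), (168, 252, BAND_PRETERM), (252, 287, BAND_TERM))

# five-band enrollment strata (days, half-open) and the per-site targets
FIVE_BAND_EDGES = {
    "20.0-23.6": (140, 168),
    "24.0-27.6": (168, 196),
    "28.0-31.6": (196, 224),
    "32.0-35.6": (224, 252),
    "36.0-40.6": (252, 287),
}
DEFAULT_STRATUM_TARGETS = {
    "20.0-23.6": 50,
    "24.0-27.6": 10,
    "28.0-31.6": 20,
    "32.0-35.6": 70,
    "36.0-40.6": 100,
}

PHASE1_COLUMNS = ["subject_id", "ga_days", "uh_op1_cm", "uh_op2_cm"]
PHASE2_COLUMNS = ["subject_id", "ga_days", "uh_cm", "ga_band"]


def ga_to_band(ga_days: int) -> str:
    """Three-band GA label for the accuracy analysis (half-open bands)."""
    ga = int(ga_days)
    for lo, hi, label in _BAND_EDGES_3:
        if lo <= ga < hi:
            return label
    raise ValueError(
        f"gestational age {ga_days} days outside the eligibility window "
        f"[{GA_MIN_DAYS}, {GA_MAX_DAYS})"
    )


@dataclass(frozen=True)
class GrowthModelParams:
    """Linear growth model for uterine height over completed weeks.

    mean UH at completed week w is ``intercept + slope * w``; each woman
    deviates from it by N(0, between_woman_sd) and each operator reading
    adds independent N(0, operator_sd).  The defaults give 22.6 cm at 24
    weeks and 33.4 cm at 36 weeks (~1 cm/week growth) and 95% limits of
    inter-operator differences of 1.96·√2·0.9 ≈ 2.5 cm.
    """

    intercept: float = 1.0
    slope: float = 0.9
    between_woman_sd: float = 2.0
    operator_sd: float = 0.9
    site: str = "synthetic"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.between_woman_sd < 0 or self.operator_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def mean_uh(self, ga_days: np.ndarray | int) -> np.ndarray:
        week = np.asarray(ga_days, dtype=int) // 7
        return self.intercept + self.slope * week


@dataclass(frozen=True)
class SamplingPlan:
    """Stratified phase-2 enrollment targets per GA band (days, half-open)."""

    strata: dict = field(default_factory=lambda: dict(DEFAULT_STRATUM_TARGETS))

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("sampling plan needs at least one stratum")
        for band, n in self.strata.items():
            if band not in FIVE_BAND_EDGES:
                raise ValueError(f"unknown stratum {band!r}")
            lo, hi = FIVE_BAND_EDGES[band]
            if hi <= lo:
                raise ValueError(f"stratum {band!r} has empty day range")
            if n < 0:
                raise ValueError(f"stratum {band!r} target must be >= 0")

    @property
    def total(self) -> int:
        return int(sum(self.strata.values()))

    @property
    def preterm_total(self) -> int:
        return int(
            sum(
                n
                for band, n in self.strata.items()
                if ga_to_band(FIVE_BAND_EDGES[band][0]) == BAND_PRETERM
            )
        )


def simulate_phase1(
    params: GrowthModelParams | None = None,
    n_per_week: int = 40,
    week_range: tuple[int, int] = (24, 36),
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired-measurement cohort: ``n_per_week`` women per completed week.

    GA is drawn uniformly at day resolution within each week.  Each
    woman's true UH is the growth-model mean at her completed week plus
    N(0, between_woman_sd); each operator reading adds independent
    N(0, operator_sd).  Deterministic under a fixed seed.
    """
    params = params or GrowthModelParams()
    lo, hi = week_range
    if n_per_week < 1:
        raise ValueError("n_per_week must be >= 1")
    if not (0 < lo <= hi):
        raise ValueError(f"invalid week range {week_range}")
    rng = np.random.default_rng(seed)
    weeks = np.repeat(np.arange(lo, hi + 1), n_per_week)
    ga_days = weeks * 7 + rng.integers(0, 7, size=weeks.size)
    true_uh = params.mean_uh(ga_days) + rng.normal(0.0, params.between_woman_sd, weeks.size)
    op1 = true_uh + rng.normal(0.0, params.operator_sd, weeks.size)
    op2 = true_uh + rng.normal(0.0, params.operator_sd, weeks.size)
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, weeks.size + 1),
            "ga_days": ga_days.astype(int),
            "uh_op1_cm": op1,
            "uh_op2_cm": op2,
        },
        columns=PHASE1_COLUMNS,
    )


def simulate_phase2(
    params: GrowthModelParams | None = None,
    plan: SamplingPlan | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-measurement evaluation cohort following a stratified plan.

    GA is uniform at day resolution within each stratum; the one masked
    UH reading carries combined woman-level and operator noise
    (variances add).  Stratum counts match the plan exactly and the RNG
    stream is consumed stratum by stratum in plan order.
    """
    params = params or GrowthModelParams()
    plan = plan or SamplingPlan()
    rng = np.random.default_rng(seed)
    total_sd = float(np.hypot(params.between_woman_sd, params.operator_sd))
    frames = []
    offset = 0
    for band, n in plan.strata.items():
        lo, hi = FIVE_BAND_EDGES[band]
        ga_days = rng.integers(lo, hi, size=n)
        uh = params.mean_uh(ga_days) + rng.normal(0.0, total_sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.arange(offset + 1, offset + n + 1),
                    "ga_days": ga_days.astype(int),
                    "uh_cm": uh,
                }
            )
        )
        offset += n
    cohort = pd.concat(frames, ignore_index=True)
    cohort["ga_band"] = [ga_to_band(g) for g in cohort["ga_days"]]
    return cohort[PHASE2_COLUMNS]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
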