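"""Descriptive statistics and CLSI-style nonparametric reference intervals.

A reference interval is the central 95% range (2.5th-97.5th percentiles)
of a biomarker in a healthy reference population. Following the CLSI EP28
nonparametric convention, percentiles are estimated by rank interpolation
at rank ``r = p * (n + 1)``; partitions with fewer than 120 subjects are
flagged as below the guideline's minimum but still reported, since small
age strata are common in pilot reference studies. Medians come with
percentile-bootstrap confidence intervals, and two-group comparisons use
the Mann-Whitney U-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "MedianSummary",
    "ReferenceInterval",
    "StratumDefinition",
    "nonparametric_percentile",
    "reference_interval",
    "stratified_reference_intervals",
    "bootstrap_median_ci",
    "mann_whitney_u",
    "CLSI_MIN_N",
    "DEFAULT_STRATA",
]

logger = logging.getLogger(__name__)

#: Minimum reference subjects per partition under the CLSI EP28 guideline.
CLSI_MIN_N = 120


@dataclass(frozen=True)
class MedianSummary:
    """Sample median with a percentile-bootstrap confidence interval."""

    median: float
    ci_low: float
    ci_high: float
    level: float
    n: int
    bootstrap_reps: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("CI must bracket the median")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ReferenceInterval:
    """Nonparametric percentile bounds for one stratum."""

    stratum_label: str
    n: int
    lower: float
    upper: float
    lower_p: float = 0.025
    upper_p: float = 0.975
    meets_clsi_min_n: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        if self.meets_clsi_min_n != (self.n >= CLSI_MIN_N):
            raise ValueError("meets_clsi_min_n inconsistent with n")


@dataclass(frozen=True)
class StratumDefinition:
    """Half-open age stratum [age_low, age_high)."""

    label: str
    age_low: float
    age_high: float

    def __post_init__(self) -> None:
        if not self.age_low < self.age_high:
            raise ValueError(f"stratum {self.label!r}: age_low must be < age_high")

    def contains(self, ages: np.ndarray) -> np.ndarray:
        return (ages >= self.age_low) & (ages < self.age_high)


DEFAULT_STRATA = tuple(
    StratumDefinition(f"{lo}-{lo + 9}", lo, lo + 10) for lo in (20, 30, 40, 50, 60)
)


def nonparametric_percentile(values: Sequence[float], p: float) -> float:
    """Rank-interpolated order statistic at rank ``r = p*(n+1)``.

    This is the CLSI nonparametric percentile (numpy's ``weibull`` method);
    ranks below 1 or above n clamp to the extreme order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of empty sample is undefined")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    return float(np.quantile(values, p, method="weibull"))


def reference_interval(
    values: Sequence[float],
    stratum_label: str = "all",
    lower_p: float = 0.025,
    upper_p: float = 0.975,
) -> ReferenceInterval:
    """Central reference interval for one stratum.

    Never refuses small samples; the ``meets_clsi_min_n`` flag records
    whether the partition satisfies the n >= 120 guideline.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    return ReferenceInterval(
        stratum_label=stratum_label,
        n=n,
        lower=nonparametric_percentile(values, lower_p),
        upper=nonparametric_percentile(values, upper_p),
        lower_p=lower_p,
        upper_p=upper_p,
        meets_clsi_min_n=n >= CLSI_MIN_N,
    )


def bootstrap_median_ci(
    values: Sequence[float],
    level: float = 0.95,
    reps: int = 2000,
    seed: int = 0,
) -> MedianSummary:
    """Percentile-bootstrap CI of the sample median (deterministic per seed)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    resamples = rng.choice(values, size=(reps, values.size), replace=True)
    boot_medians = np.median(resamples, axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_medians, [alpha / 2, 1 - alpha / 2])
    med = float(np.median(values))
    # percentile-bootstrap bounds can sit on the sample median's far side
    # for tiny n; clamp so the summary invariant lo <= median <= hi holds
    return MedianSummary(
        median=med,
        ci_low=min(float(lo), med),
        ci_high=max(float(hi), med),
        level=level,
        n=values.size,
        bootstrap_reps=reps,
        seed=seed,
    )


def stratified_reference_intervals(
    cohort: Cohort,
    strata: Sequence[StratumDefinition] = DEFAULT_STRATA,
    lower_p: float = 0.025,
    upper_p: float = 0.975,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> tuple[list[ReferenceInterval], list[MedianSummary]]:
    """One reference interval and one median summary per age stratum.

    Strata must be non-overlapping. Empty strata are omitted with a logged
    warning; subjects outside all strata are counted and logged, never
    silently dropped.
    """
    strata = list(strata)
    for i, a in enumerate(strata):
        for b in strata[i + 1 :]:
            if a.age_low < b.age_high and b.age_low < a.age_high:
                raise ValueError(f"strata {a.label!r} and {b.label!r} overlap")

    ages = cohort.data["age_years"].to_numpy()
    values = cohort.data["snfl_pg_ml"].to_numpy()
    covered = np.zeros(len(ages), dtype=bool)
    intervals: list[ReferenceInterval] = []
    medians: list[MedianSummary] = []
    for stratum in strata:
        mask = stratum.contains(ages)
        covered |= mask
        if not mask.any():
            logger.warning("stratum %s is empty; no interval estimated", stratum.label)
            continue
        vals = values[mask]
        intervals.append(reference_interval(vals, stratum.label, lower_p, upper_p))
        medians.append(bootstrap_median_ci(vals, reps=bootstrap_reps, seed=seed))
    n_outside = int((~covered).sum())
    if n_outside:
        logger.warning("%d subjects fall outside all strata and were not summarized", n_outside)
    return intervals, medians


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U-test.

    Uses the exact permutation null when ``min(n_x, n_y) <= 8`` and there
    are no ties across the pooled sample; otherwise the tie-corrected normal
    approximation with continuity correction. Returns ``U`` (for the first
    sample), the two-sided p-value, and which method was used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return {
        "U": float(res.statistic),
        "p_two_sided": min(1.0, float(res.pvalue)),
        "method": "exact" if exact else "normal_approx",
    }
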