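"""Coverage of focal conservation areas per feature, random baseline, and
equal-area comparison against a multi-species prioritization.

The central question: how much of each species' distribution falls inside a
focal region (e.g. areas designated for a single umbrella species), is that
more than the area-proportional expectation under randomly placed protection,
and how does it compare with what an equal-area complementarity-based
prioritization could cover?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    EmptyLandscapeError,
    GridMismatchError,
    InvalidComparisonError,
    InvalidParameterError,
    MissingLabelError,
)
from .grids import NormalizedFeature, RegionMask
from .prioritizer import RankMap, coverage_at_fraction

__all__ = [
    "CoverageRecord",
    "PairedTestResult",
    "overlap_fraction",
    "random_baseline",
    "coverage_vs_random",
    "equal_area_comparison",
    "paired_t",
    "group_summary",
]


@dataclass(frozen=True)
class CoverageRecord:
    feature_id: str
    species_id: str
    season_tag: str
    overlap: float
    baseline: float
    above_baseline: bool


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test summary with a 95% confidence interval."""

    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    ci_low: float
    ci_high: float
    n_pairs: int


def overlap_fraction(feature: NormalizedFeature, region: RegionMask) -> float:
    """Proportion of the feature's distribution inside the region: sum of q_ji over region cells."""
    if not feature.grid.aligned_with(region.grid):
        raise GridMismatchError("feature and region are not on the same grid")
    return float(feature.q[region.member].sum())


def random_baseline(region: RegionMask, analysis: RegionMask) -> float:
    """Expected overlap under uniformly random placement of protection.

    This is simply the region's share of analysis cells, |region|/|analysis|:
    the analytic expectation of :func:`overlap_fraction` for a feature placed
    uniformly at random. Cells of the region outside the analysis mask are
    not counted.
    """
    if not region.grid.aligned_with(analysis.grid):
        raise GridMismatchError("region and analysis mask are not on the same grid")
    n_analysis = analysis.n_cells
    if n_analysis == 0:
        raise EmptyLandscapeError("analysis mask is empty")
    n_region = int((region.member & analysis.member).sum())
    return n_region / n_analysis


def coverage_vs_random(
    features: list[NormalizedFeature],
    region: RegionMask,
    analysis: RegionMask,
) -> tuple[list[CoverageRecord], dict]:
    """Per-feature overlap vs the shared random baseline, plus tallies.

    A feature counts as better-than-random only with strictly greater
    overlap than the baseline. The summary counts both conservation features
    and species, a species being above baseline when at least one of its
    seasonal features is.
    """
    if not features:
        raise InvalidParameterError("at least one feature is required")
    baseline = random_baseline(region, analysis)
    records = [
        CoverageRecord(
            feature_id=f.feature_id,
            species_id=f.species_id,
            season_tag=f.season_tag,
            overlap=(ov := overlap_fraction(f, region)),
            baseline=baseline,
            above_baseline=ov > baseline,
        )
        for f in features
    ]
    species_above: dict[str, bool] = {}
    for r in records:
        species_above[r.species_id] = species_above.get(r.species_id, False) or r.above_baseline
    n_feat = len(records)
    n_feat_above = sum(r.above_baseline for r in records)
    n_sp = len(species_above)
    n_sp_above = sum(species_above.values())
    summary = {
        "baseline": baseline,
        "mean_overlap": float(np.mean([r.overlap for r in records])),
        "median_overlap": float(np.median([r.overlap for r in records])),
        "n_features": n_feat,
        "n_features_above": n_feat_above,
        "fraction_features_above": n_feat_above / n_feat,
        "n_species": n_sp,
        "n_species_above": n_sp_above,
        "fraction_species_above": n_sp_above / n_sp,
    }
    return records, summary


def records_to_frame(records: list[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.species_id, r.season_tag, r.overlap, r.baseline, r.above_baseline)
            for r in records
        ],
        columns=["feature_id", "species_id", "season", "overlap", "baseline", "above_baseline"],
    )


def paired_t(x, y) -> PairedTestResult:
    """Paired t-test of mean(x - y) = 0, two-sided, with 95% CI.

    t = mean(d) / (sd(d)/sqrt(n)) on n-1 degrees of freedom, d = x - y.
    A zero-variance difference vector yields t = 0, p = 1 when the mean is
    also zero (identical vectors), and is an error otherwise: the t statistic
    is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise InvalidParameterError("paired t-test needs at least 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d != 0.0:
            raise DegenerateTestError("zero-variance differences with non-zero mean")
        return PairedTestResult(0.0, 0.0, df, 1.0, 0.0, 0.0, n)
    se = sd_d / np.sqrt(n)
    t_stat = mean_d / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    t_crit = float(stats.t.ppf(0.975, df))
    return PairedTestResult(
        mean_difference=mean_d,
        t_statistic=float(t_stat),
        degrees_of_freedom=df,
        p_value=p,
        ci_low=mean_d - t_crit * se,
        ci_high=mean_d + t_crit * se,
        n_pairs=n,
    )


def equal_area_comparison(
    features: list[NormalizedFeature],
    current_region: RegionMask,
    rank_map: RankMap,
    fraction: float | None = None,
) -> tuple[pd.DataFrame, PairedTestResult]:
    """Current coverage vs coverage achievable in an equal-area prioritization.

    ``current_region`` is the existing protection (focal areas plus protected
    areas); the comparison takes the prioritization's top-ranked cells at the
    same landscape fraction and asks, per feature, how much distribution each
    strategy covers. The paired t-test is on (prioritized - current).
    """
    analysis = rank_map.analysis_mask
    region_fraction = random_baseline(current_region, analysis)
    if fraction is None:
        fraction = region_fraction
    elif abs(fraction - region_fraction) > 1e-6:
        raise InvalidComparisonError(
            f"requested fraction {fraction} != region fraction {region_fraction}"
        )
    current = np.array([overlap_fraction(f, current_region) for f in features])
    prioritized = coverage_at_fraction(rank_map, fraction, features)
    test = paired_t(prioritized, current)
    frame = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "current_coverage": current,
            "prioritized_coverage": prioritized,
            "difference": prioritized - current,
        }
    )
    return frame, test


def group_summary(records: list[CoverageRecord], groups: dict[str, str]) -> dict[str, float]:
    """Median overlap per group (e.g. taxon or season), mean-of-middle for even sizes."""
    values: dict[str, list[float]] = {}
    for r in records:
        if r.feature_id not in groups:
            raise MissingLabelError(f"feature {r.feature_id!r} has no group label")
        values.setdefault(groups[r.feature_id], []).append(r.overlap)
    return {g: float(np.median(v)) for g, v in values.items()}
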