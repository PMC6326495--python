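"""Threat masks and exposure of species distributions inside vs outside focal areas.

Two threat kinds are modelled the same way, as boolean masks over habitat
cells: forecast land-use/land-cover (LULC) conversion under one or more
future scenarios, and invasion risk (cells classed as low resistance and
resilience are the high-risk ones). Every threat applies to every feature —
the working assumption is that all habitat-associated species are affected
by direct habitat loss.

Exposure of a feature is reported two ways: over the whole study region
(the proportion of its distribution on threatened cells) and conditionally
inside the focal region (threatened share of its within-focal mass), which
makes the two numbers directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import PairedTestResult, paired_t
from .errors import (
    DegenerateTestError,
    GridMismatchError,
    InvalidClassError,
    InvalidParameterError,
)
from .grids import Grid, NormalizedFeature, RawLayer, RegionMask

__all__ = [
    "ThreatMask",
    "ExposureRecord",
    "lulc_threat_mask",
    "cheatgrass_risk_mask",
    "exposure",
    "landscape_exposure",
    "scenario_summary",
    "evaluate_threats",
]

#: resistance/resilience class codes: low R&R = high invasion risk
RR_LOW, RR_MODERATE, RR_HIGH = 1, 2, 3


@dataclass
class ThreatMask:
    """Boolean per-cell threat layer for one scenario."""

    grid: Grid
    threatened: np.ndarray
    threat_id: str
    scenario_id: str

    def __post_init__(self) -> None:
        self.threatened = np.asarray(self.threatened, dtype=bool)
        if self.threatened.shape != self.grid.shape:
            raise GridMismatchError("threat mask shape does not match grid")


@dataclass(frozen=True)
class ExposureRecord:
    feature_id: str
    threat_id: str
    scenario_id: str
    exposure_region: float
    exposure_focal: float  # NaN when the feature has no mass in the focal region
    focal_defined: bool


def lulc_threat_mask(
    baseline: RawLayer,
    future: RawLayer,
    threat_classes,
    analysis: RegionMask,
    scenario_id: str = "",
) -> ThreatMask:
    """Cells of current habitat forecast to convert to a threatening class.

    A habitat cell (analysis-mask member at baseline) is threatened exactly
    when its future land-cover class is in ``threat_classes`` (cropland,
    urban, mining, encroaching forest, ...). The baseline layer is only
    checked for alignment: habitat membership at baseline is what the
    analysis mask encodes.
    """
    if not (baseline.grid.aligned_with(future.grid) and future.grid.aligned_with(analysis.grid)):
        raise GridMismatchError("LULC layers and analysis mask are not on the same grid")
    future_vals = np.where(future.nodata_mask(), np.nan, future.values)
    threatened = analysis.member & np.isin(future_vals, list(threat_classes))
    return ThreatMask(analysis.grid, threatened, threat_id="lulc", scenario_id=scenario_id)


def cheatgrass_risk_mask(
    rr_class: RawLayer,
    analysis: RegionMask,
    scenario_id: str = "cheatgrass",
) -> ThreatMask:
    """High invasion risk: habitat cells classed as low resistance/resilience."""
    if not rr_class.grid.aligned_with(analysis.grid):
        raise GridMismatchError("risk-class layer and analysis mask are not on the same grid")
    vals = rr_class.values
    valid = ~rr_class.nodata_mask()
    known = np.isin(vals, [RR_LOW, RR_MODERATE, RR_HIGH])
    if np.any(valid & ~known):
        bad = np.unique(vals[valid & ~known])
        raise InvalidClassError(f"unknown resistance/resilience class codes: {bad.tolist()}")
    threatened = analysis.member & valid & (vals == RR_LOW)
    return ThreatMask(analysis.grid, threatened, threat_id="cheatgrass", scenario_id=scenario_id)


def exposure(
    feature: NormalizedFeature,
    threat: ThreatMask,
    focal: RegionMask,
) -> ExposureRecord:
    """Threatened proportion of one feature, region-wide and inside the focal area.

    exposure_region = sum of q over threatened cells; exposure_focal =
    threatened share of the feature's within-focal mass. A feature with zero
    mass inside the focal region gets exposure_focal = NaN and is excluded
    from paired tests downstream.
    """
    if not (feature.grid.aligned_with(threat.grid) and threat.grid.aligned_with(focal.grid)):
        raise GridMismatchError("feature, threat and focal mask are not on the same grid")
    q = feature.q
    exp_region = float(q[threat.threatened].sum())
    focal_mass = float(q[focal.member].sum())
    if focal_mass > 0:
        exp_focal = float(q[threat.threatened & focal.member].sum()) / focal_mass
        defined = True
    else:
        exp_focal, defined = float("nan"), False
    return ExposureRecord(
        feature_id=feature.feature_id,
        threat_id=threat.threat_id,
        scenario_id=threat.scenario_id,
        exposure_region=exp_region,
        exposure_focal=exp_focal,
        focal_defined=defined,
    )


def landscape_exposure(
    threat: ThreatMask, focal: RegionMask, analysis: RegionMask
) -> tuple[float, float]:
    """(threatened fraction of focal habitat area, threatened fraction of all habitat area)."""
    if not (threat.grid.aligned_with(focal.grid) and focal.grid.aligned_with(analysis.grid)):
        raise GridMismatchError("threat, focal and analysis masks are not on the same grid")
    n_analysis = int(analysis.member.sum())
    n_focal = int((focal.member & analysis.member).sum())
    if n_analysis == 0 or n_focal == 0:
        raise InvalidParameterError("analysis and focal masks must be non-empty")
    thr = threat.threatened & analysis.member
    inside = int((thr & focal.member).sum()) / n_focal
    region = int(thr.sum()) / n_analysis
    return inside, region


def records_to_frame(records: list[ExposureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.threat_id, r.scenario_id, r.exposure_region,
             r.exposure_focal, r.focal_defined)
            for r in records
        ],
        columns=["feature_id", "threat_id", "scenario_id", "exposure_region",
                 "exposure_focal", "focal_defined"],
    )


def scenario_summary(
    records: list[ExposureRecord],
    landscape_exposures: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Summarize exposure records across scenarios and features.

    Per scenario: mean exposure inside the focal region and region-wide over
    features. Feature-level paired t-test: each feature's scenario-averaged
    exposure_focal vs exposure_region (features with undefined focal exposure
    in any scenario are excluded; df = n_features - 1). When
    ``landscape_exposures`` maps scenario_id -> (inside, region) habitat-area
    fractions, a scenario-level paired test (df = n_scenarios - 1) and
    mean +/- SE across scenarios are reported as well.
    """
    if not records:
        raise InvalidParameterError("no exposure records")
    df = records_to_frame(records)

    per_scenario = (
        df.groupby("scenario_id")
        .agg(
            mean_exposure_focal=("exposure_focal", "mean"),
            mean_exposure_region=("exposure_region", "mean"),
            n_features=("feature_id", "count"),
        )
        .to_dict(orient="index")
    )

    # feature-level test on scenario-averaged exposures
    defined = df.groupby("feature_id")["focal_defined"].all()
    usable = defined[defined].index
    sub = df[df.feature_id.isin(usable)]
    by_feature = sub.groupby("feature_id")[["exposure_focal", "exposure_region"]].mean()
    feature_test: PairedTestResult | None = None
    if len(by_feature) >= 2:
        try:
            feature_test = paired_t(
                by_feature["exposure_focal"].to_numpy(),
                by_feature["exposure_region"].to_numpy(),
            )
        except DegenerateTestError:
            feature_test = None  # constant non-zero difference: t undefined

    out = {
        "per_scenario": per_scenario,
        "mean_exposure_focal": float(by_feature["exposure_focal"].mean()),
        "mean_exposure_region": float(by_feature["exposure_region"].mean()),
        "feature_test": feature_test,
        "n_features_tested": int(len(by_feature)),
    }

    if landscape_exposures is not None and len(landscape_exposures) >= 1:
        inside = np.array([v[0] for v in landscape_exposures.values()])
        region = np.array([v[1] for v in landscape_exposures.values()])
        out["landscape_inside_mean"] = float(inside.mean())
        out["landscape_region_mean"] = float(region.mean())
        if inside.size >= 2:
            out["landscape_inside_se"] = float(inside.std(ddof=1) / np.sqrt(inside.size))
            out["landscape_region_se"] = float(region.std(ddof=1) / np.sqrt(region.size))
            try:
                out["landscape_test"] = paired_t(region, inside)
            except DegenerateTestError:
                out["landscape_test"] = None
        else:
            out["landscape_inside_se"] = 0.0
            out["landscape_region_se"] = 0.0
            out["landscape_test"] = None
    return out


def evaluate_threats(
    features: list[NormalizedFeature],
    threats: list[ThreatMask],
    focal: RegionMask,
    analysis: RegionMask,
) -> tuple[list[ExposureRecord], dict]:
    """Compute all exposure records for one threat kind and summarize them."""
    if not threats:
        raise InvalidParameterError("no threat masks")
    records = [exposure(f, t, focal) for t in threats for f in features]
    landscape = {t.scenario_id: landscape_exposure(t, focal, analysis) for t in threats}
    return records, scenario_summary(records, landscape)
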