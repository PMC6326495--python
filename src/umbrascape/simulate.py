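"""Synthetic landscapes with the statistical structure the analysis assumes.

The generator emulates the input stack of a real umbrella-species study:
spatially autocorrelated species distributions with a controllable range-size
spectrum and a controllable association with one "umbrella" species' habitat
field; focal areas drawn as the top-quantile patches of that umbrella field
(the analogue of priority areas delineated for the umbrella species);
randomly placed protected areas; classed land-cover layers whose exclusions
define the habitat (analysis) mask; and per-scenario future land-cover and
invasion-risk layers whose placement can be biased toward or away from the
focal areas.

Construction is deliberately simple — white noise convolved with a Gaussian
kernel, blended with the umbrella field, thresholded at a range-size
quantile — a statistical stand-in that produces contiguous ranges, nested
rarity and umbrella co-distribution, not an ecological model. Every
generator is a pure function of (config, seed), and a :class:`SimTruth`
records the planted structure for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyFeatureError, InvalidParameterError
from .grids import (
    Grid,
    LandscapeStack,
    RawLayer,
    RegionMask,
    apply_exclusions,
    normalize_feature,
)
from .threats import ThreatMask, cheatgrass_risk_mask, lulc_threat_mask

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "gen_species",
    "gen_focal_areas",
    "gen_protected_areas",
    "gen_threats",
    "simulate_landscape",
    "LULC_SCENARIO_IDS",
]

log = logging.getLogger(__name__)

# land-cover class codes
CLASS_SHRUB, CLASS_FOREST, CLASS_WATER, CLASS_CROP, CLASS_DEVELOPED = 1, 2, 3, 4, 5
EXCLUDED_CLASSES = frozenset({CLASS_FOREST, CLASS_WATER, CLASS_CROP, CLASS_DEVELOPED})
#: future classes that threaten habitat: cropland/urban-mining expansion, forest encroachment
THREAT_CLASSES = frozenset({CLASS_FOREST, CLASS_CROP, CLASS_DEVELOPED})

LULC_SCENARIO_IDS = ("A1B", "A2", "B1", "B2")

# rng stream tags so each generator draws independently of the others
_STREAM_SPECIES, _STREAM_FOCAL, _STREAM_PROTECTED = 1, 2, 3
_STREAM_LANDCOVER, _STREAM_THREATS = 4, 5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic landscape.

    Defaults mirror the real system the generator emulates: 81 species of
    which 10 contribute paired summer/winter distributions (91 conservation
    features), 21 summer-only; focal areas over 23.3% of habitat; protected
    areas at 15.6% so the expected focal+protected union is about 35.3%;
    four future land-cover scenarios converting 11.5% of habitat; invasion
    risk over 23.9%; threats biased one smoothed-field standard deviation
    away from the focal areas.
    """

    n_rows: int = 96
    n_cols: int = 96
    n_species: int = 81
    n_seasonal_species: int = 10  # paired summer + winter features
    n_summer_only: int = 21
    n_abundance_species: int = 3  # continuous (abundance) rather than binary layers
    range_size_bounds: tuple[float, float] = (0.01, 0.6)  # log-uniform occupied fraction
    autocorr_length: float = 4.0  # Gaussian kernel sigma, in cells
    umbrella_assoc: tuple[float, ...] | None = None  # per-species, in [-1, 1]
    assoc_bounds: tuple[float, float] = (-0.2, 0.9)  # drawn when umbrella_assoc is None
    exclude_fraction: float = 0.10  # non-habitat share of the grid
    focal_fraction: float = 0.233
    protected_fraction: float = 0.156
    threat_fraction: float = 0.115  # LULC conversion share of habitat, per scenario
    cheatgrass_fraction: float = 0.239
    threat_bias: float = -1.0  # in smoothed-field SD units; negative = away from focal
    n_lulc_scenarios: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InvalidParameterError("n_species must be >= 1")
        if self.n_seasonal_species + self.n_summer_only > self.n_species:
            raise InvalidParameterError("seasonal + summer-only species exceed n_species")
        for name in ("focal_fraction", "protected_fraction", "threat_fraction",
                     "cheatgrass_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidParameterError(f"{name} must be in (0,1), got {v}")
        if not (0 <= self.exclude_fraction < 1):
            raise InvalidParameterError("exclude_fraction must be in [0,1)")
        lo, hi = self.range_size_bounds
        if not (0 < lo <= hi < 1):
            raise InvalidParameterError("range_size_bounds must satisfy 0 < lo <= hi < 1")
        if self.umbrella_assoc is not None:
            if len(self.umbrella_assoc) != self.n_species:
                raise InvalidParameterError("umbrella_assoc must have one value per species")
            if any(abs(a) > 1 for a in self.umbrella_assoc):
                raise InvalidParameterError("umbrella_assoc values must be in [-1, 1]")

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, cell_size=270.0, crs_tag="synthetic-aea")

    @property
    def n_features(self) -> int:
        return self.n_species + self.n_seasonal_species


@dataclass
class SimTruth:
    """Planted structure of one simulated landscape, for recovery tests."""

    features: pd.DataFrame  # feature_id, species_id, season_tag, umbrella_assoc, ...
    scenario_threat_bias: dict[str, float]
    realized_focal_fraction: float = float("nan")
    seed: int = 0


@dataclass
class SimResult:
    """Fully assembled synthetic input set."""

    stack: LandscapeStack
    umbrella: RawLayer
    landcover_baseline: RawLayer
    landcover_futures: list[RawLayer]
    lulc_threats: list[ThreatMask]
    cheatgrass_threat: ThreatMask
    rr_class: RawLayer
    raw_species_layers: list[RawLayer]
    truth: SimTruth

    @property
    def all_threats(self) -> list[ThreatMask]:
        return [*self.lulc_threats, self.cheatgrass_threat]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise, mean 0 / SD 1."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = f.std()
    if sd == 0:  # sigma so large the field is flat
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _top_fraction_mask(
    score: np.ndarray, fraction: float, within: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of the top-`fraction` scoring cells inside `within`.

    Exact cell count (rounded), ties broken by a seeded shuffle so degenerate
    flat score fields still yield the target fraction.
    """
    idx = np.flatnonzero(within.ravel())
    n_take = int(round(fraction * idx.size))
    vals = score.ravel()[idx]
    jitter = rng.permutation(idx.size)  # deterministic tie-break
    order = np.lexsort((jitter, -vals))
    chosen = idx[order[:n_take]]
    out = np.zeros(score.size, dtype=bool)
    out[chosen] = True
    return out.reshape(score.shape)


def _feature_plan(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign species ids, seasons, associations and range-size targets."""
    n = config.n_species
    if config.umbrella_assoc is not None:
        assoc = np.asarray(config.umbrella_assoc, dtype=float)
    else:
        lo, hi = config.assoc_bounds
        assoc = rng.uniform(lo, hi, size=n)
    lo, hi = config.range_size_bounds
    rows = []
    n_year_round = n - config.n_summer_only - config.n_seasonal_species
    for k in range(n):
        sp = f"sp{k:03d}"
        kind = "abundance" if k < config.n_abundance_species else "binary"
        if k < n_year_round:
            seasons = ["year_round"]
        elif k < n_year_round + config.n_summer_only:
            seasons = ["summer"]
        else:
            seasons = ["summer", "winter"]
        for season in seasons:
            target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            fid = sp if seasons == ["year_round"] else f"{sp}_{season}"
            rows.append((fid, sp, season, float(assoc[k]), target, kind))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "species_id", "season_tag", "umbrella_assoc",
                 "range_target", "kind"],
    )


def gen_species(
    config: SimConfig, seed: int | None = None
) -> tuple[list[RawLayer], RawLayer, SimTruth]:
    """Generate the umbrella field and all species distribution layers.

    Each species field is ``a * U + sqrt(1 - a^2) * E`` — umbrella field U,
    independent smoothed noise E, association a — thresholded at its drawn
    range-size quantile to binary presence (the first few species are left
    continuous above the threshold, emulating abundance models). Winter
    layers of seasonal species use a spatially shifted copy of the species
    field, giving partially offset seasonal ranges.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_SPECIES])
    grid = config.grid
    shape = grid.shape
    sigma = config.autocorr_length

    umbrella_field = _smooth_field(rng, shape, sigma)
    plan = _feature_plan(config, rng)

    noise_by_species: dict[str, np.ndarray] = {}
    layers: list[RawLayer] = []
    realized = []
    offset = max(1, int(round(2 * sigma)))
    for row in plan.itertuples(index=False):
        if row.species_id not in noise_by_species:
            noise_by_species[row.species_id] = _smooth_field(rng, shape, sigma)
        e = noise_by_species[row.species_id]
        a = row.umbrella_assoc
        f = a * umbrella_field + np.sqrt(max(0.0, 1 - a * a)) * e
        if row.season_tag == "winter":
            f = np.roll(f, (offset, offset), axis=(0, 1))
        target = row.range_target
        occupied, thresh = _threshold_to_fraction(f, target)
        if not occupied.any():
            # flat or pathological field: fall back to the largest allowed range
            log.warning("feature %s empty after thresholding; widening quantile", row.feature_id)
            occupied, thresh = _threshold_to_fraction(f, config.range_size_bounds[1])
        if row.kind == "abundance":
            values = np.where(occupied, f - thresh + np.ptp(f[occupied]) * 0.05 + 1e-6, 0.0)
        else:
            values = occupied.astype(float)
        layers.append(RawLayer(grid, values, layer_id=row.feature_id))
        realized.append(occupied.mean())

    plan = plan.assign(occupied_fraction=realized)
    truth = SimTruth(
        features=plan,
        scenario_threat_bias={},
        seed=seed,
    )
    umbrella = RawLayer(grid, umbrella_field, layer_id="umbrella")
    return layers, umbrella, truth


def _threshold_to_fraction(f: np.ndarray, fraction: float) -> tuple[np.ndarray, float]:
    thresh = float(np.quantile(f, 1.0 - fraction))
    occupied = f >= thresh
    return occupied, thresh


def gen_focal_areas(
    umbrella: RawLayer,
    focal_fraction: float,
    seed: int,
    analysis: RegionMask | None = None,
    smooth_sigma: float = 2.0,
) -> RegionMask:
    """Focal region: top-quantile patches of the (smoothed) umbrella layer.

    Smoothing before thresholding biases the mask toward contiguous patches.
    The realized fraction of analysis cells is exact to one cell (well within
    the documented ±0.01 tolerance).
    """
    if not (0 < focal_fraction < 1):
        raise InvalidParameterError(f"focal_fraction must be in (0,1), got {focal_fraction}")
    rng = np.random.default_rng([seed, _STREAM_FOCAL])
    within = analysis.member if analysis is not None else np.ones(umbrella.grid.shape, bool)
    score = ndimage.gaussian_filter(umbrella.values, sigma=smooth_sigma, mode="wrap")
    member = _top_fraction_mask(score, focal_fraction, within, rng)
    return RegionMask(umbrella.grid, member, mask_id="focal")


def gen_protected_areas(
    grid: Grid,
    protected_fraction: float,
    seed: int,
    analysis: RegionMask | None = None,
    autocorr_length: float = 4.0,
) -> RegionMask:
    """Protected areas: top quantile of an independent smoothed random field.

    Placement is independent of the umbrella layer, and overlap with focal
    areas is allowed (protection and focal designation are distinct things).
    """
    if not (0 < protected_fraction < 1):
        raise InvalidParameterError(
            f"protected_fraction must be in (0,1), got {protected_fraction}"
        )
    rng = np.random.default_rng([seed, _STREAM_PROTECTED])
    within = analysis.member if analysis is not None else np.ones(grid.shape, bool)
    score = _smooth_field(rng, grid.shape, autocorr_length)
    member = _top_fraction_mask(score, protected_fraction, within, rng)
    return RegionMask(grid, member, mask_id="protected")


def _gen_baseline_landcover(config: SimConfig, rng: np.random.Generator) -> RawLayer:
    """Classed baseline land cover; excluded classes carve out non-habitat."""
    grid = config.grid
    field = _smooth_field(rng, grid.shape, config.autocorr_length)
    classes = np.full(grid.shape, CLASS_SHRUB, dtype=float)
    if config.exclude_fraction > 0:
        excluded = field >= np.quantile(field, 1 - config.exclude_fraction)
        sub = _smooth_field(rng, grid.shape, config.autocorr_length)
        qs = np.quantile(sub[excluded], [0.25, 0.5, 0.75]) if excluded.any() else [0, 0, 0]
        codes = np.digitize(sub, qs) + CLASS_FOREST  # forest/water/crop/developed
        classes[excluded] = codes[excluded]
    return RawLayer(grid, classes, layer_id="landcover_baseline")


def gen_threats(
    config: SimConfig,
    focal: RegionMask,
    seed: int | None = None,
    baseline: RawLayer | None = None,
    analysis: RegionMask | None = None,
) -> tuple[list[RawLayer], list[ThreatMask], RawLayer, ThreatMask, dict[str, float]]:
    """Future land-cover scenarios and the invasion-risk class layer.

    Per scenario, a smoothed random risk field is shifted by
    ``threat_bias x focal membership`` (bias in field-SD units) and the top
    ``threat_fraction`` of habitat cells convert to a threatening class;
    negative bias therefore puts conversion preferentially outside the focal
    region. Invasion risk works the same way at ``cheatgrass_fraction``, with
    the top cells classed low resistance/resilience (= high risk).

    Returns (future land-cover layers, LULC threat masks, risk-class layer,
    invasion threat mask, per-scenario bias record).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_THREATS])
    grid = config.grid
    if baseline is None:
        baseline = _gen_baseline_landcover(
            config, np.random.default_rng([seed, _STREAM_LANDCOVER])
        )
    if analysis is None:
        analysis = apply_exclusions(baseline, EXCLUDED_CLASSES)

    focal_ind = focal.member.astype(float)
    futures: list[RawLayer] = []
    lulc_masks: list[ThreatMask] = []
    biases: dict[str, float] = {}
    scenario_ids = [
        LULC_SCENARIO_IDS[s] if s < len(LULC_SCENARIO_IDS) else f"S{s}"
        for s in range(config.n_lulc_scenarios)
    ]
    threat_codes = np.array([CLASS_CROP, CLASS_DEVELOPED, CLASS_FOREST])
    for sid in scenario_ids:
        risk = _smooth_field(rng, grid.shape, config.autocorr_length) + \
            config.threat_bias * focal_ind
        convert = _top_fraction_mask(risk, config.threat_fraction, analysis.member, rng)
        future_vals = baseline.values.copy()
        future_vals[convert] = rng.choice(threat_codes, size=int(convert.sum()))
        future = RawLayer(grid, future_vals, layer_id=f"landcover_{sid}")
        futures.append(future)
        lulc_masks.append(
            lulc_threat_mask(baseline, future, THREAT_CLASSES, analysis, scenario_id=sid)
        )
        biases[sid] = config.threat_bias

    risk = _smooth_field(rng, grid.shape, config.autocorr_length) + \
        config.threat_bias * focal_ind
    low = _top_fraction_mask(risk, config.cheatgrass_fraction, analysis.member, rng)
    rr_vals = np.where(low, 1.0, np.where(risk >= np.median(risk), 2.0, 3.0))
    rr_class = RawLayer(grid, rr_vals, layer_id="rr_class")
    cheat_mask = cheatgrass_risk_mask(rr_class, analysis)
    biases["cheatgrass"] = config.threat_bias
    return futures, lulc_masks, rr_class, cheat_mask, biases


def simulate_landscape(config: SimConfig, seed: int | None = None) -> SimResult:
    """Generate the full input set: stack, masks, threats and planted truth."""
    seed = config.seed if seed is None else seed
    baseline = _gen_baseline_landcover(config, np.random.default_rng([seed, _STREAM_LANDCOVER]))
    analysis = apply_exclusions(baseline, EXCLUDED_CLASSES)
    layers, umbrella, truth = gen_species(config, seed)
    focal = gen_focal_areas(umbrella, config.focal_fraction, seed, analysis)
    protected = gen_protected_areas(
        config.grid, config.protected_fraction, seed, analysis, config.autocorr_length
    )
    futures, lulc_masks, rr_class, cheat_mask, biases = gen_threats(
        config, focal, seed, baseline, analysis
    )

    features = []
    kept_rows = []
    for layer, row in zip(layers, truth.features.itertuples(index=False)):
        try:
            features.append(
                normalize_feature(
                    layer, analysis,
                    feature_id=row.feature_id,
                    season_tag=row.season_tag,
                    species_id=row.species_id,
                )
            )
            kept_rows.append(True)
        except EmptyFeatureError:
            log.warning("dropping feature %s: no mass on the analysis mask", row.feature_id)
            kept_rows.append(False)

    truth.features = truth.features[np.asarray(kept_rows)].reset_index(drop=True)
    truth.scenario_threat_bias = biases
    truth.realized_focal_fraction = focal.n_cells / analysis.n_cells

    stack = LandscapeStack(
        grid=config.grid,
        features=features,
        analysis_mask=analysis,
        focal_mask=focal,
        protected_mask=protected,
    )
    return SimResult(
        stack=stack,
        umbrella=umbrella,
        landcover_baseline=baseline,
        landcover_futures=futures,
        lulc_threats=lulc_masks,
        cheatgrass_threat=cheat_mask,
        rr_class=rr_class,
        raw_species_layers=layers,
        truth=truth,
    )
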