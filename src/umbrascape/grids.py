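"""Grid data model: aligned raster layers, masks, features and the landscape stack.

Every layer in one analysis lives on a single :class:`Grid` — same shape, cell
size, origin and CRS tag. Cells are addressed by 0-based row-major linear
index (``i = row * n_cols + col``); all proportions are computed over the
cells of the analysis mask only.

A species distribution enters the prioritizer as a :class:`NormalizedFeature`:
the per-cell proportion ``q_ji`` of the feature's full distribution, summing
to one over analysis cells. Binary presence layers therefore normalize to a
uniform weight over occupied cells, while abundance layers weight cells by
abundance — a single representation covers both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import (
    EmptyFeatureError,
    GridMismatchError,
    InvalidParameterError,
)

__all__ = [
    "Grid",
    "RawLayer",
    "RegionMask",
    "NormalizedFeature",
    "LandscapeStack",
    "aggregate_max",
    "apply_exclusions",
    "normalize_feature",
    "select_features",
]

#: sum-to-one tolerance for normalized features
NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class Grid:
    """Geometry shared by all layers of one analysis.

    Parameters
    ----------
    n_rows, n_cols : int
        Raster shape; at least one cell.
    cell_size : float
        Edge length of a (square) cell in map units.
    origin : tuple of float
        (x, y) map coordinates of the top-left corner of cell (0, 0).
    crs_tag : str
        Opaque identifier of the coordinate reference system; only compared
        for equality, never interpreted.
    nodata : float
        Sentinel for missing values in raw layers.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "local"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid must have at least one cell")
        if not self.cell_size > 0:
            raise InvalidParameterError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def aligned_with(self, other: "Grid") -> bool:
        """Same geometry and CRS; the nodata sentinel may differ per layer."""
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and self.crs_tag == other.crs_tag
        )


def _require_same_grid(a: Grid, b: Grid, what: str = "layers") -> None:
    if not a.aligned_with(b):
        raise GridMismatchError(f"{what} are not on the same grid: {a} vs {b}")


@dataclass
class RawLayer:
    """A single-band raster: per-cell real values with nodata holes."""

    grid: Grid
    values: np.ndarray
    layer_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"layer {self.layer_id!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata (or non-finite)."""
        return ~np.isfinite(self.values) | (self.values == self.grid.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask()]


@dataclass
class RegionMask:
    """Boolean membership raster (analysis region, focal areas, protected areas)."""

    grid: Grid
    member: np.ndarray
    mask_id: str = ""

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask {self.mask_id!r}: shape {self.member.shape} != grid {self.grid.shape}"
            )

    @property
    def n_cells(self) -> int:
        return int(self.member.sum())

    def intersection(self, other: "RegionMask", mask_id: str = "") -> "RegionMask":
        _require_same_grid(self.grid, other.grid, "masks")
        return RegionMask(self.grid, self.member & other.member, mask_id)

    def union(self, other: "RegionMask", mask_id: str = "") -> "RegionMask":
        _require_same_grid(self.grid, other.grid, "masks")
        return RegionMask(self.grid, self.member | other.member, mask_id)

    def is_subset_of(self, other: "RegionMask") -> bool:
        _require_same_grid(self.grid, other.grid, "masks")
        return bool(np.all(~self.member | other.member))


@dataclass
class NormalizedFeature:
    """One conservation feature as cell proportions ``q_ji`` summing to 1.

    ``q`` is zero outside the analysis mask and on nodata cells; a feature
    that would be all-zero is rejected at construction (see
    :func:`normalize_feature`). A species' seasonal distributions are
    separate features sharing a ``species_id``.
    """

    grid: Grid
    q: np.ndarray
    feature_id: str
    season_tag: str = "year_round"
    species_id: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != self.grid.shape:
            raise GridMismatchError(
                f"feature {self.feature_id!r}: shape {self.q.shape} != grid {self.grid.shape}"
            )
        if np.any(self.q < 0):
            raise InvalidParameterError(f"feature {self.feature_id!r}: negative proportions")
        total = float(self.q.sum())
        if not math.isclose(total, 1.0, abs_tol=NORMALIZATION_TOL):
            raise InvalidParameterError(
                f"feature {self.feature_id!r}: proportions sum to {total}, not 1"
            )
        if not self.species_id:
            self.species_id = self.feature_id


@dataclass
class LandscapeStack:
    """Aligned bundle of features, masks and the cost layer for one analysis.

    ``cost`` defaults to 1 everywhere: ranking on biological criteria alone,
    with no land-cost weighting.
    """

    grid: Grid
    features: list[NormalizedFeature]
    analysis_mask: RegionMask
    cost: np.ndarray | None = None
    focal_mask: RegionMask | None = None
    protected_mask: RegionMask | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise InvalidParameterError("a landscape stack needs at least one feature")
        _require_same_grid(self.grid, self.analysis_mask.grid, "stack components")
        for f in self.features:
            _require_same_grid(self.grid, f.grid, "stack components")
        if self.cost is None:
            self.cost = np.ones(self.grid.shape)
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.shape != self.grid.shape:
            raise GridMismatchError("cost layer shape mismatch")
        if np.any(self.cost[self.analysis_mask.member] <= 0):
            raise InvalidParameterError("cost must be positive on analysis cells")
        for m, name in ((self.focal_mask, "focal"), (self.protected_mask, "protected")):
            if m is not None:
                _require_same_grid(self.grid, m.grid, "stack components")
                if not m.is_subset_of(self.analysis_mask):
                    raise InvalidParameterError(f"{name} mask extends outside the analysis mask")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature_matrix(self) -> np.ndarray:
        """(n_features, n_cells) dense matrix of flattened q values."""
        return np.stack([f.q.ravel() for f in self.features])


def aggregate_max(layer: RawLayer, factor: int) -> RawLayer:
    """Block-aggregate a layer, taking the maximum over each block.

    The output grid has ``ceil(n/factor)`` cells along each axis — partial
    edge blocks are allowed — and a cell size ``factor`` times coarser.
    Nodata cells are ignored inside a block; a block of only nodata cells
    stays nodata. This is the max-rule coarsening used to bring fine
    species rasters onto the working analysis resolution.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidParameterError(f"aggregation factor must be a positive integer, got {factor}")
    if factor == 1:
        return RawLayer(layer.grid, layer.values.copy(), layer.layer_id)

    g = layer.grid
    out_rows = -(-g.n_rows // factor)
    out_cols = -(-g.n_cols // factor)
    # pad to a multiple of factor with nodata so partial blocks work
    vals = np.where(layer.nodata_mask(), -np.inf, layer.values)
    padded = np.full((out_rows * factor, out_cols * factor), -np.inf)
    padded[: g.n_rows, : g.n_cols] = vals
    blocks = padded.reshape(out_rows, factor, out_cols, factor)
    out = blocks.max(axis=(1, 3))
    out_grid = Grid(
        n_rows=out_rows,
        n_cols=out_cols,
        cell_size=g.cell_size * factor,
        origin=g.origin,
        crs_tag=g.crs_tag,
        nodata=g.nodata,
    )
    out = np.where(np.isneginf(out), out_grid.nodata, out)
    return RawLayer(out_grid, out, layer.layer_id)


def apply_exclusions(landcover: RawLayer, excluded_classes: Iterable) -> RegionMask:
    """Build the analysis mask from a classed land-cover layer.

    A cell is habitat (mask member) exactly when its class code is not in
    ``excluded_classes`` and it is not nodata — the rule that drops, e.g.,
    forest, water, cropland and developed land from a shrubland analysis.
    Aggregation, when used, happens before exclusion: the mask is built on
    the working (aggregated) grid.
    """
    excluded = set(excluded_classes)
    nodata = landcover.nodata_mask()
    member = ~nodata
    if excluded:
        member &= ~np.isin(landcover.values, list(excluded))
    return RegionMask(landcover.grid, member, mask_id="analysis")


def normalize_feature(
    layer: RawLayer,
    analysis_mask: RegionMask,
    feature_id: str | None = None,
    season_tag: str = "year_round",
    species_id: str = "",
) -> NormalizedFeature:
    """Turn a raw distribution/abundance layer into cell proportions q_ji.

    ``q_ji = v_i / sum(v_k over analysis cells)``; nodata and out-of-mask
    cells map to zero. Scaling the input by any positive constant leaves the
    result unchanged. A layer with no mass on the analysis mask raises
    :class:`EmptyFeatureError` — such a feature must be dropped, not kept.
    """
    _require_same_grid(layer.grid, analysis_mask.grid, "layer and analysis mask")
    vals = np.where(layer.nodata_mask(), 0.0, layer.values)
    if np.any(vals < 0):
        raise InvalidParameterError(f"feature layer {layer.layer_id!r} has negative values")
    vals = np.where(analysis_mask.member, vals, 0.0)
    total = vals.sum()
    if total <= 0:
        raise EmptyFeatureError(
            f"feature {layer.layer_id!r} has no mass on the analysis mask"
        )
    return NormalizedFeature(
        grid=layer.grid,
        q=vals / total,
        feature_id=feature_id or layer.layer_id,
        season_tag=season_tag,
        species_id=species_id,
    )


def select_features(
    range_fraction_of_region: float,
    fraction_of_range_in_region: float,
    thresholds: tuple[float, float] = (0.20, 0.20),
) -> bool:
    """Keep/drop rule for candidate features.

    Keep a species when its distribution covers at least ``t1`` of the study
    region (inclusive), or when strictly more than ``t2`` of its entire range
    falls inside the region. The first criterion admits wide-ranging species,
    the second small-ranged species concentrated in the region; note the
    deliberate ≥ vs > asymmetry.
    """
    t1, t2 = thresholds
    for name, v in (
        ("range_fraction_of_region", range_fraction_of_region),
        ("fraction_of_range_in_region", fraction_of_range_in_region),
    ):
        if not (0.0 <= v <= 1.0):
            raise InvalidParameterError(f"{name} must be in [0,1], got {v}")
    return range_fraction_of_region >= t1 or fraction_of_range_in_region > t2
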