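"""Single-band GeoTIFF I/O and the feature manifest.

Layers travel as plain north-up single-band GeoTIFFs. Grid geometry is
stored in the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint), the
nodata sentinel in the GDAL_NODATA tag, and the opaque CRS tag plus layer id
in the ImageDescription as JSON. Round-trips are bit-exact for values and
nodata. Region masks are encoded 0/1 uint8 with nodata 255.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import GridMismatchError, UnsupportedFormatError
from .grids import Grid, NormalizedFeature, RawLayer, RegionMask

__all__ = [
    "read_raster",
    "write_raster",
    "read_mask",
    "read_level_raster",
    "read_manifest",
    "write_manifest",
    "load_features",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

MASK_NODATA = 255


def _geo_extratags(grid: Grid) -> list:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]


def _write_array(array: np.ndarray, grid: Grid, nodata: float, layer_id: str, path) -> None:
    # grid.nodata may differ from the on-disk nodata (e.g. uint8 masks)
    g = Grid(grid.n_rows, grid.n_cols, grid.cell_size, grid.origin, grid.crs_tag, nodata)
    desc = json.dumps({"crs_tag": g.crs_tag, "layer_id": layer_id})
    tifffile.imwrite(
        str(path),
        array,
        photometric="minisblack",
        description=desc,
        extratags=_geo_extratags(g),
    )


def write_raster(obj, path) -> None:
    """Write a layer, mask, removal mask or rank map to a single-band GeoTIFF.

    Dispatch is by type: :class:`RawLayer` → float64 with its grid nodata;
    :class:`RegionMask` → uint8 0/1 with nodata 255; objects exposing
    ``grid`` plus a ``level`` (removal mask) or ``rank_fraction`` (rank map)
    array are written as int32 / float64 respectively.
    """
    if isinstance(obj, RawLayer):
        _write_array(np.asarray(obj.values, dtype=np.float64), obj.grid,
                     obj.grid.nodata, obj.layer_id, path)
    elif isinstance(obj, RegionMask):
        _write_array(obj.member.astype(np.uint8), obj.grid, MASK_NODATA, obj.mask_id, path)
    elif isinstance(obj, NormalizedFeature):
        _write_array(np.asarray(obj.q, dtype=np.float64), obj.grid,
                     obj.grid.nodata, obj.feature_id, path)
    elif hasattr(obj, "level"):
        _write_array(np.asarray(obj.level, dtype=np.int32), obj.grid, -1, "removal_mask", path)
    elif hasattr(obj, "rank_fraction"):
        _write_array(np.asarray(obj.rank_fraction, dtype=np.float64), obj.grid,
                     obj.grid.nodata, "rank_map", path)
    else:
        raise UnsupportedFormatError(f"cannot write object of type {type(obj).__name__}")


def _read_page(path):
    try:
        tif = tifffile.TiffFile(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    with tif:
        if len(tif.pages) != 1:
            raise UnsupportedFormatError(f"{path}: expected a single-band raster")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(f"{path}: expected a single-band raster")
        values = page.asarray()
        tags = page.tags
        cell_size = 1.0
        origin = (0.0, 0.0)
        if _TAG_PIXEL_SCALE in tags:
            cell_size = float(tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value))
        crs_tag, layer_id = "local", Path(path).stem
        if 270 in tags:
            try:
                meta = json.loads(tags[270].value)
                crs_tag = meta.get("crs_tag", crs_tag)
                layer_id = meta.get("layer_id") or layer_id
            except (json.JSONDecodeError, TypeError):
                pass
    grid = Grid(values.shape[0], values.shape[1], cell_size, origin, crs_tag, nodata)
    return grid, values, layer_id


def read_raster(path, expect_grid: Grid | None = None) -> RawLayer:
    """Read a single-band GeoTIFF as a :class:`RawLayer`.

    If ``expect_grid`` is given, the file's geometry and CRS must match it.
    """
    grid, values, layer_id = _read_page(path)
    if expect_grid is not None:
        if not grid.aligned_with(expect_grid):
            raise GridMismatchError(
                f"{path}: grid {grid} does not match stack grid {expect_grid}"
            )
        grid = Grid(grid.n_rows, grid.n_cols, grid.cell_size, grid.origin,
                    grid.crs_tag, grid.nodata)
    return RawLayer(grid, np.asarray(values, dtype=float), layer_id)


def read_mask(path, mask_id: str = "", expect_grid: Grid | None = None) -> RegionMask:
    """Read a 0/1 mask GeoTIFF; nodata (255) counts as non-member."""
    grid, values, layer_id = _read_page(path)
    if expect_grid is not None:
        if not grid.aligned_with(expect_grid):
            raise GridMismatchError(f"{path}: grid does not match stack grid")
        grid = expect_grid
    member = (values == 1)
    return RegionMask(grid, member, mask_id or layer_id)


def read_level_raster(path, expect_grid: Grid | None = None) -> np.ndarray:
    """Read an integer level raster (hierarchical removal mask); nodata → 0."""
    grid, values, _ = _read_page(path)
    if expect_grid is not None and (grid.n_rows, grid.n_cols) != expect_grid.shape:
        raise GridMismatchError(f"{path}: grid does not match stack grid")
    levels = np.asarray(values, dtype=np.int64)
    return np.where(levels < 0, 0, levels)


MANIFEST_COLUMNS = ["feature_id", "species_id", "season_tag", "path"]


def write_manifest(rows: pd.DataFrame, path) -> None:
    """Write the feature manifest CSV (feature_id, species_id, season_tag, path)."""
    rows.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise UnsupportedFormatError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_features(manifest: pd.DataFrame, analysis_mask: RegionMask, base_dir=None):
    """Load and normalize every feature listed in a manifest.

    Paths are resolved relative to ``base_dir`` when given. Raises on grid
    mismatch or an empty feature; callers decide whether to drop upstream.
    """
    from .grids import normalize_feature

    base = Path(base_dir) if base_dir is not None else None
    features = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if base is not None and not p.is_absolute():
            p = base / p
        layer = read_raster(p, expect_grid=analysis_mask.grid)
        features.append(
            normalize_feature(
                layer,
                analysis_mask,
                feature_id=row.feature_id,
                season_tag=row.season_tag,
                species_id=row.species_id,
            )
        )
    return features
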