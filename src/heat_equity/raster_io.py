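"""GeoTIFF and GeoJSON input/output for the gridded data model.

Rasters are single-band GeoTIFFs: LST as float32 (nodata honored, read as
NaN), land cover as uint8 with codes 1=URBAN, 2=NONURBAN, 3=WATER, zone maps
as int32 codes with 0 = unassigned.  Georeferencing uses the standard
ModelPixelScale/ModelTiepoint tags; nodata uses the GDAL_NODATA ascii tag.
Zone maps may alternatively come from GeoJSON polygons, rasterized with the
cell-center containment rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely import contains_xy
from shapely.geometry import shape as shapely_shape

from .grids import Georeference, LandCoverGrid, TemperatureGrid, ZoneMap

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path, array: np.ndarray, georef: Georeference, nodata=None) -> None:
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.cell_size, georef.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.origin_x, georef.origin_y, 0.0)),
    ]
    if nodata is not None:
        s = str(nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(s) + 1, s))
    tifffile.imwrite(str(path), np.ascontiguousarray(array), extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, Georeference, float | None]:
    """Return (array, georeference, nodata-or-None)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        cell = 1.0
        ox = oy = 0.0
        if _TAG_PIXEL_SCALE in tags:
            cell = float(tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            ox, oy = float(tp[3]), float(tp[4])
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    return array, Georeference(ox, oy, cell), nodata


def write_temperature(path, grid: TemperatureGrid, nodata: float = -9999.0) -> None:
    values = np.where(np.isnan(grid.values), nodata, grid.values).astype(np.float32)
    write_geotiff(path, values, grid.georef, nodata=nodata)


def read_temperature(path) -> TemperatureGrid:
    array, georef, nodata = read_geotiff(path)
    values = np.asarray(array, dtype=float)
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return TemperatureGrid(values, georef)


def write_landcover(path, grid: LandCoverGrid) -> None:
    write_geotiff(path, grid.labels.astype(np.uint8), grid.georef)


def read_landcover(path) -> LandCoverGrid:
    array, georef, _ = read_geotiff(path)
    return LandCoverGrid(array.astype(np.int64), georef)


def write_zonemap(dirpath, zones: ZoneMap, georef: Georeference) -> None:
    """Write a zone map as two int32 GeoTIFFs plus a code table CSV."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    write_geotiff(dirpath / "zones_ua.tif", zones.ua.astype(np.int32), georef)
    write_geotiff(dirpath / "zones_tract.tif", zones.tract.astype(np.int32), georef)
    rows = [{"kind": "ua", "code": c, "name": n} for c, n in sorted(zones.ua_names.items())]
    rows += [{"kind": "tract", "code": c, "name": n} for c, n in sorted(zones.tract_names.items())]
    pd.DataFrame(rows).to_csv(dirpath / "zone_ids.csv", index=False)


def read_zonemap(dirpath) -> ZoneMap:
    dirpath = Path(dirpath)
    ua, _, _ = read_geotiff(dirpath / "zones_ua.tif")
    tract, _, _ = read_geotiff(dirpath / "zones_tract.tif")
    ids = pd.read_csv(dirpath / "zone_ids.csv", dtype={"name": str})
    ua_names = {int(r.code): r.name for r in ids[ids.kind == "ua"].itertuples()}
    tract_names = {int(r.code): r.name for r in ids[ids.kind == "tract"].itertuples()}
    return ZoneMap(ua, tract, ua_names, tract_names)


def rasterize_zones(geojson, georef: Georeference, shape: tuple[int, int]) -> ZoneMap:
    """Rasterize GeoJSON zone polygons onto a grid by cell-center containment.

    Each feature needs an ``urbanized_area_id`` property and, for tract
    polygons, a ``tract_id`` property.  Later features overwrite earlier ones
    where polygons overlap (boundary cells follow the half-open convention:
    a center exactly on a boundary is not contained).
    """
    if isinstance(geojson, (str, Path)):
        geojson = json.loads(Path(geojson).read_text())
    xs, ys = georef.cell_centers(shape)
    ua = np.zeros(shape, dtype=np.int64)
    tract = np.zeros(shape, dtype=np.int64)
    ua_codes: dict[str, int] = {}
    tract_names: dict[int, str] = {}
    next_tract = 1
    for feat in geojson["features"]:
        geom = shapely_shape(feat["geometry"])
        props = feat["properties"]
        ua_id = str(props["urbanized_area_id"])
        code = ua_codes.setdefault(ua_id, len(ua_codes) + 1)
        inside = contains_xy(geom, xs.ravel(), ys.ravel()).reshape(shape)
        ua[inside] = code
        if "tract_id" in props and props["tract_id"] is not None:
            tract[inside] = next_tract
            tract_names[next_tract] = str(props["tract_id"])
            next_tract += 1
    ua_names = {code: name for name, code in ua_codes.items()}
    return ZoneMap(ua, tract, ua_names, tract_names)
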