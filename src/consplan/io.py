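"""Plain-text I/O: ESRI ASCII grids, GeoJSON reserve collections, CSV tables.

Rasters travel as single-band ESRI ASCII grids (boolean layers as 0/1,
continuous layers as floats with a nodata sentinel); vector geometries as
GeoJSON FeatureCollections; all tabular outputs as CSV with a header row.
The ASCII grid's row order (top row first) matches the package's row-0-at-top
indexing, and ``xllcorner``/``yllcorner`` anchor the grid's lower-left corner.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from consplan.errors import DataError
from consplan.grid import BinaryLayer, ContinuousLayer, GridSpec

if TYPE_CHECKING:
    from consplan.reserves import ReserveRecord

NODATA = -9999.0


def write_ascii_grid(layer: BinaryLayer | ContinuousLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (boolean as 0/1, NaN as nodata)."""
    grid = layer.grid
    x0, ytop = grid.origin
    yll = ytop - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {NODATA:.10g}\n"
    )
    if isinstance(layer, BinaryLayer):
        body = "\n".join(" ".join("1" if v else "0" for v in row) for row in layer.values)
    else:
        vals = np.where(np.isnan(layer.values), NODATA, layer.values)
        body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(
    path: str | Path, grid: GridSpec | None = None, binary: bool = False, name: str = ""
) -> BinaryLayer | ContinuousLayer:
    """Read an ESRI ASCII grid.

    If ``grid`` is given, the raster must conform to it and the returned
    layer shares it; otherwise a fresh all-land unit-area GridSpec is built
    from the header.
    """
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    cs = hdr.get("cellsize", 1.0)
    nodata = hdr.get("nodata_value", NODATA)
    vals = np.loadtxt(lines[i:], dtype=float).reshape(n_rows, n_cols)
    if grid is None:
        origin = (hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0) + n_rows * cs)
        grid = GridSpec(n_rows, n_cols, cell_size=cs, origin=origin)
    elif grid.shape != (n_rows, n_cols):
        raise DataError(f"raster {path} shape {(n_rows, n_cols)} != grid {grid.shape}")
    if binary:
        return BinaryLayer(grid, vals != 0, name=name or Path(path).stem)
    vals = np.where(vals == nodata, np.nan, vals)
    return ContinuousLayer(grid, vals, name=name or Path(path).stem)


def write_reserves_geojson(records: list["ReserveRecord"], path: str | Path) -> None:
    """Write reserves as a GeoJSON FeatureCollection keyed by id.

    Reserves without a polygon are emitted as Point features carrying their
    centroid, so round-tripping preserves the buffer-only records.
    """
    feats = []
    for r in records:
        geom = r.geometry if r.geometry is not None else shapely.points(*r.centroid)
        feats.append(
            {
                "type": "Feature",
                "id": r.id,
                "geometry": mapping(geom),
                "properties": {
                    "id": r.id,
                    "network": r.network,
                    "lon": r.centroid[0],
                    "lat": r.centroid[1],
                    "area_km2": r.terrestrial_area,
                    "year": r.designation_year,
                    "region": r.region,
                    "country": r.country,
                    "status": r.status,
                    "desig": r.desig_label,
                    "ecosystem_group": r.ecosystem_group,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1, sort_keys=True)
    )


def read_reserves_geojson(path: str | Path) -> list["ReserveRecord"]:
    """Read a reserve FeatureCollection written by :func:`write_reserves_geojson`."""
    from consplan.reserves import ReserveRecord

    fc = json.loads(Path(path).read_text())
    records = []
    for f in fc["features"]:
        p = f["properties"]
        geom = shape(f["geometry"])
        if geom.geom_type == "Point":
            geom = None
        records.append(
            ReserveRecord(
                id=str(p["id"]),
                network=p["network"],
                centroid=(float(p["lon"]), float(p["lat"])),
                terrestrial_area=float(p["area_km2"]),
                designation_year=int(p["year"]),
                region=p.get("region", ""),
                country=p.get("country", ""),
                status=p.get("status", ""),
                desig_label=p.get("desig", ""),
                geometry=geom,
                ecosystem_group=p.get("ecosystem_group"),
            )
        )
    return records
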