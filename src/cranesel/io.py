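"""Plain-text I/O: ESRI ASCII grids, GeoJSON geometries, telemetry CSV.

Rasters travel as ESRI ASCII grid (.asc) files, vectors as GeoJSON, and
fixes as CSV with ISO-8601 timestamps — all line-oriented text formats
that diff cleanly and need no binary drivers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import Raster

_NODATA = -9999.0


def write_ascii_grid(path, raster: Raster, nodata: float = _NODATA):
    """Write a raster as an ESRI ASCII grid (rows north to south)."""
    data = np.asarray(raster.data, dtype=float)
    out = np.where(np.isfinite(data), data, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.nx}\n")
        fh.write(f"nrows {raster.ny}\n")
        fh.write(f"xllcorner {raster.x0}\n")
        fh.write(f"yllcorner {raster.y0}\n")
        fh.write(f"cellsize {raster.cell}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in out[::-1]:  # ASCII grids store the north row first
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return Raster(data, header["xllcorner"], header["yllcorner"], header["cellsize"])


def write_geojson(path, geometry, properties: dict | None = None):
    """Write a shapely geometry as a single-feature GeoJSON file."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(geometry),
                "properties": properties or {},
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_geojson(path):
    """Read the first feature's geometry (and properties) from GeoJSON."""
    with open(path) as fh:
        doc = json.load(fh)
    feat = doc["features"][0]
    return shape(feat["geometry"]), feat.get("properties", {})


def write_fixes_csv(path, fixes: pd.DataFrame, seed=None):
    """Write telemetry fixes (individual_id, timestamp, x, y, altitude)."""
    cols = ["individual_id", "timestamp", "x", "y", "altitude"]
    out = fixes[cols].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    fixes = pd.read_csv(path, comment="#")
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    return fixes
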