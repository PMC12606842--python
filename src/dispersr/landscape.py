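"""Movement-boundary geometry: barrier filtering and distance rasters.

Linear features below a size that plausibly impedes movement are
discarded before distance rasters are built: roads must be wider than
3 m, rivers wider than 5 m and lakes larger than 22 500 ha.  Rivers
and lakes together form the single "waterbody" class; roads form the
other.  A distance raster stores, per cell, the Euclidean distance
from the cell center to the nearest retained feature of one class, and
covariates are sampled from it by bilinear interpolation.

Rasters are plain numpy grids written/read as ESRI ASCII text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

ROAD_MIN_WIDTH_M = 3.0
RIVER_MIN_WIDTH_M = 5.0
LAKE_MIN_AREA_HA = 22_500.0


@dataclass
class Feature:
    geometry: BaseGeometry
    kind: str                    # 'road' | 'river' | 'lake'
    attrs: dict = field(default_factory=dict)


@dataclass
class BarrierSet:
    """Size-filtered barrier features, grouped into the two raster classes."""

    roads: list[Feature] = field(default_factory=list)
    rivers: list[Feature] = field(default_factory=list)
    lakes: list[Feature] = field(default_factory=list)

    @property
    def road_geoms(self) -> list[BaseGeometry]:
        return [f.geometry for f in self.roads]

    @property
    def water_geoms(self) -> list[BaseGeometry]:
        return [f.geometry for f in self.rivers + self.lakes]


def read_barriers_geojson(path) -> list[Feature]:
    """Load barrier features from GeoJSON.

    Each feature needs a ``kind`` property ('road'/'river'/'lake') and
    a ``width_m`` (lines) or ``area_ha`` (polygons) property.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = []
    for f in gj.get("features", []):
        props = f.get("properties") or {}
        feats.append(Feature(geojson_shape(f["geometry"]),
                             props.get("kind", ""), dict(props)))
    return feats


def write_barriers_geojson(features: list[Feature], path) -> None:
    gj = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "geometry": shapely.geometry.mapping(f.geometry),
         "properties": {"kind": f.kind, **f.attrs}}
        for f in features]}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def filter_barriers(features, road_min_width_m: float = ROAD_MIN_WIDTH_M,
                    river_min_width_m: float = RIVER_MIN_WIDTH_M,
                    lake_min_area_ha: float = LAKE_MIN_AREA_HA) -> BarrierSet:
    """Keep only barrier-sized features (strict inequalities).

    Features lacking the required size attribute are rejected with a
    warning; unknown kinds are ignored.
    """
    out = BarrierSet()
    for f in features:
        if f.kind == "road":
            w = f.attrs.get("width_m")
            if w is None:
                log.warning("road without width_m rejected")
            elif w > road_min_width_m:
                out.roads.append(f)
        elif f.kind == "river":
            w = f.attrs.get("width_m")
            if w is None:
                log.warning("river without width_m rejected")
            elif w > river_min_width_m:
                out.rivers.append(f)
        elif f.kind == "lake":
            a = f.attrs.get("area_ha")
            if a is None:
                log.warning("lake without area_ha rejected")
            elif a > lake_min_area_ha:
                out.lakes.append(f)
    return out


@dataclass
class DistanceRaster:
    """Gridded Euclidean distance (m) to the nearest feature of one class.

    ``values[r, c]`` with row 0 northmost (ESRI convention); ``x0, y0``
    is the lower-left corner of the grid.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray = field(repr=False)

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0,
                self.x0 + self.ncol * self.cell, self.y0 + self.nrow * self.cell)

    def sample(self, x, y):
        """Bilinear interpolation between cell centers at (x, y).

        Points must lie inside the raster extent; between the boundary
        and the outermost cell centers the edge value is held.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
            raise ValueError("point outside raster extent")
        fc = np.clip((x - self.x0) / self.cell - 0.5, 0.0, self.ncol - 1.0)
        fr = np.clip((self.y0 + self.nrow * self.cell - y) / self.cell - 0.5,
                     0.0, self.nrow - 1.0)
        c0 = np.clip(np.floor(fc).astype(int), 0, self.ncol - 2) \
            if self.ncol > 1 else np.zeros_like(fc, dtype=int)
        r0 = np.clip(np.floor(fr).astype(int), 0, self.nrow - 2) \
            if self.nrow > 1 else np.zeros_like(fr, dtype=int)
        c1 = np.minimum(c0 + 1, self.ncol - 1)
        r1 = np.minimum(r0 + 1, self.nrow - 1)
        wc = fc - c0
        wr = fr - r0
        v = (self.values[r0, c0] * (1 - wr) * (1 - wc)
             + self.values[r0, c1] * (1 - wr) * wc
             + self.values[r1, c0] * wr * (1 - wc)
             + self.values[r1, c1] * wr * wc)
        return v if v.ndim else float(v)

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncol}\nnrows {self.nrow}\n"
                     f"xllcorner {self.x0!r}\nyllcorner {self.y0!r}\n"
                     f"cellsize {self.cell!r}\nNODATA_value -9999\n")
            np.savetxt(fh, self.values, fmt="%.3f")

    @classmethod
    def from_ascii(cls, path) -> "DistanceRaster":
        header = {}
        with open(path) as fh:
            for _ in range(6):
                k, v = fh.readline().split()
                header[k.lower()] = float(v)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(header["xllcorner"], header["yllcorner"],
                   header["cellsize"], values)


def build_distance_raster(geoms: list[BaseGeometry],
                          extent: tuple[float, float, float, float],
                          cell: float = 100.0) -> DistanceRaster:
    """Distance-to-nearest-feature raster over ``extent`` (xmin, ymin, xmax, ymax).

    Each cell holds the exact Euclidean distance from its center to the
    merged feature geometry (0 inside polygons), so the raster value at
    any point is within cell*sqrt(2)/2 of the true distance there.
    """
    if not geoms:
        raise ValueError("no features after filtering")
    xmin, ymin, xmax, ymax = extent
    ncol = int(np.ceil((xmax - xmin) / cell))
    nrow = int(np.ceil((ymax - ymin) / cell))
    xc = xmin + (np.arange(ncol) + 0.5) * cell
    yc = ymin + (nrow - 1 - np.arange(nrow) + 0.5) * cell  # row 0 northmost
    gx, gy = np.meshgrid(xc, yc)
    pts = shapely.points(gx.ravel(), gy.ravel())
    merged = shapely.union_all(geoms)
    shapely.prepare(merged)
    vals = shapely.distance(pts, merged).reshape(nrow, ncol)
    return DistanceRaster(float(xmin), float(ymin), float(cell), vals)


def sample_distance(raster: DistanceRaster, x, y):
    """Functional alias for :meth:`DistanceRaster.sample`."""
    return raster.sample(x, y)


def distance_bin_summary(strata: pd.DataFrame,
                         bins=((None, "all"), (500.0, "start<500m"),
                               (100.0, "start<100m"))) -> pd.DataFrame:
    """Observed vs random end-distances by start-distance bin.

    ``strata`` must carry road_start/water_start/road_end/water_end and
    a boolean ``used`` column.  For each class the mean +/- SE of
    end-location distances is computed over (a) all steps, (b) steps
    starting < 500 m from the class, (c) < 100 m — identically for the
    observed (used) and random rows.  Empty bins are reported with
    count 0 and NaN means.
    """
    rows = []
    for cls in ("road", "water"):
        start = strata[f"{cls}_start"].to_numpy()
        end = strata[f"{cls}_end"].to_numpy()
        used = strata["used"].to_numpy().astype(bool)
        for cut, name in bins:
            in_bin = np.ones(len(strata), bool) if cut is None else start < cut
            for grp, sel in (("observed", in_bin & used),
                             ("random", in_bin & ~used)):
                d = end[sel]
                rows.append({
                    "class": cls, "bin": name, "group": grp, "n": int(d.size),
                    "mean_m": float(d.mean()) if d.size else float("nan"),
                    "se_m": float(d.std(ddof=1) / np.sqrt(d.size))
                            if d.size > 1 else float("nan"),
                })
    return pd.DataFrame(rows)
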