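"""Raster data model for co-registered 1 km2 habitat and pressure layers.

The analysis grain is a fixed 1 km x 1 km grid in an equal-area projected
CRS, so every cell covers exactly 1 km2 and areal sums are exact.  Habitat
layers hold the fraction of each cell covered by the habitat ([0, 1]);
pressure layers hold per-cell intensity: binary presence for the invasive
benthic predators, a turbine-footprint fraction for wind parks, and a
normalised concentration (domain mean 1 = current load) for nutrients.

Rasters are single-band float32 GeoTIFFs.  Georeferencing uses the standard
GeoTIFF ModelPixelScale / ModelTiepoint tags plus the GDAL nodata convention;
nodata cells are NaN in memory.  Row 0 is the northernmost row; cell (r, c)
covers the half-open square [origin_x + c*s, origin_x + (c+1)*s) x
(top - (r+1)*s, top - r*s], with top = origin_y + n_rows*s.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

CELL_SIZE_M = 1000.0  # fixed 1 km grid

#: Pressures whose layers must be binary presence/absence.
BINARY_PRESSURES = frozenset({"round_goby", "mud_crab"})

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterError(ValueError):
    """Invalid raster content or georeferencing."""


class AlignmentError(RasterError):
    """Layers do not share one grid."""


@dataclass(frozen=True)
class GridSpec:
    """A fixed 1 km2 analysis grid in an equal-area projected CRS."""

    n_rows: int
    n_cols: int
    origin_x: float  # west edge, projected metres
    origin_y: float  # south edge, projected metres
    cell_size: float = CELL_SIZE_M
    crs_label: str = "EPSG:3035"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("grid must have at least one row and column")
        if self.cell_size != CELL_SIZE_M:
            raise RasterError(
                f"analysis grain is fixed at {CELL_SIZE_M:.0f} m cells, "
                f"got {self.cell_size}")
        label = self.crs_label.upper()
        if "4326" in label or label.startswith("GEOGCS") or "CRS84" in label:
            raise RasterError(
                "geographic (degree) rasters are rejected; provide an "
                "equal-area projected CRS")

    @property
    def top(self) -> float:
        return self.origin_y + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of one cell in projected metres."""
        s = self.cell_size
        minx = self.origin_x + col * s
        maxy = self.top - row * s
        return (minx, maxy - s, minx + s, maxy)


@dataclass(frozen=True, eq=False)
class HabitatLayer:
    habitat_id: str
    grid: GridSpec
    cover: np.ndarray  # fraction of cell covered, [0, 1] or NaN

    def __post_init__(self) -> None:
        _check_shape(self.cover, self.grid)
        vals = self.cover[np.isfinite(self.cover)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise RasterError(
                f"habitat cover for {self.habitat_id!r} outside [0, 1]: "
                f"range [{vals.min():g}, {vals.max():g}]")


@dataclass(frozen=True, eq=False)
class PressureLayer:
    pressure_id: str
    grid: GridSpec
    intensity: np.ndarray  # >= 0; {0,1} for binary species-presence layers

    def __post_init__(self) -> None:
        _check_shape(self.intensity, self.grid)
        vals = self.intensity[np.isfinite(self.intensity)]
        if vals.size and vals.min() < 0:
            raise RasterError(
                f"pressure intensity for {self.pressure_id!r} must be >= 0")
        if self.pressure_id in BINARY_PRESSURES and vals.size:
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise RasterError(
                    f"{self.pressure_id!r} layer must be binary presence {{0,1}}")


def _check_shape(array: np.ndarray, grid: GridSpec) -> None:
    if array.ndim != 2 or array.shape != grid.shape:
        raise RasterError(
            f"array shape {array.shape} does not match grid {grid.shape}")


# ---------------------------------------------------------------------------
# GeoTIFF I/O

def write_raster(layer: HabitatLayer | PressureLayer, path: str | Path) -> Path:
    """Write a layer as a single-band float32 GeoTIFF (NaN = nodata)."""
    path = Path(path)
    grid = layer.grid
    data = (layer.cover if isinstance(layer, HabitatLayer)
            else layer.intensity).astype(np.float32)
    kind = "habitat" if isinstance(layer, HabitatLayer) else "pressure"
    ident = (layer.habitat_id if isinstance(layer, HabitatLayer)
             else layer.pressure_id)
    description = json.dumps(
        {"kind": kind, "id": ident, "crs_label": grid.crs_label})
    s = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, data, description=description, extratags=extratags)
    return path


def write_array(array: np.ndarray, grid: GridSpec, path: str | Path,
                name: str = "values") -> Path:
    """Write an arbitrary float field (e.g. a percent-change map) as a
    georeferenced single-band GeoTIFF, without layer-kind validation."""
    path = Path(path)
    _check_shape(np.asarray(array), grid)
    description = json.dumps(
        {"kind": "field", "id": name, "crs_label": grid.crs_label})
    s = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32),
                     description=description, extratags=extratags)
    return path


def read_raster(path: str | Path, kind: str,
                layer_id: str | None = None) -> HabitatLayer | PressureLayer:
    """Read a single-band GeoTIFF as a habitat or pressure layer.

    ``kind`` is ``"habitat"`` or ``"pressure"``.  Habitat cover supplied on a
    0-100 % scale (max > 1) is rescaled to [0, 1] with a logged notice.  The
    layer id defaults to the one stored in the file description.
    """
    path = Path(path)
    if kind not in ("habitat", "pressure"):
        raise ValueError(f"kind must be 'habitat' or 'pressure', got {kind!r}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterError(f"{path.name}: expected a single-band raster")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterError(f"{path.name}: expected a single-band raster")
        data = page.asarray().astype(np.float64)
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise RasterError(f"{path.name}: missing georeference tags") from exc
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except json.JSONDecodeError:
                pass
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        if nodata_tag is not None:
            try:
                nodata = float(nodata_tag.value)
                if math.isfinite(nodata):
                    data[data == nodata] = np.nan
            except (TypeError, ValueError):
                pass
    if sx != sy:
        raise RasterError(f"{path.name}: non-square cells ({sx} x {sy})")
    top = float(tiepoint[4])
    grid = GridSpec(
        n_rows=data.shape[0], n_cols=data.shape[1],
        origin_x=float(tiepoint[3]), origin_y=top - data.shape[0] * float(sx),
        cell_size=float(sx),
        crs_label=meta.get("crs_label", "projected"))
    ident = layer_id or meta.get("id") or path.stem
    if kind == "habitat":
        finite = data[np.isfinite(data)]
        if finite.size and finite.max() > 1:
            logger.info("%s: cover max %.3g > 1, rescaling from percent to "
                        "fraction", path.name, finite.max())
            data = data / 100.0
        return HabitatLayer(habitat_id=ident, grid=grid, cover=data)
    return PressureLayer(pressure_id=ident, grid=grid, intensity=data)


def align_layers(
    layers: Sequence[HabitatLayer | PressureLayer],
) -> Sequence[HabitatLayer | PressureLayer]:
    """Validate that all layers share one grid; returns them unchanged."""
    if not layers:
        raise AlignmentError("need at least one layer")
    ref = layers[0].grid
    mismatches = []
    for layer in layers[1:]:
        if layer.grid != ref:
            ident = getattr(layer, "habitat_id", None) or layer.pressure_id
            mismatches.append(f"{ident}: {layer.grid} != {ref}")
    if mismatches:
        raise AlignmentError("grid mismatch:\n" + "\n".join(mismatches))
    return layers


# ---------------------------------------------------------------------------
# Wind parks

def turbine_footprint_fraction(turbine_diameter_m: float,
                               spacing_m: float) -> float:
    """Seafloor fraction occupied by turbine foundations inside a park.

    One circular gravity foundation of diameter d per spacing s x spacing s
    of park area: pi (d/2)^2 / s^2.  For d = 100 m and s = 800 m this is
    ~0.0123, i.e. foundations cover on the order of 1 % of the seafloor.
    """
    if turbine_diameter_m <= 0 or spacing_m <= 0:
        raise RasterError("turbine diameter and spacing must be > 0")
    if spacing_m <= turbine_diameter_m:
        raise RasterError("turbine spacing must exceed the foundation diameter")
    return math.pi * (turbine_diameter_m / 2.0) ** 2 / spacing_m ** 2


def rasterize_windparks(
    polygons: Iterable[BaseGeometry],
    turbine_diameter_m: float,
    spacing_m: float,
    grid: GridSpec,
) -> PressureLayer:
    """Per-cell wind-park intensity = in-park area fraction x footprint fraction.

    Polygons must be in the grid CRS (projected metres).  Cells fully inside a
    park get the footprint fraction; boundary cells get it scaled by the area
    fraction of the cell inside the park; cells outside parks get 0.
    """
    polys = [p for p in polygons if not p.is_empty]
    frac = turbine_footprint_fraction(turbine_diameter_m, spacing_m)
    intensity = np.zeros(grid.shape)
    if not polys:
        logger.warning("no wind-park polygons supplied; returning a zero layer")
        return PressureLayer("wind_park", grid, intensity)
    from shapely.ops import unary_union
    union = unary_union(polys)
    minx, miny, maxx, maxy = union.bounds
    s = grid.cell_size
    c0 = max(0, int(math.floor((minx - grid.origin_x) / s)))
    c1 = min(grid.n_cols - 1, int(math.floor((maxx - grid.origin_x) / s)))
    r0 = max(0, int(math.floor((grid.top - maxy) / s)))
    r1 = min(grid.n_rows - 1, int(math.floor((grid.top - miny) / s)))
    cell_area = s * s
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            cell = box(*grid.cell_bounds(r, c))
            if cell.intersects(union):
                area = cell.intersection(union).area
                intensity[r, c] = (area / cell_area) * frac
    return PressureLayer("wind_park", grid, intensity)


def read_windpark_geojson(path: str | Path) -> list[BaseGeometry]:
    """Read wind-park polygons from a GeoJSON FeatureCollection or geometry."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc.get("features", [])]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    for g in geoms:
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise RasterError(f"wind-park geometry must be polygonal, "
                              f"got {g.geom_type}")
    return geoms


def downsample_block_mean(fine_cover: np.ndarray, factor: int,
                          habitat_id: str, grid: GridSpec) -> HabitatLayer:
    """Block-mean a finer cover array down to the 1 km analysis grain.

    For users whose native habitat maps are finer than 1 km (e.g. 100 m
    cells, ``factor=10``): averages ``factor x factor`` blocks (NaN-aware)
    and attaches the supplied 1 km ``grid``.
    """
    if factor < 1:
        raise RasterError("downsampling factor must be >= 1")
    arr = np.asarray(fine_cover, dtype=float)
    if arr.shape[0] % factor or arr.shape[1] % factor:
        raise RasterError(
            f"shape {arr.shape} is not divisible by factor {factor}")
    nr, nc = arr.shape[0] // factor, arr.shape[1] // factor
    blocks = arr.reshape(nr, factor, nc, factor)
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(blocks, axis=(1, 3))
    return HabitatLayer(habitat_id, grid, coarse)
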