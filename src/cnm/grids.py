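"""Raster data model and I/O for environmental grids.

Grids live on a regular lon/lat lattice described by the upper-left corner,
a square cell size in arc-minutes, and a row-major value matrix. Cells are
half-open: a point on a shared edge belongs to the higher-index cell, so
every in-extent point maps to exactly one cell.

Two on-disk formats are supported: single-band float32 GeoTIFF (georeference
carried in the ModelPixelScale/ModelTiepoint tags, nodata in GDAL_NODATA)
and the ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
ASCII_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised when a grid file does not parse as the named standard."""


class OutOfExtentError(ValueError):
    """Raised when a point falls outside a grid's extent."""


class EmptyDomainError(ValueError):
    """Raised when an operation needs valid cells but the mask has none."""


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude pair in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass
class EnvGrid:
    """A single-band raster on a regular lon/lat lattice.

    Parameters
    ----------
    values : (nrows, ncols) float array, row 0 at the top (northernmost).
    nodata_mask : boolean array, True where the cell carries no data.
    origin_lon, origin_lat : upper-left corner of the grid, degrees.
    cell_size : cell edge, arc-minutes.
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size: float
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("values must be finite on unmasked cells")

    # -- geometry ---------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_deg(self) -> float:
        """Cell edge in degrees."""
        return self.cell_size / 60.0

    def same_geometry(self, other: "EnvGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=tol)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, abs_tol=tol)
        )

    def cell_index(self, point: GeoPoint) -> tuple[int, int]:
        """Row/col of the cell containing ``point`` (half-open cells)."""
        col = math.floor((point.lon - self.origin_lon) / self.cell_deg)
        row = math.floor((self.origin_lat - point.lat) / self.cell_deg)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise OutOfExtentError(
                f"point ({point.lon}, {point.lat}) outside grid extent"
            )
        return row, col

    def cell_center(self, row: int, col: int) -> GeoPoint:
        lon = self.origin_lon + (col + 0.5) * self.cell_deg
        lat = self.origin_lat - (row + 0.5) * self.cell_deg
        return GeoPoint(lon, lat)

    def copy(self) -> "EnvGrid":
        return EnvGrid(
            self.values.copy(),
            self.origin_lon,
            self.origin_lat,
            self.cell_size,
            self.nodata_mask.copy(),
        )


class GridStack:
    """An ordered collection of co-registered layers."""

    def __init__(self, layers: Mapping[str, EnvGrid] | None = None) -> None:
        self._layers: dict[str, EnvGrid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: EnvGrid) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not grid.same_geometry(ref):
                raise ValueError(f"layer {name!r} geometry differs from stack")
        self._layers[name] = grid

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    @property
    def shape(self) -> tuple[int, int]:
        ref = next(iter(self._layers.values()))
        return ref.values.shape

    def __getitem__(self, name: str) -> EnvGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def items(self) -> Iterable[tuple[str, EnvGrid]]:
        return self._layers.items()

    @property
    def geometry(self) -> EnvGrid:
        """A reference layer carrying the shared geometry."""
        return next(iter(self._layers.values()))

    def combined_mask(self) -> np.ndarray:
        """Union of the layers' nodata masks (True = no data anywhere)."""
        mask = np.zeros(self.shape, dtype=bool)
        for grid in self._layers.values():
            mask |= grid.nodata_mask
        return mask

    def subset(self, names: Sequence[str]) -> "GridStack":
        return GridStack({n: self._layers[n] for n in names})


# -- I/O -------------------------------------------------------------------


def write_grid(grid: EnvGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as GeoTIFF or ESRI ASCII; the format defaults from suffix."""
    path = Path(path)
    fmt = format or _format_from_suffix(path)
    if fmt == "esri_ascii":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown grid format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None) -> EnvGrid:
    """Read a single-band grid, masking nodata cells."""
    path = Path(path)
    fmt = format or _format_from_suffix(path)
    if fmt == "esri_ascii":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown grid format {fmt!r}")


def _format_from_suffix(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        return "esri_ascii"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer grid format from suffix {suffix!r}")


def _write_ascii(grid: EnvGrid, path: Path) -> None:
    cell_deg = grid.cell_deg
    xll = grid.origin_lon
    yll = grid.origin_lat - grid.nrows * cell_deg
    out = grid.values.copy()
    out[grid.nodata_mask] = ASCII_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(cell_deg)!r}\n")
        fh.write(f"NODATA_value {float(ASCII_NODATA)!r}\n")
        for row in out:
            # repr of a Python float is the shortest exact round-trip form
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: Path) -> EnvGrid:
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"bad value for header field {parts[0]!r}: {parts[1]!r}"
                ) from exc
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise GridFormatError(f"missing header field {req!r}")
    nodata = header.get("nodata_value", ASCII_NODATA)
    for line in lines[i:]:
        if line.strip():
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError as exc:
                raise GridFormatError(f"non-numeric data row: {line[:60]!r}") from exc
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise GridFormatError(
            f"data shape mismatch: header says {nrows}x{ncols}, "
            f"got {len(rows)} rows"
        )
    values = np.array(rows, dtype=np.float64)
    mask = values == nodata
    cell_min = header["cellsize"] * 60.0
    origin_lat = header["yllcorner"] + nrows * header["cellsize"]
    values = values.copy()
    values[mask] = np.nan
    return EnvGrid(values, header["xllcorner"], origin_lat, cell_min, mask)


def _write_geotiff(grid: EnvGrid, path: Path) -> None:
    import tifffile

    cell_deg = grid.cell_deg
    out = grid.values.astype(np.float32).copy()
    out[grid.nodata_mask] = np.float32(ASCII_NODATA)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cell_deg, cell_deg, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, str(ASCII_NODATA)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path) -> EnvGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            scale_value = None if scale is None else tuple(scale.value)
            tp = None if tiepoint is None else tuple(tiepoint.value)
            nodata_value = None if nodata_tag is None else str(nodata_tag.value)
    except Exception as exc:  # malformed file
        raise GridFormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError("only single-band rasters are supported")
    if scale_value is None or tp is None:
        raise GridFormatError("missing GeoTIFF georeference tags")
    sx, sy = float(scale_value[0]), float(scale_value[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise GridFormatError("non-square pixels are not supported")
    origin_lon = float(tp[3]) - float(tp[0]) * sx
    origin_lat = float(tp[4]) + float(tp[1]) * sy
    values = np.asarray(values, dtype=np.float64)
    if nodata_value is not None:
        nodata = float(nodata_value.strip("\x00 "))
        mask = values == nodata
    else:
        mask = ~np.isfinite(values)
    values = values.copy()
    values[mask] = np.nan
    return EnvGrid(values, origin_lon, origin_lat, sx * 60.0, mask)


# -- point operations -------------------------------------------------------


def extract_values(stack: GridStack, points: Sequence[GeoPoint]) -> pd.DataFrame:
    """Values of every layer at each point's cell (nearest cell, no interpolation).

    Points landing on a nodata cell of any layer yield a row with NaNs for the
    masked layers and ``missing=True``; points outside the extent raise.
    """
    names = stack.layer_names
    geom = stack.geometry
    n = len(points)
    data = np.empty((n, len(names)))
    missing = np.zeros(n, dtype=bool)
    for i, pt in enumerate(points):
        try:
            row, col = geom.cell_index(pt)
        except OutOfExtentError as exc:
            raise OutOfExtentError(f"point index {i}: {exc}") from exc
        for j, name in enumerate(names):
            grid = stack[name]
            if grid.nodata_mask[row, col]:
                data[i, j] = np.nan
                missing[i] = True
            else:
                data[i, j] = grid.values[row, col]
    df = pd.DataFrame(data, columns=names)
    df["missing"] = missing
    return df


def sample_random_points(
    mask_grid: EnvGrid, n: int, seed: int
) -> list[GeoPoint]:
    """Uniform random points over the valid cells of ``mask_grid``.

    A cell is drawn uniformly among valid (unmasked) cells, then the point is
    jittered uniformly within the cell; the half-open cell convention means
    jitter stays strictly inside the chosen cell.
    """
    valid = np.flatnonzero(~mask_grid.nodata_mask.ravel())
    if valid.size == 0:
        raise EmptyDomainError("mask grid has no valid cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(valid, size=n, replace=True)
    rows, cols = np.unravel_index(cells, mask_grid.values.shape)
    cell_deg = mask_grid.cell_deg
    u = rng.random(n)
    v = rng.random(n)
    lons = mask_grid.origin_lon + (cols + u) * cell_deg
    lats = mask_grid.origin_lat - (rows + v) * cell_deg
    return [GeoPoint(float(lo), float(la)) for lo, la in zip(lons, lats)]


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    lat1, lat2 = math.radians(a.lat), math.radians(b.lat)
    dlat = lat2 - lat1
    dlon = math.radians(b.lon - a.lon)
    s = (
        math.sin(dlat / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def pairwise_haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances, vectorized."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    s = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))
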