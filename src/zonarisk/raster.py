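"""Lightweight gridded-raster containers and text raster I/O.

Rasters are regular lon/lat grids (WGS84 decimal degrees) stored row-major
from the north-west corner, the convention of most GIS raster formats.
Files are exchanged in the ESRI ASCII grid format (``.asc``): a six-line
header (``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize``,
``NODATA_value``) followed by whitespace-separated cell values, readable by
QGIS/ArcGIS/GDAL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Georeferencing of a regular grid: upper-left corner and cell size.

    ``origin_lon``/``origin_lat`` are the coordinates of the *outer corner*
    of the top-left cell; ``cell_size`` is in decimal degrees and applies to
    both axes. Row index grows southward, column index eastward.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.nrows}x{self.ncols}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat of the center(s) of cell(s) ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D arrays of cell-center lon and lat for the full grid."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.cell_center(rows, cols)

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each lon/lat point."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.index_of(lon, lat)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)


@dataclass
class RasterGrid:
    """A single-band raster: values, georeferencing and a nodata mask.

    ``mask`` is True where the cell holds NO data (numpy.ma convention).
    """

    values: np.ndarray
    transform: GridTransform
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.transform.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match transform "
                f"shape {self.transform.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """Same grid and mask, new cell values."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            mask=self.mask.copy(),
            units=self.units if units is None else units,
        )

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.transform == other.transform


def write_ascii_grid(raster: RasterGrid, path: str | Path, fmt: str = "%.6g") -> Path:
    """Write a raster as an ESRI ASCII grid with nodata = -9999."""
    path = Path(path)
    t = raster.transform
    vals = np.where(raster.mask, NODATA, raster.values)
    header = (
        f"ncols {t.ncols}\n"
        f"nrows {t.nrows}\n"
        f"xllcorner {t.origin_lon!r}\n"
        f"yllcorner {t.origin_lat - t.nrows * t.cell_size!r}\n"
        f"cellsize {t.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, units: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or a GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", NODATA)
    transform = GridTransform(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nrows=nrows,
        ncols=ncols,
    )
    mask = vals == nodata
    values = np.where(mask, np.nan, vals)
    return RasterGrid(values=values, transform=transform, mask=mask, units=units)


class PredictorStack:
    """An ordered collection of co-registered, named raster layers.

    All layers must share one :class:`GridTransform`; the stack's combined
    validity is the intersection of the per-layer valid masks (a cell is
    usable only where every layer holds data).
    """

    def __init__(self, layers: Mapping[str, RasterGrid]):
        if not layers:
            raise ValueError("a PredictorStack needs at least one layer")
        self._layers: dict[str, RasterGrid] = dict(layers)
        names = list(self._layers)
        ref = self._layers[names[0]].transform
        for name, layer in self._layers.items():
            if layer.transform != ref:
                raise ValueError(
                    f"layer {name!r} transform {layer.transform} differs from "
                    f"{names[0]!r} transform {ref}"
                )
        self.transform = ref

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    @property
    def valid(self) -> np.ndarray:
        """Cells valid in every layer."""
        v = np.ones(self.transform.shape, dtype=bool)
        for layer in self._layers.values():
            v &= layer.valid
        return v

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return PredictorStack({n: self._layers[n] for n in names})

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at the given cells."""
        return np.column_stack(
            [self._layers[n].values[rows, cols] for n in self._layers]
        )

    def values_3d(self) -> np.ndarray:
        """(n_layers, nrows, ncols) array of all layer values."""
        return np.stack([self._layers[n].values for n in self._layers])

    def replace_layers(self, new: Mapping[str, np.ndarray]) -> "PredictorStack":
        """Stack with some layers' values replaced (grid and masks kept)."""
        layers = {}
        for name, layer in self._layers.items():
            if name in new:
                layers[name] = layer.with_values(new[name])
            else:
                layers[name] = layer
        return PredictorStack(layers)

    def write_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        return [
            write_ascii_grid(layer, directory / f"{name}.asc")
            for name, layer in self._layers.items()
        ]

    @classmethod
    def read_dir(cls, directory: str | Path, names: list[str] | None = None) -> "PredictorStack":
        directory = Path(directory)
        if names is None:
            names = sorted(p.stem for p in directory.glob("*.asc"))
        if not names:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        return cls({n: read_ascii_grid(directory / f"{n}.asc") for n in names})
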