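"""Co-registered monthly environmental grids and per-record value attachment.

Rasters are exchanged in a plain-text single-band dialect modelled on the
ESRI ASCII grid, with cell-center registration::

    ncols 10
    nrows 8
    xllcenter -10.0
    yllcenter 30.0
    cellsize 0.5
    nodata_value -9999.0
    <nrows data rows, northernmost first, ncols whitespace-separated values>

``xllcenter``/``yllcenter`` give the lon/lat of the *center* of the
lower-left (south-west) cell.  A stack bundles one such grid per
(variable, month); all layers must share shape, origin and cell size.

"Nearest" is evaluated in degrees on the lon/lat plane.  At ~5-km cells
inside the western-Palearctic window this planar approximation displaces the
chosen cell by at most a fraction of a cell and is the documented behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import RecordSet

VARIABLES = ("LST", "NDVI", "Tmin", "Tmax", "rain")


@dataclass(frozen=True)
class GridGeometry:
    """Shape and placement of a raster grid (cell-center registered)."""

    ncols: int
    nrows: int
    xllcenter: float
    yllcenter: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def matches(self, other: "GridGeometry", rtol: float = 1e-9) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and math.isclose(self.xllcenter, other.xllcenter, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.yllcenter, other.yllcenter, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol, abs_tol=1e-12)
        )

    # Arrays are stored [row, col] with row 0 the northernmost row.
    def lon_of_col(self, col: np.ndarray | int) -> np.ndarray | float:
        return self.xllcenter + np.asarray(col) * self.cellsize

    def lat_of_row(self, row: np.ndarray | int) -> np.ndarray | float:
        return self.yllcenter + (self.nrows - 1 - np.asarray(row)) * self.cellsize

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the nearest cell center, or None outside the extent.

        Fractional indices are rounded half-down so that a point equidistant
        from two centers goes to the lower (row, col) index.
        """
        fc = (lon - self.xllcenter) / self.cellsize
        fr = ((self.yllcenter + (self.nrows - 1) * self.cellsize) - lat) / self.cellsize
        col = int(math.ceil(fc - 0.5))
        row = int(math.ceil(fr - 0.5))
        if not (0 <= col < self.ncols and 0 <= row < self.nrows):
            return None
        return row, col

    def cell_polygon_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of one cell's footprint."""
        lon = float(self.lon_of_col(col))
        lat = float(self.lat_of_row(row))
        h = self.cellsize / 2.0
        return lon - h, lon + h, lat - h, lat + h


@dataclass
class RasterStack:
    """Co-registered monthly layers keyed by (variable, month)."""

    geometry: GridGeometry
    layers: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def add(self, variable: str, month: int, values: np.ndarray, source: str = "") -> None:
        if not 1 <= month <= 12:
            raise ValueError(f"month {month} outside 1..12")
        key = (variable, month)
        if key in self.layers:
            raise ValueError(f"duplicate layer ({variable}, {month})")
        values = np.asarray(values, dtype=float)
        if values.shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError(
                f"layer ({variable}, {month}){' from ' + source if source else ''}: "
                f"shape {values.shape} does not match grid "
                f"({self.geometry.nrows}, {self.geometry.ncols})"
            )
        self.layers[key] = values

    @property
    def variables(self) -> list[tuple[str, int]]:
        """Layer keys in canonical (variable, month) order."""
        return sorted(self.layers)

    def valid_mask(self, keys: Sequence[tuple[str, int]] | None = None) -> np.ndarray:
        """Boolean grid of cells with data in every requested layer."""
        keys = self.variables if keys is None else list(keys)
        mask = np.ones((self.geometry.nrows, self.geometry.ncols), dtype=bool)
        for key in keys:
            mask &= self.layers[key] != self.geometry.nodata
        return mask

    def to_matrix(
        self, keys: Sequence[tuple[str, int]] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
        """Flatten valid cells to a (cells x variables) matrix.

        Returns ``(matrix, flat_valid_mask, keys)``; the mask indexes the
        row-major flattened grid so matrix rows can be mapped back to cells.
        """
        keys = self.variables if keys is None else list(keys)
        mask = self.valid_mask(keys).ravel()
        cols = [self.layers[k].ravel()[mask] for k in keys]
        return np.column_stack(cols) if cols else np.empty((0, 0)), mask, keys


# ---------------------------------------------------------------------------
# Plain-text grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcenter", "yllcenter", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read one single-band plain-text grid (northernmost row first)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    missing = [k for k in _HEADER_KEYS[:5] if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header key(s) {missing}")
    geom = GridGeometry(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcenter=header["xllcenter"],
        yllcenter=header["yllcenter"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if data.shape != (geom.nrows, geom.ncols):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header "
            f"({geom.nrows}, {geom.ncols})"
        )
    return geom, data


def write_ascii_grid(path: str | Path, geom: GridGeometry, values: np.ndarray) -> None:
    values = np.asarray(values)
    if values.shape != (geom.nrows, geom.ncols):
        raise ValueError("values shape does not match geometry")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {geom.ncols}\n")
        fh.write(f"nrows {geom.nrows}\n")
        fh.write(f"xllcenter {geom.xllcenter!r}\n")
        fh.write(f"yllcenter {geom.yllcenter!r}\n")
        fh.write(f"cellsize {geom.cellsize!r}\n")
        fh.write(f"nodata_value {geom.nodata!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_grid(
    entries: Iterable[tuple[str | Path, str, int]] | str | Path,
) -> RasterStack:
    """Assemble a RasterStack from a manifest.

    ``entries`` is either an iterable of ``(path, variable, month)`` tuples or
    the path of a manifest CSV with lines ``path,variable,month`` (paths
    relative to the manifest).  Layers failing co-registration raise a
    ``ValueError`` naming the offending file.
    """
    if isinstance(entries, (str, Path)):
        manifest = Path(entries)
        parsed: list[tuple[Path, str, int]] = []
        for line in manifest.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p, var, month = (tok.strip() for tok in line.split(","))
            parsed.append((manifest.parent / p, var, int(month)))
        entries = parsed
    stack: RasterStack | None = None
    for path, variable, month in entries:
        geom, data = read_ascii_grid(path)
        if stack is None:
            stack = RasterStack(geometry=geom)
        elif not stack.geometry.matches(geom):
            raise ValueError(
                f"layer {path} ({variable}, {month}) is not co-registered with "
                f"the stack: {geom} vs {stack.geometry}"
            )
        stack.add(variable, month, data, source=str(path))
    if stack is None:
        raise ValueError("empty manifest: no layers to read")
    return stack


def write_stack(stack: RasterStack, directory: str | Path) -> Path:
    """Write every layer plus a ``manifest.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with manifest.open("w", encoding="utf-8") as fh:
        for (var, month), values in sorted(stack.layers.items()):
            name = f"{var}_{month:02d}.grd"
            write_ascii_grid(directory / name, stack.geometry, values)
            fh.write(f"{name},{var},{month}\n")
    return manifest


# ---------------------------------------------------------------------------
# Environmental attachment
# ---------------------------------------------------------------------------


@dataclass
class EnvVector:
    """Monthly environmental values attached to one record.

    ``complete`` is true iff every requested layer resolved to data;
    ``inside`` is false when the point falls outside the grid extent (no
    value is fabricated in that case).
    """

    index: int
    values: dict[tuple[str, int], float] = field(default_factory=dict)
    complete: bool = False
    inside: bool = True


def attach_environment(
    rs: RecordSet | Sequence, stack: RasterStack,
    keys: Sequence[tuple[str, int]] | None = None,
) -> list[EnvVector]:
    """Attach each record's nearest-cell value for every (variable, month).

    Accepts a RecordSet or any sequence of objects with ``lon``/``lat``.
    Points on nodata cells yield ``complete=False``; points outside the
    extent yield ``inside=False`` with no values.
    """
    keys = stack.variables if keys is None else list(keys)
    geom = stack.geometry
    records = rs.records if isinstance(rs, RecordSet) else list(rs)
    out: list[EnvVector] = []
    for i, rec in enumerate(records):
        cell = geom.nearest_cell(rec.lon, rec.lat)
        if cell is None:
            out.append(EnvVector(index=i, inside=False, complete=False))
            continue
        row, col = cell
        values: dict[tuple[str, int], float] = {}
        complete = True
        for key in keys:
            v = float(stack.layers[key][row, col])
            values[key] = v
            if v == geom.nodata:
                complete = False
        out.append(EnvVector(index=i, values=values, complete=complete))
    return out


def env_matrix(
    vectors: Sequence[EnvVector], keys: Sequence[tuple[str, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack complete EnvVectors into a matrix.

    Returns ``(matrix, used_mask)`` where ``used_mask[i]`` marks vectors that
    were inside the extent and complete (incomplete vectors are excluded, the
    default policy for downstream ordination).
    """
    used = np.array([v.inside and v.complete for v in vectors], dtype=bool)
    rows = [[v.values[k] for k in keys] for v in vectors if v.inside and v.complete]
    mat = np.asarray(rows, dtype=float) if rows else np.empty((0, len(keys)))
    return mat, used
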