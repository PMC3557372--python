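"""Hexagonal binning of records for geographic occurrence summaries.

Records are aggregated into a lattice of pointy-top hexagons addressed by
axial coordinates (q, r_ax).  "0.5 degree resolution" is interpreted as the
horizontal center-to-center spacing of adjacent hexagons in a row; lon/lat
are treated as a plane, a cartographic approximation adequate for display
and summary at this scale.

Point-to-hexagon assignment uses the standard fractional-axial transform
followed by cube rounding; ties on hexagon edges resolve deterministically
through IEEE round-half-to-even inside the cube rounding, so assignment is
stable across runs and record orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import RecordSet

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class HexGrid:
    """Pointy-top hexagon lattice on the lon/lat plane."""

    spacing: float = 0.5          # degrees between adjacent column centers
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def size(self) -> float:
        """Hexagon circumradius; pointy-top width = sqrt(3) * size = spacing."""
        return self.spacing / SQRT3


def hex_assign(lon: float, lat: float, grid: HexGrid) -> tuple[int, int]:
    """Axial (q, r_ax) address of the hexagon containing a point."""
    if not (math.isfinite(lon) and math.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    x = lon - grid.origin[0]
    y = lat - grid.origin[1]
    s = grid.size
    qf = (SQRT3 / 3.0 * x - y / 3.0) / s
    rf = (2.0 / 3.0 * y) / s
    return _cube_round(qf, rf)


def _cube_round(qf: float, rf: float) -> tuple[int, int]:
    sf = -qf - rf
    q, r, c = round(qf), round(rf), round(sf)
    dq, dr, dc = abs(q - qf), abs(r - rf), abs(c - sf)
    if dq > dr and dq > dc:
        q = -r - c
    elif dr > dc:
        r = -q - c
    return int(q), int(r)


def hex_center(q: int, r_ax: int, grid: HexGrid) -> tuple[float, float]:
    """(lon, lat) of a hexagon's center."""
    s = grid.size
    lon = grid.origin[0] + s * SQRT3 * (q + r_ax / 2.0)
    lat = grid.origin[1] + s * 1.5 * r_ax
    return lon, lat


def hex_percentages(rs: RecordSet, grid: HexGrid | None = None) -> pd.DataFrame:
    """Per-species, per-hexagon record counts and percentages.

    Returns one row per non-empty (species, cell): columns ``species``,
    ``q``, ``r_ax``, ``center_lon``, ``center_lat``, ``n`` and ``percent``
    (= 100 * n / species total).  Species with zero records are simply
    absent.  Assignment is invariant to record order.
    """
    grid = grid or HexGrid()
    counts: dict[tuple[str, int, int], int] = {}
    totals: dict[str, int] = {}
    for rec in rs.records:
        species = rec.species or rec.species_raw
        q, r_ax = hex_assign(rec.lon, rec.lat, grid)
        counts[(species, q, r_ax)] = counts.get((species, q, r_ax), 0) + 1
        totals[species] = totals.get(species, 0) + 1
    rows = []
    for (species, q, r_ax), n in sorted(counts.items()):
        lon, lat = hex_center(q, r_ax, grid)
        rows.append(
            {
                "species": species,
                "q": q,
                "r_ax": r_ax,
                "center_lon": lon,
                "center_lat": lat,
                "n": n,
                "percent": 100.0 * n / totals[species],
            }
        )
    return pd.DataFrame(
        rows, columns=["species", "q", "r_ax", "center_lon", "center_lat", "n", "percent"]
    )
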