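"""Regular latitude–longitude ocean grids.

The analyses all run on a regular grid of cells (30-arc-minute cells at full
resolution, i.e. 360 x 720, but the resolution is a parameter so tests and
examples can use tiny grids). Each cell carries its centre coordinates, its
exact spherical area, a depth, and a sea/land flag.

Cell areas use the spherical band formula

    A = R^2 * dlon * (sin(lat_top) - sin(lat_bottom))

with the mean Earth radius R = 6371 km, so the areas of a full latitude band
sum exactly to the analytic band area and the whole grid to 4*pi*R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mean Earth radius in km, used for all areas and great-circle distances.
EARTH_RADIUS_KM = 6371.0


@dataclass
class GridDefinition:
    """A regular lat/lon grid with per-cell geometry.

    Attributes
    ----------
    table:
        One row per cell with columns ``cell_id`` (0-based, row-major from
        the south-west corner), ``lat``, ``lon`` (cell-centre degrees),
        ``area_km2``, ``depth_m`` (positive down; NaN on land) and
        ``sea_mask``.
    n_lat, n_lon:
        Grid dimensions; ``len(table) == n_lat * n_lon``.
    """

    table: pd.DataFrame
    n_lat: int
    n_lon: int

    def __post_init__(self) -> None:
        if len(self.table) != self.n_lat * self.n_lon:
            raise ValueError("cell count must equal n_lat * n_lon")

    @property
    def sea_cells(self) -> np.ndarray:
        """cell_ids of sea cells."""
        t = self.table
        return t.loc[t["sea_mask"], "cell_id"].to_numpy()

    @property
    def total_area_km2(self) -> float:
        return float(self.table["area_km2"].sum())

    def cell_latlon(self, cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates (degrees) for an array of cell ids."""
        sub = self.table.set_index("cell_id").loc[np.asarray(cell_ids)]
        return sub["lat"].to_numpy(), sub["lon"].to_numpy()

    def rowcol(self, cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """0-based (row, col) of cell ids; row 0 is the southernmost band."""
        ids = np.asarray(cell_ids)
        return ids // self.n_lon, ids % self.n_lon

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def band_area_km2(lat_bottom_deg: float, lat_top_deg: float, n_lon: int) -> float:
    """Exact spherical area of one cell in the latitude band [bottom, top]."""
    dlon = 2.0 * np.pi / n_lon
    s = np.sin(np.deg2rad(lat_top_deg)) - np.sin(np.deg2rad(lat_bottom_deg))
    return float(EARTH_RADIUS_KM**2 * dlon * s)


def generate_grid(
    n_lat: int,
    n_lon: int,
    land_fraction: float = 0.0,
    depth_params: tuple[float, float] = (50.0, 5000.0),
    seed: int = 0,
) -> GridDefinition:
    """Build a seeded regular grid with random land cells and depths.

    Parameters
    ----------
    n_lat, n_lon:
        Number of latitude bands / longitude columns (>= 1 each).
    land_fraction:
        Fraction of cells flagged as land, drawn uniformly at random
        (0 <= land_fraction < 1). Land cells have no depth and no area-based
        role in any ocean sum.
    depth_params:
        ``(min_depth_m, max_depth_m)``; sea-cell depths are drawn uniformly
        from this range. Equal endpoints give a constant depth.
    seed:
        Seeds land placement and depths; the geometry itself is
        deterministic.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("n_lat and n_lon must be >= 1")
    if not 0.0 <= land_fraction < 1.0:
        raise ValueError("land_fraction must be in [0, 1)")
    lo, hi = float(depth_params[0]), float(depth_params[1])
    if lo < 0 or hi < lo:
        raise ValueError("depth_params must satisfy 0 <= min <= max")

    rng = np.random.default_rng(seed)
    n_cells = n_lat * n_lon

    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lat_centers = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_edges = np.linspace(-180.0, 180.0, n_lon + 1)
    lon_centers = 0.5 * (lon_edges[:-1] + lon_edges[1:])

    # one exact area per latitude band, repeated along longitude
    band_areas = np.array(
        [band_area_km2(lat_edges[i], lat_edges[i + 1], n_lon) for i in range(n_lat)]
    )

    lat = np.repeat(lat_centers, n_lon)
    lon = np.tile(lon_centers, n_lat)
    area = np.repeat(band_areas, n_lon)

    n_land = int(round(land_fraction * n_cells))
    sea_mask = np.ones(n_cells, dtype=bool)
    if n_land > 0:
        land_ids = rng.choice(n_cells, size=n_land, replace=False)
        sea_mask[land_ids] = False

    depth = np.full(n_cells, np.nan)
    n_sea = int(sea_mask.sum())
    if n_sea:
        depth[sea_mask] = lo if hi == lo else rng.uniform(lo, hi, size=n_sea)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "lat": lat,
            "lon": lon,
            "area_km2": area,
            "depth_m": depth,
            "sea_mask": sea_mask,
        }
    )
    return GridDefinition(table=table, n_lat=n_lat, n_lon=n_lon)


def coastal_sea_cells(grid: GridDefinition) -> np.ndarray:
    """Sea cells adjacent (rook neighbourhood) to at least one land cell.

    On an all-sea grid every sea cell counts as coastal, so worlds without
    explicit land still have ports and mariculture origins.
    """
    sea = grid.table["sea_mask"].to_numpy().reshape(grid.n_lat, grid.n_lon)
    if sea.all():
        return grid.sea_cells
    land = ~sea
    near_land = np.zeros_like(sea)
    near_land[1:, :] |= land[:-1, :]
    near_land[:-1, :] |= land[1:, :]
    # longitude wraps around
    near_land |= np.roll(land, 1, axis=1)
    near_land |= np.roll(land, -1, axis=1)
    coastal = sea & near_land
    ids = np.flatnonzero(coastal.reshape(-1))
    if ids.size == 0:  # isolated sea cells surrounded by sea diagonal only
        return grid.sea_cells
    return ids
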