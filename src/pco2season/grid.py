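"""Grid bookkeeping: polar-cap domain, spherical areas, masks, regridding.

The analysis domain in real applications is the Arctic Ocean inside its four
gateways (Barents Sea Opening, Fram/Davis/Bering straits); since those
polygon coordinates are application data, the built-in domain is an idealized
polar cap (configurable latitude) on a regular latitude-longitude grid, with
a hook to load a user-supplied domain mask instead.  Cell areas are exact
spherical-zone weights.  Regridding between regular grids is
nearest-neighbour by great-circle (chord) distance with masked sources
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GridSpec",
    "RegionMask",
    "EARTH_RADIUS_M",
    "spherical_cell_areas",
    "area_weighted_mean",
    "regrid_nearest",
    "build_masks",
]

EARTH_RADIUS_M = 6.371e6


@dataclass
class GridSpec:
    """Regular lat-lon grid with areas, land/domain masks and bottom depth."""

    lat: np.ndarray  # (nlat,) cell centers, degrees north
    lon: np.ndarray  # (nlon,) cell centers, degrees east
    cell_area: np.ndarray  # (nlat, nlon) m^2
    land_mask: np.ndarray  # True over land
    domain_mask: np.ndarray  # True inside the analysis domain (ocean only)
    depth: np.ndarray  # (nlat, nlon) bottom depth, m

    def __post_init__(self) -> None:
        shape = (self.lat.size, self.lon.size)
        for name in ("cell_area", "land_mask", "domain_mask", "depth"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match grid")
        if np.any(self.cell_area[~self.land_mask] <= 0):
            raise ValueError("ocean cell areas must be positive")
        if np.any(self.domain_mask & self.land_mask):
            raise ValueError("domain mask overlaps land")


@dataclass
class RegionMask:
    """Named sub-regions of the domain; shelf and basin partition it."""

    shelf: np.ndarray  # depth < shelf threshold
    basin: np.ndarray
    sectors: dict  # name -> boolean mask (longitude sectors of the shelf)

    def __post_init__(self) -> None:
        if np.any(self.shelf & self.basin):
            raise ValueError("shelf and basin overlap")


def spherical_cell_areas(lat, lon) -> np.ndarray:
    """Exact spherical-zone areas (m^2) for regular cell-center coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.diff(lat).mean() if lat.size > 1 else 1.0
    dlon = np.diff(lon).mean() if lon.size > 1 else 360.0
    lo = np.radians(np.clip(lat - dlat / 2.0, -90.0, 90.0))
    hi = np.radians(np.clip(lat + dlat / 2.0, -90.0, 90.0))
    band = EARTH_RADIUS_M**2 * np.radians(dlon) * (np.sin(hi) - np.sin(lo))
    return np.repeat(band[:, None], lon.size, axis=1)


def area_weighted_mean(field, mask, areas) -> float:
    """Area-weighted mean of `field` over cells where `mask` is True."""
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    areas = np.asarray(areas, dtype=float)
    if not mask.any():
        raise ValueError("mask selects no cells")
    w = areas * mask
    return float((field * w).sum() / w.sum())


def _unit_vectors(lat2d, lon2d) -> np.ndarray:
    la = np.radians(lat2d).ravel()
    lo = np.radians(lon2d).ravel()
    return np.column_stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)]
    )


def regrid_nearest(
    src_field,
    src_grid: GridSpec,
    dst_grid: GridSpec,
    cutoff_km: float | None = None,
):
    """Nearest-neighbour regridding by great-circle distance.

    Masked (land) source cells are excluded.  Destination cells with no
    unmasked source within `cutoff_km` (if given) come back as nan.
    Leading dimensions of `src_field` (e.g. months) are carried through.
    """
    src = np.asarray(src_field, dtype=float)
    nlat, nlon = src_grid.lat.size, src_grid.lon.size
    if src.shape[-2:] != (nlat, nlon):
        raise ValueError("source field does not match source grid")
    slat, slon = np.meshgrid(src_grid.lat, src_grid.lon, indexing="ij")
    ocean = ~src_grid.land_mask.ravel()
    if not ocean.any():
        raise ValueError("source grid is all land")
    tree = cKDTree(_unit_vectors(slat, slon)[ocean])
    dlat, dlon = np.meshgrid(dst_grid.lat, dst_grid.lon, indexing="ij")
    dist, idx = tree.query(_unit_vectors(dlat, dlon))
    flat_src = src.reshape(src.shape[:-2] + (nlat * nlon,))[..., ocean]
    out = flat_src[..., idx]
    if cutoff_km is not None:
        chord = 2.0 * np.sin(cutoff_km * 1e3 / (2.0 * EARTH_RADIUS_M))
        out = np.where(dist <= chord, out, np.nan)
    return out.reshape(src.shape[:-2] + (dst_grid.lat.size, dst_grid.lon.size))


def build_masks(
    lat_min: float = 70.0,
    dlat: float = 2.0,
    dlon: float = 20.0,
    shelf_lat_max: float = 78.0,
    shelf_depth: float = 200.0,
    basin_depth: float = 3000.0,
    shelf_threshold: float = 500.0,
    land_sectors: tuple = (),
) -> tuple[GridSpec, RegionMask]:
    """Idealized polar-cap grid: shelf ring equatorward, deep basin poleward.

    `land_sectors` is a tuple of (lon_west, lon_east) intervals masked as
    land on the shelf ring.  The shelf (depth < `shelf_threshold`) and the
    basin partition the domain exactly.
    """
    lat = np.arange(lat_min + dlat / 2.0, 90.0, dlat)
    lon = np.arange(-180.0 + dlon / 2.0, 180.0, dlon)
    areas = spherical_cell_areas(lat, lon)
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    depth = np.where(lat2d < shelf_lat_max, shelf_depth, basin_depth)
    land = np.zeros(lat2d.shape, dtype=bool)
    for west, east in land_sectors:
        land |= (lon2d >= west) & (lon2d <= east) & (lat2d < shelf_lat_max)
    domain = ~land
    grid = GridSpec(
        lat=lat, lon=lon, cell_area=areas, land_mask=land,
        domain_mask=domain, depth=depth,
    )
    shelf = domain & (depth < shelf_threshold)
    basin = domain & ~shelf
    sectors = {
        "barents_like": shelf & (lon2d >= 0) & (lon2d < 60),
        "kara_like": shelf & (lon2d >= 60) & (lon2d < 120),
        "chukchi_like": shelf & (lon2d >= -180) & (lon2d < -120),
    }
    return grid, RegionMask(shelf=shelf, basin=basin, sectors=sectors)
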