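"""Spherical geometry helpers shared by the simulation, weights and mapping code.

All coordinates are WGS84 longitude/latitude in decimal degrees; distances
are great-circle (haversine) metres on a sphere of mean Earth radius.
Using one metric everywhere keeps the simulated fields, the k-NN weights
and the IDW surfaces mutually consistent.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

#: Mean Earth radius (IUGG), metres.
EARTH_RADIUS_M = 6_371_008.8


def haversine(a, b) -> np.ndarray:
    """Great-circle distance in metres between lon/lat points ``a`` and ``b``.

    Parameters
    ----------
    a, b : array-like, shape (..., 2)
        Points as ``(lon, lat)`` in decimal degrees. Broadcasting applies,
        so a single pair against an (n, 2) array works.

    Returns
    -------
    ndarray or float
        Distance(s) in metres.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine(coords) -> np.ndarray:
    """Full n x n haversine distance matrix (metres) for an (n, 2) lon/lat array."""
    coords = np.asarray(coords, dtype=float)
    return haversine(coords[:, None, :], coords[None, :, :])


def geodesic_translate(coords, distance_m: float, bearing_deg: float) -> np.ndarray:
    """Move every lon/lat point by ``distance_m`` metres along ``bearing_deg``.

    Uses the direct geodesic on the sphere (bearing measured clockwise from
    north). At the sub-kilometre scales used for privacy displacement the
    translation preserves pairwise distances to well under 0.1 %.
    """
    coords = np.asarray(coords, dtype=float)
    if distance_m < 0:
        raise ConfigurationError("displacement distance must be >= 0 m")
    if distance_m == 0:
        return coords.copy()
    lon1 = np.radians(coords[..., 0])
    lat1 = np.radians(coords[..., 1])
    theta = np.radians(bearing_deg)
    delta = distance_m / EARTH_RADIUS_M
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    out = np.empty_like(coords)
    out[..., 0] = np.degrees(lon2)
    out[..., 1] = np.degrees(lat2)
    return out


def make_grid(bbox, n_cells_per_axis: int) -> np.ndarray:
    """Regular lon/lat lattice of cell centres covering ``bbox``.

    Parameters
    ----------
    bbox : (lon_min, lat_min, lon_max, lat_max)
    n_cells_per_axis : int
        Number of cells along each axis; the grid has ``n**2`` points.

    Returns
    -------
    ndarray, shape (n_cells_per_axis**2, 2)
    """
    lon_min, lat_min, lon_max, lat_max = map(float, bbox)
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ConfigurationError(f"degenerate bbox {bbox!r}")
    if n_cells_per_axis < 1:
        raise ConfigurationError("n_cells_per_axis must be >= 1")
    dx = (lon_max - lon_min) / n_cells_per_axis
    dy = (lat_max - lat_min) / n_cells_per_axis
    lons = lon_min + dx * (np.arange(n_cells_per_axis) + 0.5)
    lats = lat_min + dy * (np.arange(n_cells_per_axis) + 0.5)
    gx, gy = np.meshgrid(lons, lats)
    return np.column_stack([gx.ravel(), gy.ravel()])
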