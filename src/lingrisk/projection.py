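"""Behrmann equal-area cylindrical projection on the authalic sphere.

The Behrmann projection is the cylindrical equal-area projection with
standard parallels at 30° N/S.  On a sphere of radius ``R`` the forward
mapping is

    x = R * lambda * cos(30°)
    y = R * sin(phi) / cos(30°)

with longitude ``lambda`` and latitude ``phi`` in radians.  Because the
projection is exactly equal-area, grid cells of a fixed projected size all
cover the same true area, which is what makes per-cell richness and median
comparisons unit-consistent.
"""

from __future__ import annotations

import numpy as np

#: Authalic sphere radius in metres (the radius of the sphere with the same
#: surface area as the WGS84 ellipsoid) — the standard choice for
#: equal-area work.
AUTHALIC_RADIUS_M = 6_371_007.181

#: cos(30°), the standard-parallel scale factor.
COS_STANDARD_PARALLEL = np.cos(np.deg2rad(30.0))


def behrmann_project(lon, lat, radius: float = AUTHALIC_RADIUS_M):
    """Project geographic coordinates (degrees) to Behrmann metres.

    Parameters
    ----------
    lon, lat : array-like
        Longitude in [-180, 180] and latitude in [-90, 90] degrees.
    radius : float
        Sphere radius in metres.

    Returns
    -------
    (x, y) : ndarray pair in metres.

    Raises
    ------
    ValueError
        If any coordinate is outside the valid geographic range.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180.0 + 1e-12) or np.any(np.abs(lat) > 90.0 + 1e-12):
        raise ValueError("coordinates outside lon [-180, 180] / lat [-90, 90]")
    x = radius * np.deg2rad(lon) * COS_STANDARD_PARALLEL
    y = radius * np.sin(np.deg2rad(lat)) / COS_STANDARD_PARALLEL
    return x, y


def behrmann_inverse(x, y, radius: float = AUTHALIC_RADIUS_M):
    """Inverse projection: Behrmann metres back to (lon, lat) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.rad2deg(x / (radius * COS_STANDARD_PARALLEL))
    s = np.clip(y * COS_STANDARD_PARALLEL / radius, -1.0, 1.0)
    lat = np.rad2deg(np.arcsin(s))
    return lon, lat


def global_extent(radius: float = AUTHALIC_RADIUS_M):
    """Projected bounds (xmin, ymin, xmax, ymax) of the whole sphere."""
    xmax = radius * np.pi * COS_STANDARD_PARALLEL
    ymax = radius / COS_STANDARD_PARALLEL
    return (-xmax, -ymax, xmax, ymax)
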