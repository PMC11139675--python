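"""Planar metric projection for a small study site.

A spherical transverse-Mercator projection centred on the site keeps all
distances planar and metric. For a study area a few kilometres across the
difference from an ellipsoidal UTM projection is millimetres, far below
GPS accuracy, so the spherical form is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


@dataclass(frozen=True)
class TransverseMercator:
    """Transverse-Mercator frame centred at (``lon0``, ``lat0``) degrees.

    ``forward`` maps geographic coordinates to planar easting/northing in
    metres; ``inverse`` maps back. Both accept scalars or numpy arrays.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        b = np.cos(phi) * np.sin(lam)
        x = EARTH_RADIUS_M * np.arctanh(b)
        y = EARTH_RADIUS_M * (
            np.arctan2(np.tan(phi), np.cos(lam)) - np.radians(self.lat0)
        )
        return x, y

    def inverse(self, x, y):
        xr = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        d = np.asarray(y, dtype=float) / EARTH_RADIUS_M + np.radians(self.lat0)
        lon = self.lon0 + np.degrees(np.arctan2(np.sinh(xr), np.cos(d)))
        lat = np.degrees(np.arcsin(np.sin(d) / np.cosh(xr)))
        return lon, lat

    @classmethod
    def for_points(cls, lon, lat) -> "TransverseMercator":
        """Frame centred on the bounding box of the given coordinates."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return cls(
            lon0=float((lon.min() + lon.max()) / 2.0),
            lat0=float((lat.min() + lat.max()) / 2.0),
        )
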