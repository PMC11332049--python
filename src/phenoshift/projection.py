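"""Spherical Lambert azimuthal equal-area (LAEA) projection.

The analysis grid is defined on an equal-area plane so that every 50 x 50 km
cell covers the same ground area. The projection used here is the spherical
LAEA centred on Europe with the same centre and false origin as the standard
European LAEA grid (ETRS89-LAEA): lon0 = 10 degrees E, lat0 = 52 degrees N,
false easting 4 321 000 m, false northing 3 210 000 m. The sphere uses the
authalic Earth radius, so areas in the projected plane match areas on the
authalic sphere exactly; departures from the ellipsoidal LAEA are a few
hundred metres in position, irrelevant at 50 km cell size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic (equal-area) Earth radius in metres.
AUTHALIC_RADIUS_M = 6_371_007.1810


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Forward/inverse spherical LAEA transform.

    Parameters
    ----------
    lon0, lat0:
        Projection centre in decimal degrees.
    false_easting, false_northing:
        Offsets added to the projected coordinates (metres).
    radius:
        Sphere radius (metres).
    """

    lon0: float = 10.0
    lat0: float = 52.0
    false_easting: float = 4_321_000.0
    false_northing: float = 3_210_000.0
    radius: float = AUTHALIC_RADIUS_M
    name: str = "laea_europe"

    def forward(self, lon, lat):
        """Project geographic coordinates (degrees) to planar x, y (metres)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam = np.radians(lon - self.lon0)
        phi = np.radians(lat)
        phi0 = np.radians(self.lat0)
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # k' is singular only at the antipode of the centre; clip for safety.
        kp = np.sqrt(2.0 / np.clip(1.0 + cos_c, 1e-12, None))
        x = self.radius * kp * np.cos(phi) * np.sin(lam) + self.false_easting
        y = self.radius * kp * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        ) + self.false_northing
        return x, y

    def inverse(self, x, y):
        """Planar x, y (metres) back to geographic lon, lat (degrees)."""
        x = np.asarray(x, dtype=float) - self.false_easting
        y = np.asarray(y, dtype=float) - self.false_northing
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0.0,
                phi0,
                np.arcsin(
                    np.clip(
                        np.cos(c) * np.sin(phi0)
                        + np.where(rho == 0.0, 0.0, y * np.sin(c) * np.cos(phi0) / np.where(rho == 0.0, 1.0, rho)),
                        -1.0,
                        1.0,
                    )
                ),
            )
            lam = np.where(
                rho == 0.0,
                0.0,
                np.arctan2(
                    x * np.sin(c),
                    rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
                ),
            )
        return self.lon0 + np.degrees(lam), np.degrees(phi)
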