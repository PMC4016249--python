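"""WGS84 <-> UTM conversion.

Implements the transverse Mercator projection with the 6th-order Krüger
series in the third flattening n (Karney 2011, "Transverse Mercator with an
accuracy of a few nanometers"). Within a UTM zone the series truncation
error is sub-millimetre, far below GPS noise, and forward/inverse are
mutually consistent to well under 1e-9 degrees.

All functions accept scalars or numpy arrays of latitude/longitude in
decimal degrees and return easting/northing in metres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "utm_zone",
    "latlon_to_utm",
    "utm_to_latlon",
    "ZoneStraddleError",
]

# WGS84 ellipsoid
_A = 6378137.0              # semi-major axis, m
_F = 1.0 / 298.257223563    # flattening
_E = np.sqrt(_F * (2.0 - _F))  # first eccentricity
_N3 = _F / (2.0 - _F)       # third flattening n

_K0 = 0.9996                # UTM scale on the central meridian
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

# Rectifying radius A1 = a/(1+n) * (1 + n^2/4 + n^4/64 + n^6/256)
_A1 = _A / (1.0 + _N3) * (1.0 + _N3**2 / 4.0 + _N3**4 / 64.0 + _N3**6 / 256.0)

_n = _N3
# Karney (2011) eq. 35: conformal -> rectifying (forward) coefficients
_ALPHA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
    + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
])
# Karney (2011) eq. 36: rectifying -> conformal (inverse) coefficients
_BETA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
    - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440 + 46 * _n**5 / 105
    - 1118711 * _n**6 / 3870720,
    17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
    + 5569 * _n**6 / 90720,
    4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
    4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
    20648693 * _n**6 / 638668800,
])
_J = np.arange(1, 7)


class ZoneStraddleError(ValueError):
    """Raised when one batch of coordinates spans more than one UTM zone."""

    def __init__(self, zones):
        self.zones = sorted(set(int(z) for z in zones))
        super().__init__(
            "coordinates straddle UTM zones "
            + " and ".join(str(z) for z in self.zones)
            + "; project each zone separately"
        )


def utm_zone(lon: float) -> int:
    """UTM longitudinal zone number (1-60) for a longitude in degrees."""
    return int(np.floor((float(lon) + 180.0) / 6.0)) % 60 + 1


def _central_meridian(zone: int) -> float:
    return zone * 6.0 - 183.0


def _check_single_zone(lon):
    zones = np.floor((np.asarray(lon, dtype=float) + 180.0) / 6.0).astype(int) % 60 + 1
    uniq = np.unique(zones)
    if uniq.size > 1:
        raise ZoneStraddleError(uniq)
    return int(uniq[0])


def latlon_to_utm(lat, lon, zone: int | None = None):
    """Forward UTM projection.

    Parameters
    ----------
    lat, lon : array_like
        Geodetic coordinates, decimal degrees. ``|lat| <= 84`` (UTM domain).
    zone : int, optional
        Force a zone; by default the zone is derived from the data and all
        points must fall inside it (:class:`ZoneStraddleError` otherwise).

    Returns
    -------
    easting, northing : ndarray (m), and the zone number used.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("latitude outside UTM domain (|lat| <= 84)")
    if zone is None:
        zone = _check_single_zone(lon)
    lam = np.radians(lon - _central_meridian(zone))
    phi = np.radians(lat)

    # conformal latitude via tau' (Karney eq. 7-8)
    s = np.sin(phi)
    tau = np.tan(phi)
    sig = np.sinh(_E * np.arctanh(_E * s))
    taup = tau * np.sqrt(1.0 + sig**2) - sig * np.sqrt(1.0 + tau**2)

    xi_p = np.arctan2(taup, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(taup, np.cos(lam)))

    jxi = 2.0 * np.multiply.outer(_J, xi_p)
    jeta = 2.0 * np.multiply.outer(_J, eta_p)
    al = _ALPHA.reshape((6,) + (1,) * xi_p.ndim)
    xi = xi_p + np.sum(al * np.sin(jxi) * np.cosh(jeta), axis=0)
    eta = eta_p + np.sum(al * np.cos(jxi) * np.sinh(jeta), axis=0)

    easting = _FALSE_EASTING + _K0 * _A1 * eta
    northing = _K0 * _A1 * xi
    south = np.any(lat < 0)
    if south and np.any(lat >= 0):
        raise ValueError("mixed hemispheres in one batch")
    if south:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing, zone


def utm_to_latlon(easting, northing, zone: int, south: bool = False):
    """Inverse UTM projection; returns (lat, lon) in decimal degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not 1 <= int(zone) <= 60:
        raise ValueError(f"invalid UTM zone {zone}")
    y = northing - (_FALSE_NORTHING_SOUTH if south else 0.0)
    xi = y / (_K0 * _A1)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A1)

    jxi = 2.0 * np.multiply.outer(_J, xi)
    jeta = 2.0 * np.multiply.outer(_J, eta)
    be = _BETA.reshape((6,) + (1,) * xi.ndim)
    xi_p = xi - np.sum(be * np.sin(jxi) * np.cosh(jeta), axis=0)
    eta_p = eta - np.sum(be * np.cos(jxi) * np.sinh(jeta), axis=0)

    sh = np.sinh(eta_p)
    taup = np.sin(xi_p) / np.hypot(sh, np.cos(xi_p))
    lam = np.arctan2(sh, np.cos(xi_p))

    # Newton-solve tau from tau' (Karney eq. 19-21)
    tau = taup.copy() if hasattr(taup, "copy") else np.asarray(taup, dtype=float)
    tau = np.atleast_1d(np.array(tau, dtype=float))
    taup_a = np.atleast_1d(taup)
    for _ in range(6):
        sig = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau**2)))
        f = tau * np.sqrt(1.0 + sig**2) - sig * np.sqrt(1.0 + tau**2) - taup_a
        dtau = (np.sqrt((1.0 + sig**2) * (1.0 + tau**2)) - sig * tau) \
            * (1.0 - _E**2) * np.sqrt(1.0 + tau**2) / (1.0 + (1.0 - _E**2) * tau**2)
        tau = tau - f / dtau
    phi = np.arctan(tau).reshape(np.shape(taup))

    lat = np.degrees(phi)
    lon = np.degrees(lam) + _central_meridian(int(zone))
    if np.ndim(easting) == 0:
        return float(lat), float(lon)
    return lat, lon
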