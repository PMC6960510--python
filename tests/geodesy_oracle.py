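"""Independent transverse-Mercator oracle (Snyder / USGS PP-1395 series).

Deliberately a different formulation from the package's Krüger-series
implementation, so the two can cross-check each other to centimetre level.
"""

import math

_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_E4 = _E2 * _E2
_E6 = _E4 * _E2
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996


def snyder_utm(lat_deg: float, lon_deg: float, zone: int):
    """Forward UTM (northern hemisphere) via Snyder's series formulas."""
    lat = math.radians(lat_deg)
    lon0 = math.radians(-183.0 + 6.0 * zone)
    dlon = math.radians(lon_deg) - lon0

    sin_l, cos_l, tan_l = math.sin(lat), math.cos(lat), math.tan(lat)
    n_rad = _A / math.sqrt(1.0 - _E2 * sin_l**2)
    t = tan_l**2
    c = _EP2 * cos_l**2
    a_term = cos_l * dlon
    m = _A * (
        (1 - _E2 / 4 - 3 * _E4 / 64 - 5 * _E6 / 256) * lat
        - (3 * _E2 / 8 + 3 * _E4 / 32 + 45 * _E6 / 1024) * math.sin(2 * lat)
        + (15 * _E4 / 256 + 45 * _E6 / 1024) * math.sin(4 * lat)
        - (35 * _E6 / 3072) * math.sin(6 * lat)
    )
    easting = _K0 * n_rad * (
        a_term
        + (1 - t + c) * a_term**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_term**5 / 120
    ) + 500000.0
    northing = _K0 * (
        m
        + n_rad * tan_l * (
            a_term**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a_term**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a_term**6 / 720
        )
    )
    return easting, northing
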