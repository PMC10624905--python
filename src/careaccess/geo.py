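"""Spherical geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

#: Length of one degree of latitude on the sphere, km (2*pi*R / 360).
KM_PER_DEG_LAT = 2.0 * np.pi * EARTH_RADIUS_KM / 360.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
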