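"""Great-circle helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = 111.32


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def km_offset_to_degrees(east_km, north_km, ref_lat):
    """Convert a planar (east, north) km offset to (dlat, dlon) degrees.

    Small-extent approximation: 1 deg lat = 111.32 km, lon scaled by cos(lat).
    Not valid near the poles or across the antimeridian.
    """
    dlat = north_km / KM_PER_DEG_LAT
    dlon = east_km / (KM_PER_DEG_LAT * np.cos(np.radians(ref_lat)))
    return dlat, dlon
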