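"""Great-circle geometry on a spherical Earth (R = 6371.0 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees.

    Vectorised: accepts scalars or broadcastable arrays. Symmetric,
    non-negative, and zero iff the coordinates coincide.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2))
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lat1))
            and np.all(np.isfinite(lon2)) and np.all(np.isfinite(lat2))):
        raise ValueError("coordinates must be finite")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    if d.ndim == 0:
        return float(d)
    return d
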