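"""Great-circle geometry on the sphere.

All geographic distances in this package come through :func:`haversine`,
computed on a sphere of radius 6,371,000 m (the mean Earth radius). Inputs
are decimal degrees, longitude first.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance between points, in the units of ``radius``.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding for antipodal/identical points
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
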