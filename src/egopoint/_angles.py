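"""Pure angle/vector geometry shared by the data model and circular statistics.

World frame is ENU (East, North, Up).  Body azimuth is measured from the
participant's facing direction, positive to the right (clockwise seen from
above), wrapped to (-180, 180].  Elevation is measured from the horizontal
plane, positive up, in [-90, 90].
"""

from __future__ import annotations

import numpy as np

# Azimuth is meaningless closer than this to the poles (straight up/down).
AZIMUTH_UNDEFINED_ELEVATION_DEG = 89.9


def wrap_deg(angle_deg):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = (a + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle_deg) or getattr(angle_deg, "ndim", 1) == 0:
        return float(wrapped)
    return wrapped


def enu_to_azel(e, n, u, facing_heading_deg=0.0):
    """Convert ENU unit-vector components to (body azimuth, elevation) degrees.

    The compass heading of the horizontal projection is atan2(e, n), degrees
    clockwise from North; body azimuth subtracts the facing heading.
    Elevation is asin(u).  Components need not be exactly unit norm; they are
    normalised first.  Raises on a zero vector.
    """
    e, n, u = float(e), float(n), float(u)
    norm = float(np.sqrt(e * e + n * n + u * u))
    if norm < 1e-12:
        raise ValueError("zero pointing vector has no direction")
    e, n, u = e / norm, n / norm, u / norm
    elevation = float(np.degrees(np.arcsin(np.clip(u, -1.0, 1.0))))
    heading = float(np.degrees(np.arctan2(e, n)))
    azimuth = wrap_deg(heading - facing_heading_deg)
    return azimuth, elevation


def azel_to_enu(azimuth_deg, elevation_deg, facing_heading_deg=0.0):
    """Convert (body azimuth, elevation) degrees to an ENU unit vector."""
    heading = np.radians(azimuth_deg + facing_heading_deg)
    el = np.radians(elevation_deg)
    ce = np.cos(el)
    return (
        float(np.sin(heading) * ce),
        float(np.cos(heading) * ce),
        float(np.sin(el)),
    )


def azimuth_defined(elevation_deg) -> bool:
    """Whether azimuth is analysable at this elevation (not near a pole)."""
    return abs(float(elevation_deg)) <= AZIMUTH_UNDEFINED_ELEVATION_DEG


def great_circle_deg(az1, el1, az2, el2):
    """Great-circle angle in degrees between two (azimuth, elevation) directions."""
    v1 = np.array(azel_to_enu(az1, el1))
    v2 = np.array(azel_to_enu(az2, el2))
    # atan2 form keeps full precision for nearly parallel vectors
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)),
                                       np.dot(v1, v2))))
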