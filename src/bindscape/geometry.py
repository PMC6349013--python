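"""Anchored geographic coordinate system on the protein surface.

The analysis treats the protein as a globe: an origin atom (for PDE2A, the
catalytic-pocket Zn2+) anchors the center, the X axis points toward one
anchor C-alpha, the Y axis is the second anchor direction orthogonalized
against X, and Z completes a right-handed system.  A ligand center of mass is
projected radially from the origin onto the unit sphere and reported as a
latitude/longitude pair, exactly like geographic coordinates: latitude is the
angle above the equatorial (XY) plane, longitude the angle from the prime
meridian (XZ half-plane through +X), positive eastward.

Because the projection is radial, the geographic position depends only on the
direction origin->point, never on its distance, so the irregular molecular
surface never needs to be triangulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FrameDegeneracyError, ProjectionUndefinedError

__all__ = [
    "ReferenceFrame",
    "GeoPosition",
    "build_frame",
    "to_geographic",
    "geo_to_unit",
    "geolabel",
    "angular_distance",
    "slerp",
    "circular_mean",
]

_TOL = 1e-12


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal frame anchored at the pocket origin.

    Attributes
    ----------
    origin : (3,) ndarray, Å
    ex, ey, ez : (3,) unit ndarrays
        The X, Y and Z axes. ``det[ex ey ez] = +1``.
    """

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray

    def __post_init__(self):
        for name in ("origin", "ex", "ey", "ez"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are (ex, ey, ez); maps world to frame coords."""
        return np.vstack([self.ex, self.ey, self.ez])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World coordinates -> frame coordinates (origin-centred)."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        """Frame coordinates -> world coordinates."""
        return np.asarray(points, dtype=float) @ self.rotation + self.origin


@dataclass(frozen=True)
class GeoPosition:
    """Latitude/longitude in degrees: lat in [-90, +90], lon in [-180, +180).

    Either pole carries lon = 0 by convention.
    """

    lat: float
    lon: float

    def __post_init__(self):
        object.__setattr__(self, "lat", float(self.lat))
        object.__setattr__(self, "lon", float(self.lon))


def _normalize_lon(lon: float) -> float:
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon


def build_frame(origin, x_anchor, y_anchor) -> ReferenceFrame:
    """Build the anchored frame from the origin and two axis-anchor atoms.

    ``ex`` points exactly along origin->x_anchor; ``ey`` is origin->y_anchor
    Gram-Schmidt-orthogonalized against ``ex`` (the two anchor lines of a real
    protein are generally not orthogonal); ``ez = ex x ey``.

    Raises
    ------
    FrameDegeneracyError
        If an anchor coincides with the origin or the anchors are collinear.
    """
    origin = np.asarray(origin, dtype=float)
    vx = np.asarray(x_anchor, dtype=float) - origin
    vy = np.asarray(y_anchor, dtype=float) - origin
    nx = np.linalg.norm(vx)
    ny = np.linalg.norm(vy)
    if nx < _TOL or ny < _TOL:
        raise FrameDegeneracyError("anchor coincides with the origin")
    ex = vx / nx
    vy_perp = vy - np.dot(vy, ex) * ex
    ny_perp = np.linalg.norm(vy_perp)
    if ny_perp < _TOL * ny:
        raise FrameDegeneracyError("anchors are collinear with the origin")
    ey = vy_perp / ny_perp
    ez = np.cross(ex, ey)
    return ReferenceFrame(origin=origin, ex=ex, ey=ey, ez=ez)


def to_geographic(frame: ReferenceFrame, point) -> GeoPosition:
    """Radially project a 3D point onto the globe and return lat/lon.

    lat = asin(d.ez), lon = atan2(d.ey, d.ex) with d the unit vector from the
    origin to the point; independent of the distance |point - origin|.
    """
    d = np.asarray(point, dtype=float) - frame.origin
    r = np.linalg.norm(d)
    if r < _TOL:
        raise ProjectionUndefinedError("point coincides with the frame origin")
    d = d / r
    z = float(np.clip(np.dot(d, frame.ez), -1.0, 1.0))
    lat = float(np.degrees(np.arcsin(z)))
    x = float(np.dot(d, frame.ex))
    y = float(np.dot(d, frame.ey))
    if abs(lat) >= 90.0 - 1e-12 or (abs(x) < _TOL and abs(y) < _TOL):
        lon = 0.0  # poles carry longitude 0
    else:
        lon = _normalize_lon(float(np.degrees(np.arctan2(y, x))))
    return GeoPosition(lat=lat, lon=lon)


def geo_to_unit(g: GeoPosition) -> np.ndarray:
    """Unit direction (frame coordinates) of a geographic position."""
    lat = np.radians(g.lat)
    lon = np.radians(g.lon)
    return np.array(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def geolabel(g: GeoPosition) -> str:
    """Hemisphere-labelled string, e.g. ``(30, -60) -> "30° N, 60° W"``.

    Non-negative boundary values (equator, prime meridian) are labelled
    N / E.  Magnitudes are printed with trailing zeros trimmed.
    """

    def fmt(value: float) -> str:
        text = f"{abs(value):.6f}".rstrip("0").rstrip(".")
        return text

    ns = "N" if g.lat >= 0 else "S"
    ew = "E" if g.lon >= 0 else "W"
    return f"{fmt(g.lat)}° {ns}, {fmt(g.lon)}° {ew}"


def angular_distance(a: GeoPosition, b: GeoPosition) -> float:
    """Great-circle angular distance in degrees."""
    dot = float(np.clip(np.dot(geo_to_unit(a), geo_to_unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def slerp(a: GeoPosition, b: GeoPosition, n: int) -> list[GeoPosition]:
    """``n`` evenly spaced points along the great-circle segment a->b
    (endpoints included)."""
    ua, ub = geo_to_unit(a), geo_to_unit(b)
    omega = np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0))
    ts = np.linspace(0.0, 1.0, n)
    out = []
    for t in ts:
        if omega < 1e-12:
            v = ua
        else:
            v = (np.sin((1 - t) * omega) * ua + np.sin(t * omega) * ub) / np.sin(omega)
        v = v / np.linalg.norm(v)
        out.append(_unit_to_geo(v))
    return out


def circular_mean(positions: list[GeoPosition]) -> GeoPosition:
    """Spherical mean: normalized sum of the unit direction vectors."""
    if not positions:
        raise ValueError("empty position list")
    v = np.sum([geo_to_unit(g) for g in positions], axis=0)
    n = np.linalg.norm(v)
    if n < _TOL:
        raise ValueError("degenerate (antipodal) position set has no mean")
    return _unit_to_geo(v / n)


def _unit_to_geo(d: np.ndarray) -> GeoPosition:
    lat = float(np.degrees(np.arcsin(np.clip(d[2], -1.0, 1.0))))
    if abs(lat) >= 90.0 - 1e-12:
        lon = 0.0
    else:
        lon = _normalize_lon(float(np.degrees(np.arctan2(d[1], d[0]))))
    return GeoPosition(lat=lat, lon=lon)
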