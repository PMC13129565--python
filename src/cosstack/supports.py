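"""Space-time supports at the two misaligned resolutions.

Exposure observations are *point-referenced and interval-aggregated*: a planar
site together with a time interval over which the measurement was averaged
(e.g., a monitoring station reporting monthly means).  Outcomes are
*block-referenced*: a polygon together with a time interval (e.g., a county
and a year).  The latent process lives at exact space-time coordinates, and
every observed quantity is an average of it over one of these supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely import wkt as _wkt


__all__ = [
    "KernelParams",
    "TimeInterval",
    "PointSupport",
    "BlockSupport",
    "PredPoint",
    "PolygonSampleCache",
    "polygon_from_wkt",
    "polygon_from_geojson",
]


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class KernelParams:
    """Separable spatial-temporal correlation parameters plus noise ratio.

    Parameters
    ----------
    phi1
        Spatial decay of the isotropic Matérn correlation (inverse distance
        units).  Larger values mean shorter spatial range.
    nu
        Matérn smoothness.  ``nu=0.5`` is the exponential correlation.
    phi2
        Temporal decay of the exponential correlation (inverse time units).
    delta2
        Noise-to-process variance ratio: the measurement-error variance of an
        interval-averaged observation is ``delta2 * sigma2 / |interval|``.

    One ``KernelParams`` instance identifies one candidate model in the
    stacking ensemble.
    """

    phi1: float
    nu: float
    phi2: float
    delta2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi1", _require_positive("phi1", self.phi1))
        object.__setattr__(self, "nu", _require_positive("nu", self.nu))
        object.__setattr__(self, "phi2", _require_positive("phi2", self.phi2))
        object.__setattr__(self, "delta2", _require_positive("delta2", self.delta2))

    def label(self) -> str:
        return (
            f"phi1={self.phi1:g}, nu={self.nu:g}, "
            f"phi2={self.phi2:g}, delta2={self.delta2:g}"
        )


@dataclass(frozen=True)
class TimeInterval:
    """A closed time interval ``(a, b)`` with positive length ``b - a``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        a, b = float(self.a), float(self.b)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("interval endpoints must be finite")
        if not a < b:
            raise ValueError(f"need a < b, got ({a}, {b}); zero-width intervals rejected")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def length(self) -> float:
        return self.b - self.a

    def midpoint(self) -> float:
        return 0.5 * (self.a + self.b)

    def overlap(self, other: "TimeInterval") -> float:
        return max(0.0, min(self.b, other.b) - max(self.a, other.a))


@dataclass(frozen=True)
class PointSupport:
    """A point-referenced, interval-aggregated support (site, interval)."""

    site: tuple[float, float]
    interval: TimeInterval

    def __post_init__(self) -> None:
        x, y = (float(v) for v in self.site)
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("site coordinates must be finite")
        object.__setattr__(self, "site", (x, y))


@dataclass(frozen=True)
class PredPoint:
    """An exact space-time coordinate at which to predict the latent process."""

    site: tuple[float, float]
    time: float

    def __post_init__(self) -> None:
        x, y = (float(v) for v in self.site)
        t = float(self.time)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(t)):
            raise ValueError("prediction coordinates must be finite")
        object.__setattr__(self, "site", (x, y))
        object.__setattr__(self, "time", t)


@dataclass(frozen=True)
class BlockSupport:
    """A block-referenced support: a planar polygon and a time interval."""

    polygon: Polygon
    interval: TimeInterval

    def __post_init__(self) -> None:
        poly = self.polygon
        if not isinstance(poly, Polygon):
            raise TypeError("polygon must be a shapely Polygon")
        if not poly.is_valid:
            raise ValueError("polygon is invalid (self-intersecting?)")
        if poly.area <= 0.0:
            raise ValueError("polygon must have positive area")

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def volume(self) -> float:
        """Space-time volume |B| * |I| controlling outcome-noise heteroskedasticity."""
        return self.polygon.area * self.interval.length()


def polygon_from_wkt(text: str) -> Polygon:
    poly = _wkt.loads(text)
    if not isinstance(poly, Polygon):
        raise ValueError(f"expected a POLYGON WKT, got {poly.geom_type}")
    return poly


def polygon_from_geojson(record: dict) -> Polygon:
    """Build a polygon from a GeoJSON-style geometry mapping."""
    geom = shapely.geometry.shape(record)
    if not isinstance(geom, Polygon):
        raise ValueError(f"expected a Polygon geometry, got {geom.geom_type}")
    return geom


@dataclass
class PolygonSampleCache:
    """Uniform within-polygon Monte Carlo sample, fixed and reused.

    The same point cloud is reused for every covariance entry touching the
    polygon, which makes Monte Carlo block covariances exact covariances of
    finite averages (hence symmetric and positive semidefinite up to the
    self-consistency of the approximation).
    """

    polygon: Polygon
    seed: int
    n_mc: int
    points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_mc < 1:
            raise ValueError("n_mc must be at least 1")
        if self.polygon.area <= 0.0:
            raise ValueError("cannot sample from a degenerate polygon")
        self.points = _uniform_in_polygon(self.polygon, self.n_mc, self.seed)


def _uniform_in_polygon(poly: Polygon, n: int, seed: int) -> np.ndarray:
    """Rejection-sample ``n`` uniform points inside ``poly`` (reproducibly)."""
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance rate = area / bbox area; Voronoi cells and county-like shapes
    # are well above 0.1, so this terminates quickly
    while filled < n:
        m = max(2 * (n - filled), 64)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = cand[inside]
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out
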