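"""Constructive geometry: vectorised primitives, regions and point/ray queries.

The phantom is a set of prioritised material regions, each a boolean
combination of elementary surfaces (spheres, axis-aligned boxes/ellipsoids,
arbitrary half-spaces), the same modelling vocabulary as general-purpose
transport codes.  Overlaps are resolved by integer priority: the
highest-priority region containing a point claims it.

All hot-path queries (`region_index`, `nearest_crossing`) are vectorised over
``(N, 3)`` point/direction arrays; scalar conveniences (`region_at`,
`distance_to_boundary`) wrap them for the public module surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import Material

__all__ = [
    "WORLD_EXIT",
    "Sphere",
    "Ellipsoid",
    "Box",
    "HalfSpace",
    "Polytope",
    "Intersection",
    "Union",
    "Region",
    "Geometry",
]

#: Sentinel region id returned for points/rays leaving the modelled world.
WORLD_EXIT = "<world-exit>"

_EPS = 1e-9


def _as_points(p):
    p = np.asarray(p, dtype=float)
    return p.reshape(1, 3) if p.ndim == 1 else p


class Shape:
    """Interface: vectorised membership and candidate ray crossings."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # (N,3) -> (N,) bool
        raise NotImplementedError

    def primitives(self) -> list["Shape"]:
        return [self]

    def ray_ts(self, origins, directions) -> np.ndarray:
        """Candidate boundary crossings, shape (N, k); np.inf pads misses."""
        raise NotImplementedError

    def bounds(self):
        """Axis-aligned bounding box ``(lo, hi)`` or None if unbounded."""
        return None


@dataclass(frozen=True)
class Sphere(Shape):
    center: tuple
    radius: float

    def contains(self, points):
        d = _as_points(points) - np.asarray(self.center)
        return np.einsum("ij,ij->i", d, d) <= self.radius**2 + _EPS

    def ray_ts(self, origins, directions):
        o = _as_points(origins) - np.asarray(self.center)
        d = _as_points(directions)
        b = np.einsum("ij,ij->i", o, d)
        c = np.einsum("ij,ij->i", o, o) - self.radius**2
        disc = b * b - c
        sq = np.sqrt(np.maximum(disc, 0.0))
        t1 = -b - sq
        t2 = -b + sq
        # grazing rays (disc ~ 0) are treated as non-entering
        miss = disc <= 1e-12
        t1 = np.where(miss, np.inf, t1)
        t2 = np.where(miss, np.inf, t2)
        return np.stack([t1, t2], axis=1)

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def bounds(self):
        c = np.asarray(self.center)
        return c - self.radius, c + self.radius


@dataclass(frozen=True)
class Ellipsoid(Shape):
    """Axis-aligned ellipsoid: sum(((p - c)/semi_axes)^2) <= 1."""

    center: tuple
    semi_axes: tuple

    def contains(self, points):
        d = (_as_points(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.einsum("ij,ij->i", d, d) <= 1.0 + _EPS

    def ray_ts(self, origins, directions):
        ax = np.asarray(self.semi_axes)
        o = (_as_points(origins) - np.asarray(self.center)) / ax
        d = _as_points(directions) / ax
        a = np.einsum("ij,ij->i", d, d)
        b = np.einsum("ij,ij->i", o, d)
        c = np.einsum("ij,ij->i", o, o) - 1.0
        disc = b * b - a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b - sq) / a
            t2 = (-b + sq) / a
        miss = disc <= 1e-12
        return np.stack([np.where(miss, np.inf, t1), np.where(miss, np.inf, t2)], axis=1)

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def bounds(self):
        c = np.asarray(self.center)
        ax = np.asarray(self.semi_axes)
        return c - ax, c + ax


@dataclass(frozen=True)
class Box(Shape):
    """Axis-aligned box [lo, hi]."""

    lo: tuple
    hi: tuple

    def contains(self, points):
        p = _as_points(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo - _EPS) & (p <= hi + _EPS), axis=1)

    def ray_ts(self, origins, directions):
        o = _as_points(origins)
        d = _as_points(directions)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - o) / d
            t_hi = (hi - o) / d
        t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=1)
        t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=1)
        hit = t_near < t_far
        return np.stack(
            [np.where(hit, t_near, np.inf), np.where(hit, t_far, np.inf)], axis=1
        )

    def bounds(self):
        return np.asarray(self.lo, dtype=float), np.asarray(self.hi, dtype=float)


@dataclass(frozen=True)
class HalfSpace(Shape):
    """Points with normal . p <= offset (normal need not be unit)."""

    normal: tuple
    offset: float

    def contains(self, points):
        return _as_points(points) @ np.asarray(self.normal) <= self.offset + _EPS

    def ray_ts(self, origins, directions):
        n = np.asarray(self.normal)
        num = self.offset - _as_points(origins) @ n
        den = _as_points(directions) @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / den
        t = np.where(np.abs(den) < 1e-14, np.inf, t)
        return t.reshape(-1, 1)


class Polytope(Shape):
    """Convex polytope: intersection of half-spaces ``normals @ p <= offsets``.

    Unlike an :class:`Intersection` of :class:`HalfSpace` objects, the ray
    query returns only the actual entry/exit crossings (slab method), which
    keeps the transport step count down for beam modifiers.
    """

    def __init__(self, normals, offsets, bounds_hint=None):
        self.normals = np.asarray(normals, dtype=float)
        self.offsets = np.asarray(offsets, dtype=float)
        self._bounds = None
        if bounds_hint is not None:
            self._bounds = (np.asarray(bounds_hint[0], float), np.asarray(bounds_hint[1], float))

    def bounds(self):
        return self._bounds

    def contains(self, points):
        return np.all(_as_points(points) @ self.normals.T <= self.offsets + _EPS, axis=1)

    def ray_ts(self, origins, directions):
        o = _as_points(origins)
        d = _as_points(directions)
        den = d @ self.normals.T                      # (N, m)
        num = self.offsets - o @ self.normals.T
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / den
        entering = den < -1e-14
        exiting = den > 1e-14
        t_lo = np.where(entering, t, -np.inf).max(axis=1)
        t_hi = np.where(exiting, t, np.inf).min(axis=1)
        # parallel to a violated plane -> no intersection at all
        blocked = np.any((np.abs(den) <= 1e-14) & (num < 0), axis=1)
        hit = (t_lo < t_hi) & ~blocked
        return np.stack(
            [np.where(hit, t_lo, np.inf), np.where(hit, t_hi, np.inf)], axis=1
        )


@dataclass(frozen=True)
class Intersection(Shape):
    shapes: tuple

    def contains(self, points):
        out = self.shapes[0].contains(points)
        for s in self.shapes[1:]:
            out &= s.contains(points)
        return out

    def primitives(self):
        return [p for s in self.shapes for p in s.primitives()]

    def ray_ts(self, origins, directions):
        return np.concatenate([s.ray_ts(origins, directions) for s in self.shapes], axis=1)

    def bounds(self):
        los, his = [], []
        for s in self.shapes:
            b = s.bounds()
            if b is not None:
                los.append(b[0])
                his.append(b[1])
        if not los:
            return None
        return np.max(los, axis=0), np.min(his, axis=0)


@dataclass(frozen=True)
class Union(Shape):
    shapes: tuple

    def contains(self, points):
        out = self.shapes[0].contains(points)
        for s in self.shapes[1:]:
            out |= s.contains(points)
        return out

    def primitives(self):
        return [p for s in self.shapes for p in s.primitives()]

    def ray_ts(self, origins, directions):
        return np.concatenate([s.ray_ts(origins, directions) for s in self.shapes], axis=1)

    def bounds(self):
        boxes = [s.bounds() for s in self.shapes]
        if any(b is None for b in boxes):
            return None
        return (np.min([b[0] for b in boxes], axis=0),
                np.max([b[1] for b in boxes], axis=0))


@dataclass
class Region:
    """A material region with an integer priority for overlap resolution."""

    id: str
    shape: Shape
    material: Material
    priority: int = 0


@dataclass
class Geometry:
    """Priority-resolved set of regions with fast point and ray queries.

    The region list must include exactly one enclosing world region (by
    convention the lowest priority); points outside every region map to
    :data:`WORLD_EXIT`.
    """

    regions: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")
        prios = [r.priority for r in self.regions]
        if len(set(prios)) != len(prios):
            raise ValueError(
                "regions must carry distinct priorities to resolve overlaps"
            )
        self._ordered = sorted(self.regions, key=lambda r: -r.priority)
        self._primitives = [p for r in self._ordered for p in r.shape.primitives()]
        self._compile_surfaces()
        self._inner_bounds = self._compute_inner_bounds()

    def _compile_surfaces(self):
        """Group primitives by type so ray queries batch into a few numpy passes."""
        spheres, boxes, halves, polys = [], [], [], []
        for p in self._primitives:
            if isinstance(p, Sphere):
                spheres.append((p.center, (p.radius,) * 3))
            elif isinstance(p, Ellipsoid):
                spheres.append((p.center, p.semi_axes))
            elif isinstance(p, Box):
                boxes.append((p.lo, p.hi))
            elif isinstance(p, HalfSpace):
                halves.append((p.normal, p.offset))
            else:
                polys.append(p)
        self._ell_c = np.array([c for c, _ in spheres], dtype=float).reshape(-1, 3)
        self._ell_inv = 1.0 / np.array(
            [a for _, a in spheres], dtype=float
        ).reshape(-1, 3) if spheres else np.empty((0, 3))
        self._box_lo = np.array([lo for lo, _ in boxes], dtype=float).reshape(-1, 3)
        self._box_hi = np.array([hi for _, hi in boxes], dtype=float).reshape(-1, 3)
        self._half_n = np.array([n for n, _ in halves], dtype=float).reshape(-1, 3)
        self._half_c = np.array([c for _, c in halves], dtype=float)
        self._polys = polys

    def _compute_inner_bounds(self):
        """Union bbox of every region except the enclosing (lowest-priority) world."""
        los, his = [], []
        for r in self._ordered[:-1]:
            b = r.shape.bounds()
            if b is None:
                return None
            los.append(b[0])
            his.append(b[1])
        if not los:
            return None
        return np.min(los, axis=0), np.max(his, axis=0)

    @property
    def ordered_regions(self):
        return self._ordered

    @property
    def world_index(self) -> int:
        return len(self._ordered) - 1

    def region_index(self, points) -> np.ndarray:
        """Index into ``ordered_regions`` for each point; -1 if outside the world."""
        p = _as_points(points)
        out = np.full(len(p), -1, dtype=np.int64)
        unassigned = np.ones(len(p), dtype=bool)
        if self._inner_bounds is not None and len(p) > 8:
            lo, hi = self._inner_bounds
            outside = np.any((p < lo) | (p > hi), axis=1)
            if outside.any():
                world = self._ordered[-1]
                idx = np.flatnonzero(outside)
                hit = world.shape.contains(p[idx])
                out[idx[hit]] = self.world_index
                unassigned[outside] = False
        for i, region in enumerate(self._ordered):
            if not unassigned.any():
                break
            idx = np.flatnonzero(unassigned)
            hit = region.shape.contains(p[idx])
            out[idx[hit]] = i
            unassigned[idx[hit]] = False
        return out

    def region_at(self, point) -> str:
        """Region id claiming ``point`` (priority-resolved), or WORLD_EXIT."""
        i = int(self.region_index(np.asarray(point, dtype=float))[0])
        return WORLD_EXIT if i < 0 else self._ordered[i].id

    def escapes_inner(self, origins, directions) -> np.ndarray:
        """True for rays that cannot re-enter the non-world part of the geometry.

        Used by the transport engine to retire photons that have left the
        anatomy (and any beam-line modifiers) and are flying through the
        near-vacuum world region.
        """
        if self._inner_bounds is None:
            return np.zeros(len(_as_points(origins)), dtype=bool)
        o = _as_points(origins)
        d = _as_points(directions)
        lo, hi = self._inner_bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lo - o) / d
            t_hi = (hi - o) / d
        t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=1)
        t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=1)
        return (t_far < 0) | (t_near > t_far)

    def nearest_crossing(self, origins, directions, tol=1e-7) -> np.ndarray:
        """Distance to the nearest candidate surface crossing per ray (inf if none)."""
        o = _as_points(origins)
        d = _as_points(directions)
        n = len(o)
        best = np.full(n, np.inf)

        if len(self._ell_c):
            oc = (o[:, None, :] - self._ell_c[None, :, :]) * self._ell_inv[None, :, :]
            dc = d[:, None, :] * self._ell_inv[None, :, :]
            a = np.einsum("npk,npk->np", dc, dc)
            b = np.einsum("npk,npk->np", oc, dc)
            c = np.einsum("npk,npk->np", oc, oc) - 1.0
            disc = b * b - a * c
            ok = disc > 1e-12
            sq = np.sqrt(np.where(ok, disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-b - sq) / a
                t2 = (-b + sq) / a
            t1 = np.where(ok & (t1 > tol), t1, np.inf)
            t2 = np.where(ok & (t2 > tol), t2, np.inf)
            best = np.minimum(best, np.minimum(t1, t2).min(axis=1))

        if len(self._box_lo):
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (self._box_lo[None, :, :] - o[:, None, :]) / d[:, None, :]
                t_hi = (self._box_hi[None, :, :] - o[:, None, :]) / d[:, None, :]
            t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=2)
            t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=2)
            hit = t_near < t_far
            t_near = np.where(hit & (t_near > tol), t_near, np.inf)
            t_far = np.where(hit & (t_far > tol), t_far, np.inf)
            best = np.minimum(best, np.minimum(t_near, t_far).min(axis=1))

        if len(self._half_n):
            den = d @ self._half_n.T
            num = self._half_c[None, :] - o @ self._half_n.T
            with np.errstate(divide="ignore", invalid="ignore"):
                t = num / den
            t = np.where((np.abs(den) > 1e-14) & (t > tol), t, np.inf)
            best = np.minimum(best, t.min(axis=1))

        for poly in self._polys:
            ts = poly.ray_ts(o, d)
            ts = np.where(ts > tol, ts, np.inf)
            best = np.minimum(best, ts.min(axis=1))
        return best

    def _candidate_ts(self, origin, direction):
        o = np.asarray(origin, dtype=float).reshape(1, 3)
        d = np.asarray(direction, dtype=float).reshape(1, 3)
        ts = np.concatenate([p.ray_ts(o, d).ravel() for p in self._primitives])
        ts = np.unique(ts[(ts > 1e-7) & np.isfinite(ts)])
        return ts

    def distance_to_boundary(self, point, direction, eps=1e-6):
        """Distance along ``direction`` to the next region change.

        Returns ``(distance, next_region_id)``; crossings that do not change
        the region are skipped.  Rays escaping the world return the distance
        to the world boundary and :data:`WORLD_EXIT`.

        ``direction`` must be unit-norm.
        """
        direction = np.asarray(direction, dtype=float)
        if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
            raise ValueError("direction must be unit-norm")
        point = np.asarray(point, dtype=float)
        current = self.region_at(point)
        for t in self._candidate_ts(point, direction):
            rid = self.region_at(point + (t + eps) * direction)
            if rid != current:
                return float(t), rid
        return np.inf, WORLD_EXIT
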