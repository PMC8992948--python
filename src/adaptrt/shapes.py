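"""Analytic star-shaped solids used to build the pelvic phantom.

Each shape exposes a *normalized radius* rho(x): positively homogeneous of
degree 1 about the shape center, with rho <= 1 exactly on the solid.  This is
the property the radial organ-deformation warps rely on: along any ray from
the center, rho grows linearly, so a monotone 1-D radial profile yields an
exactly invertible warp.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Shape:
    center: np.ndarray

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.normalized_radius(pts) <= 1.0

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi) of the solid."""
        raise NotImplementedError


@dataclass
class Ellipsoid(Shape):
    """Axis-aligned ellipsoid with semi-axes (a, b, c) mm."""
    center: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.semi_axes = np.asarray(self.semi_axes, float)
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        d = (np.asarray(pts, float) - self.center) / self.semi_axes
        return np.sqrt(np.sum(d * d, axis=-1))

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def bbox(self):
        return self.center - self.semi_axes, self.center + self.semi_axes


@dataclass
class SuperTube(Shape):
    """Tube-like superellipsoid: circular/elliptic cross-section in (x, y),
    flattened p-norm closure along z.

    rho = (((dx/a)^2 + (dy/b)^2)^(p/2) + |dz/c|^p)^(1/p); p >= 2.  For large p
    the solid approaches a cylinder of half-length c with rounded ends; it is
    star-shaped and rho is homogeneous of degree 1.
    """
    center: np.ndarray
    semi_axes: np.ndarray  # (a, b, c); c = half-length along z
    p: float = 6.0

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.semi_axes = np.asarray(self.semi_axes, float)
        if np.any(self.semi_axes <= 0) or self.p < 2:
            raise ValueError("invalid tube parameters")

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        d = (np.asarray(pts, float) - self.center) / self.semi_axes
        trans = d[..., 0] ** 2 + d[..., 1] ** 2
        return (trans ** (self.p / 2.0) + np.abs(d[..., 2]) ** self.p) ** (1.0 / self.p)

    def bbox(self):
        return self.center - self.semi_axes, self.center + self.semi_axes


@dataclass
class EllipticCylinder(Shape):
    """Infinite elliptic cylinder along z (used for the body outline), or a
    finite one when half_length is given."""
    center: np.ndarray  # z component ignored when infinite
    semi_axes: np.ndarray  # (a, b)
    half_length: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.semi_axes = np.asarray(self.semi_axes, float)

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        d0 = (pts[..., 0] - self.center[0]) / self.semi_axes[0]
        d1 = (pts[..., 1] - self.center[1]) / self.semi_axes[1]
        rho = np.sqrt(d0 * d0 + d1 * d1)
        if self.half_length is not None:
            rho = np.maximum(rho, np.abs(pts[..., 2] - self.center[2]) / self.half_length)
        return rho


@dataclass
class Union(Shape):
    parts: tuple[Shape, ...]

    def __post_init__(self):
        self.parts = tuple(self.parts)
        self.center = np.mean([p.center for p in self.parts], axis=0)

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        return np.minimum.reduce([p.normalized_radius(pts) for p in self.parts])

    def bbox(self):
        boxes = [p.bbox() for p in self.parts]
        return (np.min([b[0] for b in boxes], axis=0),
                np.max([b[1] for b in boxes], axis=0))


@dataclass
class Difference(Shape):
    """outer minus inner (e.g. a bone shell)."""
    outer: Shape
    inner: Shape

    def __post_init__(self):
        self.center = self.outer.center

    def normalized_radius(self, pts: np.ndarray) -> np.ndarray:
        # not homogeneous; only used for membership, never for warps
        ro = self.outer.normalized_radius(pts)
        ri = self.inner.normalized_radius(pts)
        return np.where(ri < 1.0, np.maximum(ro, 2.0 - ri), ro)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.outer.contains(pts) & ~self.inner.contains(pts)
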