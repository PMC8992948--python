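"""Parametric, exactly invertible deformations linking daily to planning
anatomy.

A daily anatomy is generated from the planning phantom by composing:

* one :class:`RadialScaleWarp` per organ — uniform scaling inside the organ
  (volume factor s^3) blending smoothly to identity at ``support`` times the
  organ's normalized radius, which carries the surrounding soft tissue along;
* a :class:`LocalTranslationWarp` for the seminal-vesicle shift coupled to
  rectum/bladder filling;
* a :class:`RigidTransform` for the set-up error.

Because each elementary map is invertible in closed or 1-D-monotone form, the
ground-truth correspondence between daily and planning coordinates is known
exactly — this replaces the deformable image registration a clinical workflow
would use for contour propagation and dose accumulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .shapes import Shape


class SamplingError(RuntimeError):
    """A requested deformation is not invertible (radial profile not monotone
    or fixed-point inversion failed)."""


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class RigidTransform:
    """Rotation (deg, intrinsic x-y-z) about ``center`` followed by a
    translation, all in world mm."""

    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.translation_mm = np.asarray(self.translation_mm, float)
        self.center = np.asarray(self.center, float)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.angles_deg, degrees=True)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return self.rotation.apply(pts - self.center) + self.center + self.translation_mm

    forward = apply

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return self.rotation.inv().apply(pts - self.center - self.translation_mm) + self.center

    inverse = inverse_apply

    def inverted(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        t = -rinv.apply(self.translation_mm)
        return RigidTransform(rinv.as_euler("xyz", degrees=True), t, self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first). Centers must match."""
        if not np.allclose(self.center, other.center):
            raise ValueError("compose requires a common center")
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation_mm) + self.translation_mm
        return RigidTransform(r.as_euler("xyz", degrees=True), t, self.center)

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.angles_deg, 0, atol=1e-12)
                and np.allclose(self.translation_mm, 0, atol=1e-12))

    def to_dict(self) -> dict:
        return {"angles_deg": self.angles_deg.tolist(),
                "translation_mm": self.translation_mm.tolist(),
                "center": self.center.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.array(d["angles_deg"]),
                              np.array(d["translation_mm"]),
                              np.array(d["center"]))


class Warp:
    def forward(self, pts: np.ndarray) -> np.ndarray:  # planning -> daily
        raise NotImplementedError

    def inverse(self, pts: np.ndarray) -> np.ndarray:  # daily -> planning
        raise NotImplementedError


class RadialScaleWarp(Warp):
    """Scale a star-shaped organ by linear factor ``scale`` about its center.

    In normalized-radius coordinates the radial profile is

        f(rho) = scale * rho                    rho <= 1
        f(rho) = rho + (scale-1) * h(t)         1 < rho < support
        f(rho) = rho                            rho >= support

    with h the complementary smoothstep of t = (rho-1)/(support-1).  The organ
    interior is scaled uniformly (volume factor scale^3); tissue in the blend
    shell is carried smoothly.  Monotonicity of f (checked at construction) is
    exactly the invertibility condition.
    """

    _GRID_N = 4096

    def __init__(self, shape: Shape, scale: float, support: float = 1.8):
        if scale <= 0:
            raise SamplingError("scale must be positive")
        if support <= 1.0:
            raise ValueError("support must exceed 1")
        self.shape = shape
        self.scale = float(scale)
        self.support = float(support)
        rho = np.linspace(0.0, support * 1.5, self._GRID_N)
        f = self._profile(rho)
        if np.any(np.diff(f) <= 0):
            raise SamplingError(
                f"radial profile not monotone (scale={scale:.3f}, support={support})")
        self._rho_grid, self._f_grid = rho, f

    def _profile(self, rho: np.ndarray) -> np.ndarray:
        s, P = self.scale, self.support
        t = (rho - 1.0) / (P - 1.0)
        h = 1.0 - _smoothstep(t)
        out = np.where(rho <= 1.0, s * rho, rho + (s - 1.0) * h)
        return out

    def _candidates(self, pts: np.ndarray) -> np.ndarray:
        """Points possibly inside the support (cheap bbox test); everything
        else is identity."""
        lo, hi = self.shape.bbox()
        c = self.shape.center
        lo = c + self.support * (np.asarray(lo) - c)
        hi = c + self.support * (np.asarray(hi) - c)
        return np.all((pts >= lo) & (pts <= hi), axis=-1)

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        sel = self._candidates(pts)
        out = pts.copy()
        if np.any(sel):
            out[sel] = self._forward_core(pts[sel])
        return out

    def _forward_core(self, pts: np.ndarray) -> np.ndarray:
        c = self.shape.center
        rho = self.shape.normalized_radius(pts)
        f = self._profile(rho)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(rho > 0, f / np.where(rho > 0, rho, 1.0), self.scale)
        return c + factor[..., None] * (pts - c)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        # the inverse moves points inward only when scale > 1, so the forward
        # support bbox also bounds the inverse's active set
        sel = self._candidates(pts)
        out = pts.copy()
        if np.any(sel):
            out[sel] = self._inverse_core(pts[sel])
        return out

    def _inverse_core(self, pts: np.ndarray) -> np.ndarray:
        c = self.shape.center
        rho_y = self.shape.normalized_radius(pts)
        # outside the support the warp is the identity; the interpolation grid
        # only needs to cover the scaled+blend region
        rho_x = np.where(rho_y >= self.support, rho_y,
                         np.interp(rho_y, self._f_grid, self._rho_grid))
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(rho_y > 0, rho_x / np.where(rho_y > 0, rho_y, 1.0),
                              1.0 / self.scale)
        return c + factor[..., None] * (pts - c)


class LocalTranslationWarp(Warp):
    """Translate the interior of an envelope shape by ``shift_mm``, decaying
    smoothly to zero at ``support`` times the envelope's normalized radius.

    Invertible when |shift| * max|grad(decay)| < 1; the inverse is computed by
    fixed-point iteration (a contraction under that condition).
    """

    def __init__(self, envelope: Shape, shift_mm, support: float = 2.5,
                 max_iter: int = 100, tol: float = 1e-7):
        self.envelope = envelope
        self.shift_mm = np.asarray(shift_mm, float)
        self.support = float(support)
        self.max_iter = max_iter
        self.tol = tol
        semi = getattr(envelope, "semi_axes", None)
        if semi is not None:
            # Lipschitz bound of the displacement field; > ~1 breaks both
            # invertibility and the fixed-point inversion
            lip = float(np.linalg.norm(self.shift_mm)) * 1.5 / (
                (self.support - 1.0) * float(np.min(semi)))
            if lip >= 0.95:
                raise SamplingError(
                    f"translation warp too steep (Lipschitz {lip:.2f})")

    def _decay(self, pts: np.ndarray) -> np.ndarray:
        rho = self.envelope.normalized_radius(pts)
        t = (rho - 1.0) / (self.support - 1.0)
        return 1.0 - _smoothstep(t)

    def _candidates(self, pts: np.ndarray, margin: float) -> np.ndarray:
        lo, hi = self.envelope.bbox()
        c = self.envelope.center
        lo = c + self.support * (np.asarray(lo) - c) - margin
        hi = c + self.support * (np.asarray(hi) - c) + margin
        return np.all((pts >= lo) & (pts <= hi), axis=-1)

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        sel = self._candidates(pts, 0.0)
        out = pts.copy()
        if np.any(sel):
            out[sel] = pts[sel] + self._decay(pts[sel])[..., None] * self.shift_mm
        return out

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(pts, float))
        sel = self._candidates(y, float(np.linalg.norm(self.shift_mm)))
        out = y.copy()
        if np.any(sel):
            out[sel] = self._inverse_core(y[sel])
        return out

    def _inverse_core(self, y: np.ndarray) -> np.ndarray:
        x = y - self._decay(y)[..., None] * self.shift_mm
        for _ in range(self.max_iter):
            x_new = y - self._decay(x)[..., None] * self.shift_mm
            err = np.max(np.abs(x_new - x)) if x.size else 0.0
            x = x_new
            if err < self.tol:
                return x
        raise SamplingError("fixed-point inversion of translation warp failed")


@dataclass
class Deformation:
    """Composite map between planning (reference) and daily coordinates.

    ``to_daily`` applies the organ warps in order and then the rigid set-up
    error; ``to_reference`` is the exact inverse chain.
    """

    warps: list = field(default_factory=list)
    setup: RigidTransform | None = None

    def to_daily(self, pts: np.ndarray) -> np.ndarray:
        out = np.asarray(pts, float)
        for w in self.warps:
            out = w.forward(out)
        if self.setup is not None:
            out = self.setup.apply(out)
        return out

    def to_reference(self, pts: np.ndarray) -> np.ndarray:
        out = np.asarray(pts, float)
        if self.setup is not None:
            out = self.setup.inverse_apply(out)
        for w in reversed(self.warps):
            out = w.inverse(out)
        return out

    def with_extra_rigid(self, post: RigidTransform) -> "Deformation":
        """Deformation into coordinates further transformed by ``post``
        (e.g. a couch correction applied after the set-up error)."""
        setup = post if self.setup is None else post.compose(self.setup)
        return Deformation(self.warps, setup)

    @property
    def is_identity(self) -> bool:
        return not self.warps and (self.setup is None or self.setup.is_identity)
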