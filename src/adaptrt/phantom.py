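"""Synthetic pelvic planning phantom.

Stands in for a planning CT of a high-risk prostate-cancer patient: an
ellipsoidal prostate at the isocenter, paired posterior-superior seminal
vesicle (SV) lobes, a tubular rectum posterior to prostate/SV, an ellipsoidal
bladder anterior-superior, a simplified pelvic bone ring with femoral heads,
all inside a water-equivalent elliptic body.  HU are class-constant per
tissue.  The clinical target volume (CTV) is prostate plus the entire SV.

Organ masks are evaluated analytically at voxel centers, with a fixed
priority order resolving (small) overlaps, so prostate/SV/rectum/bladder are
pairwise disjoint by construction and CTV = prostate u SV exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .ct import hu_to_stopping_power
from .deformation import Deformation, RigidTransform
from .grids import VoxelGrid
from .shapes import (Difference, EllipticCylinder, Ellipsoid, Shape, SuperTube,
                     Union)

ORGANS = ("prostate", "sv", "rectum", "bladder")
#: label codes; higher-priority structures claim a voxel first
PRIORITY = ("prostate", "sv", "rectum", "bladder", "bone", "body")
LABELS = {name: i + 1 for i, name in enumerate(PRIORITY)}  # 0 = air


class GeometryError(ValueError):
    """Requested organ geometries overlap beyond tolerance or do not fit."""


@dataclass
class PhantomConfig:
    """Geometric and HU parameters of the reference phantom (mm, LPS,
    isocenter at the prostate center)."""

    spacing: tuple = (2.0, 2.0, 2.0)
    extent_lo: tuple = (-168.0, -112.0, -88.0)
    extent_hi: tuple = (168.0, 112.0, 88.0)

    body_center: tuple = (0.0, 4.0)
    body_semi_axes: tuple = (160.0, 104.0)

    bone_center: tuple = (0.0, 6.0, 0.0)
    bone_outer: tuple = (128.0, 92.0)
    bone_inner: tuple = (106.0, 80.0)
    bone_half_length: float = 70.0
    femoral_head_radius: float = 21.0
    femoral_head_centers: tuple = ((-93.0, 6.0, -8.0), (93.0, 6.0, -8.0))

    prostate_center: tuple = (0.0, 0.0, 0.0)
    prostate_semi_axes: tuple = (21.0, 19.0, 18.0)

    sv_lobe_centers: tuple = ((-13.0, 14.0, 22.0), (13.0, 14.0, 22.0))
    sv_lobe_semi_axes: tuple = (9.0, 6.0, 13.0)

    rectum_center: tuple = (0.0, 30.0, 0.0)
    rectum_semi_axes: tuple = (18.0, 18.0, 62.0)
    rectum_p: float = 6.0

    bladder_center: tuple = (0.0, -20.0, 44.0)
    bladder_semi_axes: tuple = (38.0, 28.0, 30.0)

    hu: dict = field(default_factory=lambda: {
        "air": -1000.0, "body": 0.0, "prostate": 40.0, "sv": 35.0,
        "rectum": 30.0, "bladder": 15.0, "bone": 700.0})
    overlap_tolerance: float = 0.10

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            return v
        return {k: conv(getattr(self, k)) for k in self.__dataclass_fields__}

    @staticmethod
    def from_dict(d: dict) -> "PhantomConfig":
        def conv(v):
            if isinstance(v, list):
                return tuple(conv(x) for x in v)
            return v
        return PhantomConfig(**{k: conv(v) for k, v in d.items()})


@dataclass
class PelvicGeometry:
    """Analytic shapes + HU of one patient, evaluated lazily at points."""

    organs: dict
    sv_lobes: tuple
    sv_envelope: Ellipsoid
    bone: Shape
    body: Shape
    hu: dict
    isocenter: np.ndarray

    @staticmethod
    def from_config(cfg: PhantomConfig) -> "PelvicGeometry":
        prostate = Ellipsoid(cfg.prostate_center, cfg.prostate_semi_axes)
        lobes = tuple(Ellipsoid(c, cfg.sv_lobe_semi_axes)
                      for c in cfg.sv_lobe_centers)
        sv = Union(lobes)
        lc = np.asarray(cfg.sv_lobe_centers, float)
        sa = np.asarray(cfg.sv_lobe_semi_axes, float)
        env_center = lc.mean(axis=0)
        env_semi = np.abs(lc - env_center).max(axis=0) + sa + 4.0
        envelope = Ellipsoid(env_center, env_semi)
        rectum = SuperTube(cfg.rectum_center, cfg.rectum_semi_axes, p=cfg.rectum_p)
        bladder = Ellipsoid(cfg.bladder_center, cfg.bladder_semi_axes)
        ring = Difference(
            EllipticCylinder(cfg.bone_center, cfg.bone_outer, cfg.bone_half_length),
            EllipticCylinder(cfg.bone_center, cfg.bone_inner))
        heads = [Ellipsoid(c, (cfg.femoral_head_radius,) * 3)
                 for c in cfg.femoral_head_centers]
        bone = Union((ring, *heads))
        body = EllipticCylinder((*cfg.body_center, 0.0), cfg.body_semi_axes)
        return PelvicGeometry(
            organs={"prostate": prostate, "sv": sv, "rectum": rectum,
                    "bladder": bladder},
            sv_lobes=lobes, sv_envelope=envelope, bone=bone, body=body,
            hu=dict(cfg.hu), isocenter=np.asarray(cfg.prostate_center, float))

    def labels_at(self, pts: np.ndarray) -> np.ndarray:
        """Priority-resolved tissue label at each point (0 = air)."""
        pts = np.asarray(pts, float)
        out = np.zeros(pts.shape[:-1], dtype=np.uint8)
        shapes = {**self.organs, "bone": self.bone, "body": self.body}
        unclaimed = np.ones_like(out, dtype=bool)
        for name in PRIORITY:
            inside = shapes[name].contains(pts) & unclaimed
            out[inside] = LABELS[name]
            unclaimed &= ~inside
        return out

    def hu_at(self, labels: np.ndarray) -> np.ndarray:
        hu = np.full(labels.shape, self.hu["air"], dtype=float)
        for name in PRIORITY:
            hu[labels == LABELS[name]] = self.hu[name]
        return hu


@dataclass
class StructureSet:
    """Boolean masks co-registered to one grid; CTV = prostate u SV."""

    masks: dict

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "ctv":
            return self.ctv
        return self.masks[name]

    @property
    def ctv(self) -> np.ndarray:
        return self.masks["prostate"] | self.masks["sv"]

    def names(self):
        return list(self.masks)


@dataclass
class AnatomyInstance:
    """One anatomy (planning or daily): HU grid, structures, and — for daily
    instances — the exact deformation that generated it."""

    grid: VoxelGrid
    structures: StructureSet
    geometry: PelvicGeometry
    config: PhantomConfig | None = None
    deformation: Deformation | None = None
    setup_error: RigidTransform | None = None
    organ_scale_factors: dict | None = None
    isocenter_mm: np.ndarray | None = None

    @property
    def isocenter(self) -> np.ndarray:
        if self.isocenter_mm is not None:
            return np.asarray(self.isocenter_mm, float)
        return self.geometry.isocenter

    @cached_property
    def rsp(self) -> VoxelGrid:
        """Relative stopping power volume derived from HU."""
        return hu_to_stopping_power(self.grid)

    def structure_volume_ml(self, name: str) -> float:
        return float(np.count_nonzero(self.structures[name])
                     * self.grid.voxel_volume / 1000.0)

    def with_alignment(self, correction: RigidTransform) -> "AnatomyInstance":
        """Anatomy after a rigid couch correction applied on top of the daily
        coordinates (masks/HU re-evaluated exactly from the analytic chain)."""
        deform = self.deformation or Deformation()
        new_deform = deform.with_extra_rigid(correction)
        return _evaluate_instance(self.grid, self.geometry, self.config,
                                  new_deform, self.setup_error,
                                  self.organ_scale_factors)


def _evaluate_instance(grid: VoxelGrid, geometry: PelvicGeometry,
                       config, deformation: Deformation | None,
                       setup_error, organ_scale_factors) -> AnatomyInstance:
    centers = grid.voxel_centers()
    if deformation is None or deformation.is_identity:
        ref_pts = centers
    else:
        ref_pts = deformation.to_reference(centers)
    labels = geometry.labels_at(ref_pts).reshape(grid.shape)
    hu = geometry.hu_at(labels)
    masks = {name: labels == LABELS[name] for name in PRIORITY}
    # the body structure is the whole patient outline (organs and bone are
    # inside it), not just the unclaimed soft tissue
    masks["body"] = labels > 0
    return AnatomyInstance(
        grid=grid.like(hu), structures=StructureSet(masks),
        geometry=geometry, config=config, deformation=deformation,
        setup_error=setup_error, organ_scale_factors=organ_scale_factors)


def build_water_box_phantom(side_mm: float = 300.0, ctv_side_mm: float = 50.0,
                            spacing: float = 5.0) -> AnatomyInstance:
    """Uniform water cube with a cubic target at its center: the digital
    phantom used for engine validation and water-box planning checks."""
    half = side_mm / 2.0
    grid = VoxelGrid.from_extent((-half,) * 3, (half,) * 3, spacing)
    hu = np.zeros(grid.shape)
    centers = grid.voxel_centers()
    c = ctv_side_mm / 2.0
    ctv = np.all(np.abs(centers) <= c, axis=1).reshape(grid.shape)
    empty = np.zeros(grid.shape, dtype=bool)
    masks = {"prostate": ctv, "sv": empty, "rectum": empty.copy(),
             "bladder": empty.copy(), "bone": empty.copy(),
             "body": np.ones(grid.shape, dtype=bool)}
    return AnatomyInstance(grid=grid.like(hu), structures=StructureSet(masks),
                           geometry=None, isocenter_mm=np.zeros(3))


def build_reference_phantom(config: PhantomConfig | None = None) -> AnatomyInstance:
    """Construct the planning phantom for one synthetic patient.

    Raises
    ------
    GeometryError
        If any two requested organ shapes overlap by more than
        ``config.overlap_tolerance`` of the smaller organ's volume, or an
        organ pokes outside the body outline.
    """
    cfg = config or PhantomConfig()
    geometry = PelvicGeometry.from_config(cfg)
    grid = VoxelGrid.from_extent(cfg.extent_lo, cfg.extent_hi, cfg.spacing)
    centers = grid.voxel_centers()

    raw = {name: shape.contains(centers)
           for name, shape in geometry.organs.items()}
    body_in = geometry.body.contains(centers)
    names = list(raw)
    for i, a in enumerate(names):
        na = np.count_nonzero(raw[a])
        if na == 0:
            raise GeometryError(f"organ {a!r} has zero volume on this grid")
        if np.count_nonzero(raw[a] & ~body_in):
            raise GeometryError(f"organ {a!r} extends outside the body contour")
        for b in names[i + 1:]:
            nb = np.count_nonzero(raw[b])
            inter = np.count_nonzero(raw[a] & raw[b])
            # abutting pairs are anatomically expected (prostate/SV merge
            # into the CTV; the SV and prostate rest on the rectal wall);
            # the priority rule keeps the masks disjoint in any case
            # the rectal tube deliberately wraps the posterior prostate/SV
            # surface; the priority rule carves the target out of it, leaving
            # the anatomically concave anterior rectal wall
            lax = ({"prostate", "sv"}, {"sv", "rectum"}, {"prostate", "rectum"})
            tol = 0.8 if {a, b} in lax else cfg.overlap_tolerance
            if inter > tol * min(na, nb):
                raise GeometryError(
                    f"organs {a!r} and {b!r} overlap by {inter} voxels "
                    f"(> {tol:.0%} of the smaller organ)")

    return _evaluate_instance(grid, geometry, cfg, None, None, None)


def sample_patient_config(rng: np.random.Generator,
                          base: PhantomConfig | None = None) -> PhantomConfig:
    """Per-patient anatomical variability: jittered organ sizes/positions
    around the baseline phantom (the cohort analogue of 23 different
    patients)."""
    cfg = base or PhantomConfig()

    def jit(scale_lo, scale_hi, size=3):
        return rng.uniform(scale_lo, scale_hi, size=size)

    prost = np.asarray(cfg.prostate_semi_axes) * jit(0.88, 1.15)
    svsemi = np.asarray(cfg.sv_lobe_semi_axes) * jit(0.88, 1.12)
    svc = np.asarray(cfg.sv_lobe_centers, float)
    svc[:, 1] += rng.uniform(-2.0, 3.0)
    svc[:, 2] += rng.uniform(-3.0, 3.0) + (prost[2] - cfg.prostate_semi_axes[2])
    rect = np.asarray(cfg.rectum_semi_axes) * np.array(
        [*jit(0.85, 1.2, 2), rng.uniform(0.9, 1.05)])
    rectc = np.asarray(cfg.rectum_center, float)
    rectc[1] += rng.uniform(-2.0, 4.0) + (rect[1] - cfg.rectum_semi_axes[1])
    # bladder jitter kept tight so its warp support clears the bone ring
    blad = np.asarray(cfg.bladder_semi_axes) * jit(0.85, 1.05)
    bladc = np.asarray(cfg.bladder_center, float)
    bladc[2] += rng.uniform(-2.0, 2.0)

    def t(a):
        return tuple(np.round(np.asarray(a, float), 3).tolist())

    return replace(
        cfg,
        prostate_semi_axes=t(prost),
        sv_lobe_semi_axes=t(svsemi),
        sv_lobe_centers=(t(svc[0]), t(svc[1])),
        rectum_semi_axes=t(rect),
        rectum_center=t(rectc),
        bladder_semi_axes=t(blad),
        bladder_center=t(bladc),
    )
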