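"""Pencil-beam model: analytic Bragg depth-dose, lateral spread, spot plans.

The engine is a deliberately simple stand-in for a clinical spot-scanning
dose algorithm: parallel (non-divergent) opposed lateral beams, an analytic
Bragg curve (power-law-ish entrance rising into a Gaussian peak with a
Gaussian distal falloff), and a lateral Gaussian whose sigma grows linearly
with depth.  It is validated against its own quadrature/per-voxel oracles,
not against measured beam data.

Beam geometry: field 0 is the right lateral beam travelling +x, field 1 the
left lateral beam travelling -x; the beam's-eye-view plane is the world
(y, z) plane for both, which keeps spot bookkeeping trivial.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

N_FIELDS = 2
FIELD_DIRECTIONS = {0: np.array([1.0, 0.0, 0.0]), 1: np.array([-1.0, 0.0, 0.0])}


@dataclass
class BeamModel:
    """Machine/beamline parameterization (all lengths in mm water unless
    noted)."""

    #: lateral sigma at zero depth (in patient), mm
    sigma0_mm: float = 5.0
    #: linear growth of lateral sigma with water-equivalent depth (mm/mm)
    sigma_growth: float = 0.025
    #: entrance dose as a fraction of the Bragg-peak dose
    entrance_fraction: float = 0.30
    #: linear rise of the plateau toward the peak (fraction of peak)
    plateau_rise: float = 0.18
    #: proximal peak width scale (fraction of range, floored at peak_sigma_min)
    peak_sigma_rel: float = 0.012
    peak_sigma_min_mm: float = 3.0
    #: distal 80%->20% falloff distance, mm
    distal_falloff_mm: float = 4.0
    #: dose is exactly zero beyond range + distal_cutoff
    distal_cutoff_mm: float = 10.0
    #: energy-layer spacing in water range, mm
    layer_spacing_mm: float = 5.0
    #: lateral spot spacing as a multiple of sigma0
    lateral_spacing_factor: float = 1.5
    #: WEPL margin of layers around the CTV envelope, mm
    range_margin_mm: float = 10.0
    #: lateral margin of spot positions around the CTV footprint, mm
    lateral_margin_mm: float = 5.0
    #: deliverable water ranges, mm
    range_min_mm: float = 30.0
    range_max_mm: float = 350.0

    @property
    def distal_sigma_mm(self) -> float:
        # Gaussian z-scores of the 80% and 20% points
        return self.distal_falloff_mm / 1.1268

    def sigma_at(self, depth_mm: np.ndarray) -> np.ndarray:
        return self.sigma0_mm + self.sigma_growth * np.maximum(depth_mm, 0.0)

    def peak_sigma(self, range_mm) -> np.ndarray:
        return np.maximum(self.peak_sigma_rel * np.asarray(range_mm, float),
                          self.peak_sigma_min_mm)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "BeamModel":
        return BeamModel(**d)


def bragg_depth_dose(range_mm, wepl_mm, model: BeamModel | None = None):
    """Dose per unit fluence at water-equivalent depth ``wepl_mm`` for a
    pencil beam of nominal range (R80-ish) ``range_mm``.  Peak normalized to
    1 at wepl == range; entrance-to-peak ratio = entrance_fraction; exactly
    zero beyond range + distal_cutoff.  Vectorized over both arguments."""
    m = model or BeamModel()
    r = np.asarray(range_mm, float)
    z = np.asarray(wepl_mm, float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    sp = m.peak_sigma(r)
    c0, rise = m.entrance_fraction, m.plateau_rise
    peak_amp = 1.0 - c0 - rise
    pre = c0 + rise * np.clip(z / r, 0.0, 1.0) \
        + peak_amp * np.exp(-0.5 * ((z - r) / sp) ** 2)
    post = np.exp(-0.5 * ((z - r) / m.distal_sigma_mm) ** 2)
    out = np.where(z <= r, pre, post)
    out = np.where(z >= r + m.distal_cutoff_mm, 0.0, out)
    return out


@dataclass
class PencilBeamSpot:
    """One scanned spot: field, lateral beam's-eye-view position, nominal
    water range (R80) and fluence weight."""

    field_id: int
    y_mm: float
    z_mm: float
    range_mm: float
    weight: float

    def __post_init__(self):
        if self.field_id not in FIELD_DIRECTIONS:
            raise ValueError("field_id must be 0 (right lat) or 1 (left lat)")
        if self.weight < 0:
            raise ValueError("spot weight must be non-negative")


@dataclass
class SpotPlan:
    """Two opposed lateral fields of pencil-beam spots plus prescription
    metadata.  Spot arrays are parallel: ``field_id[i], y_mm[i], z_mm[i],
    range_mm[i], weight[i]`` describe spot i."""

    field_id: np.ndarray
    y_mm: np.ndarray
    z_mm: np.ndarray
    range_mm: np.ndarray
    weight: np.ndarray
    beam_model: BeamModel = field(default_factory=BeamModel)
    prescription_gy: float = 63.0
    n_fractions: int = 21
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.field_id = np.asarray(self.field_id, int)
        self.y_mm = np.asarray(self.y_mm, float)
        self.z_mm = np.asarray(self.z_mm, float)
        self.range_mm = np.asarray(self.range_mm, float)
        self.weight = np.asarray(self.weight, float)
        n = len(self.field_id)
        if not all(len(a) == n for a in
                   (self.y_mm, self.z_mm, self.range_mm, self.weight)):
            raise ValueError("spot arrays must have equal length")
        if np.any(self.weight < 0):
            raise ValueError("spot weights must be non-negative")
        bm = self.beam_model
        if n and (self.range_mm.min() < bm.range_min_mm
                  or self.range_mm.max() > bm.range_max_mm):
            raise ValueError("spot range outside machine limits")

    @property
    def n_spots(self) -> int:
        return len(self.field_id)

    def spots(self):
        """Iterate spots as :class:`PencilBeamSpot` objects."""
        for i in range(self.n_spots):
            yield PencilBeamSpot(int(self.field_id[i]), float(self.y_mm[i]),
                                 float(self.z_mm[i]), float(self.range_mm[i]),
                                 float(self.weight[i]))

    def with_weights(self, weight: np.ndarray, **meta) -> "SpotPlan":
        return SpotPlan(self.field_id, self.y_mm, self.z_mm, self.range_mm,
                        np.asarray(weight, float), self.beam_model,
                        self.prescription_gy, self.n_fractions,
                        {**self.meta, **meta})

    def to_json(self) -> str:
        return json.dumps({
            "field_id": self.field_id.tolist(),
            "y_mm": self.y_mm.tolist(),
            "z_mm": self.z_mm.tolist(),
            "range_mm": self.range_mm.tolist(),
            "weight": self.weight.tolist(),
            "beam_model": self.beam_model.to_dict(),
            "prescription_gy": self.prescription_gy,
            "n_fractions": self.n_fractions,
            "meta": self.meta,
        }, indent=1)

    @staticmethod
    def from_json(text: str) -> "SpotPlan":
        d = json.loads(text)
        return SpotPlan(
            np.array(d["field_id"]), np.array(d["y_mm"]), np.array(d["z_mm"]),
            np.array(d["range_mm"]), np.array(d["weight"]),
            BeamModel.from_dict(d["beam_model"]), d["prescription_gy"],
            d["n_fractions"], d.get("meta", {}))


def place_spots(wepl_fields, target_mask_pts, beam: BeamModel,
                prescription_gy: float = 63.0, n_fractions: int = 21,
                lateral_expand_mm: float = 0.0) -> SpotPlan:
    """Lay out energy layers and lateral spot positions covering the target.

    Parameters
    ----------
    wepl_fields : callable
        ``wepl_fields(field_id, pts) -> WEPL (mm water)`` at world points.
    target_mask_pts : (N, 3) array
        World coordinates of target (CTV) voxel centers.
    lateral_expand_mm : float
        Extra widening of the lateral footprint beyond the standard margin
        (used to pre-cover anticipated daily anatomical variation).
    """
    pts = np.asarray(target_mask_pts, float)
    if len(pts) == 0:
        raise ValueError("empty target")
    spacing = beam.lateral_spacing_factor * beam.sigma0_mm
    margin = beam.lateral_margin_mm + lateral_expand_mm
    y_lo, y_hi = pts[:, 1].min() - margin, pts[:, 1].max() + margin
    z_lo, z_hi = pts[:, 2].min() - margin, pts[:, 2].max() + margin
    ys = np.arange(y_lo, y_hi + spacing / 2, spacing)
    zs = np.arange(z_lo, z_hi + spacing / 2, spacing)

    fids, sy, sz, sr = [], [], [], []
    for fid in range(N_FIELDS):
        wepl = wepl_fields(fid, pts)
        lo = max(wepl.min() - beam.range_margin_mm, beam.range_min_mm)
        hi = min(wepl.max() + beam.range_margin_mm, beam.range_max_mm)
        layers = np.arange(lo, hi + beam.layer_spacing_mm / 2,
                           beam.layer_spacing_mm)
        # per lateral cell, the WEPL interval of target voxels it covers
        for y in ys:
            for z in zs:
                near = (np.abs(pts[:, 1] - y) <= spacing + margin) & \
                       (np.abs(pts[:, 2] - z) <= spacing + margin)
                if not np.any(near):
                    continue
                w_lo = wepl[near].min() - beam.range_margin_mm
                w_hi = wepl[near].max() + beam.range_margin_mm
                for r in layers:
                    if w_lo <= r <= w_hi:
                        fids.append(fid)
                        sy.append(y)
                        sz.append(z)
                        sr.append(r)
    return SpotPlan(np.array(fids), np.array(sy), np.array(sz), np.array(sr),
                    np.ones(len(fids)), beam, prescription_gy, n_fractions,
                    {"placement": "lattice"})
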