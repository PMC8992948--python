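"""Volume I/O (NRRD/MetaImage via SimpleITK), YAML configuration, run
manifests and fixture-cohort generation.

Volumes are exchanged as NRRD (self-describing origin/spacing/orientation,
no patient-identity baggage); masks as unsigned-8-bit label volumes, one
file per structure plus a combined label map.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from . import __version__
from .grids import VoxelGrid
from .phantom import (LABELS, PRIORITY, AnatomyInstance, PhantomConfig,
                      build_reference_phantom, sample_patient_config)
from .variation import VariationParams, sample_daily_anatomy


class VolumeFormatError(ValueError):
    pass


def write_volume(path, grid: VoxelGrid) -> None:
    """Write a grid as NRRD/MetaImage with full geometry headers.

    Array axes are (x, y, z) internally and (z, y, x) in ITK; the transpose
    round-trips losslessly.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def _check_nrrd_geometry(path: Path) -> None:
    """NRRD stores geometry in 'space directions'/'spacings' header fields;
    refuse files that carry neither (SimpleITK would silently assume unit
    spacing)."""
    with open(path, "rb") as fh:
        header = fh.read(4096).decode("latin1", errors="replace")
    head = header.split("\n\n", 1)[0].lower()
    if "space directions" not in head and "spacings" not in head:
        raise VolumeFormatError(
            f"{path}: NRRD header lacks 'space directions'/'spacings'")


def read_volume(path) -> VoxelGrid:
    """Read an NRRD/MetaImage volume; raises VolumeFormatError when geometry
    headers are missing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".nrrd":
        _check_nrrd_geometry(path)
    img = sitk.ReadImage(str(path))
    vals = sitk.GetArrayFromImage(img).T
    return VoxelGrid(np.array(img.GetOrigin()), np.array(img.GetSpacing()),
                     vals)


def write_anatomy(out_dir, anatomy: AnatomyInstance, stem: str = "anatomy") -> dict:
    """Write HU volume, per-structure masks and combined label map; returns
    the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    hu_path = out / f"{stem}_hu.nrrd"
    write_volume(hu_path, anatomy.grid)
    files["hu"] = str(hu_path)
    labels = np.zeros(anatomy.grid.shape, dtype=np.uint8)
    for name in PRIORITY:
        mask = anatomy.structures[name]
        labels[mask] = LABELS[name]
        p = out / f"{stem}_{name}.nrrd"
        write_volume(p, anatomy.grid.like(mask.astype(np.uint8)))
        files[name] = str(p)
    lp = out / f"{stem}_labels.nrrd"
    write_volume(lp, anatomy.grid.like(labels))
    files["labels"] = str(lp)
    return files


# ---------------------------------------------------------------------------
# YAML config round trips


def save_yaml(path, obj_dict: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj_dict, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# run manifest


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, file hashes."""

    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    software_version: str = __version__
    created: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S"))

    def add_files(self, files: dict) -> None:
        for key, path in files.items():
            self.files[key] = {"path": str(path), "sha256": _hash_file(path)}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @staticmethod
    def load(path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return RunManifest(**d)


# ---------------------------------------------------------------------------
# fixture cohorts


def generate_fixture_cohort(n_patients: int, n_fractions: int, seed: int,
                            out_dir, spacing_mm: float = 6.0,
                            variation: VariationParams | None = None,
                            write_daily_volumes: bool = True) -> RunManifest:
    """Seeded, size-reduced cohort on disk (reference + daily anatomies per
    patient) with a manifest; deterministic directory contents for a given
    (n_patients, n_fractions, seed)."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = variation or VariationParams()
    manifest = RunManifest(
        config={"n_patients": n_patients, "n_fractions": n_fractions,
                "spacing_mm": spacing_mm, "variation": params.to_dict()},
        master_seed=seed)
    for p in range(n_patients):
        rng = np.random.default_rng([seed, p])
        cfg = replace(sample_patient_config(rng), spacing=(spacing_mm,) * 3)
        ref = build_reference_phantom(cfg)
        pdir = out / f"P{p:02d}"
        files = write_anatomy(pdir, ref, stem="reference")
        save_yaml(pdir / "phantom.yaml", cfg.to_dict())
        patient_seed = (seed * 100003 + p) % (2 ** 31)
        manifest.stage_seeds[f"P{p:02d}"] = patient_seed
        for f in range(n_fractions):
            daily = sample_daily_anatomy(ref, params, f, patient_seed)
            if write_daily_volumes:
                files.update({f"fx{f:02d}_{k}": v for k, v in
                              write_anatomy(pdir, daily,
                                            stem=f"fx{f:02d}").items()})
        manifest.add_files(files)
    save_yaml(out / "variation.yaml", params.to_dict())
    manifest.save(out / "manifest.json")
    return manifest
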