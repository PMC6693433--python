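"""Serialization: phantoms and dose grids as NIfTI + YAML sidecars, fitted
models as structured text / joblib containers, fluence maps as ASCII."""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib
import nibabel as nib
import numpy as np
import yaml

from .dose import DoseGrid
from .energy import EnergyModel
from .fluence import FluenceModel, SplitModel, SCHEMA_VERSION
from .phantom import Phantom, PhantomSpec

MASK_LABELS = {"body": 1, "breast_target": 2, "ipsilateral_lung": 3, "heart": 4}
_FORMAT_VERSION = "1"


def _plain(obj):
    """Recursively convert numpy scalars/arrays to built-in types for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _affine(origin, voxel_size):
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    aff[:3, 3] = origin
    return aff


def save_phantom(phantom: Phantom, directory, stem: str = "phantom") -> Path:
    """One density volume + one labeled-mask volume + YAML sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.origin, phantom.voxel_size)
    nib.save(nib.Nifti1Image(phantom.density.astype(np.float32), aff),
             directory / f"{stem}_density.nii.gz")
    labels = np.zeros(phantom.density.shape, dtype=np.uint8)
    for name, code in MASK_LABELS.items():  # later labels overwrite earlier
        labels[phantom.masks[name]] = code
    nib.save(nib.Nifti1Image(labels, aff), directory / f"{stem}_masks.nii.gz")
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "voxel_size_mm": float(phantom.voxel_size),
        "origin_mm": [float(x) for x in phantom.origin],
        "mask_labels": MASK_LABELS,
        "spec": _plain(asdict(phantom.spec)) if phantom.spec else None,
    }
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(sidecar))
    return directory / f"{stem}.yaml"


def load_phantom(directory, stem: str = "phantom") -> Phantom:
    directory = Path(directory)
    sidecar = yaml.safe_load((directory / f"{stem}.yaml").read_text())
    density = np.asarray(
        nib.load(directory / f"{stem}_density.nii.gz").dataobj,
        dtype=np.float32)
    labels = np.asarray(
        nib.load(directory / f"{stem}_masks.nii.gz").dataobj, dtype=np.uint8)
    # overlapping structures were flattened by priority; rebuild supersets
    masks = {name: labels >= 1 if name == "body" else labels == code
             for name, code in sidecar["mask_labels"].items()}
    spec = PhantomSpec(**sidecar["spec"]) if sidecar.get("spec") else None
    return Phantom(density=density, masks=masks,
                   origin=np.array(sidecar["origin_mm"]),
                   voxel_size=float(sidecar["voxel_size_mm"]), spec=spec)


def save_dose(dose: DoseGrid, directory, stem: str = "dose") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(dose.dose.astype(np.float32),
                             _affine(dose.origin, dose.voxel_size)),
             directory / f"{stem}.nii.gz")
    sidecar = {"format_version": _FORMAT_VERSION, "units": "cGy",
               "voxel_size_mm": float(dose.voxel_size),
               "origin_mm": [float(x) for x in dose.origin]}
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(sidecar))
    return directory / f"{stem}.yaml"


def load_dose(directory, stem: str = "dose") -> DoseGrid:
    directory = Path(directory)
    sidecar = yaml.safe_load((directory / f"{stem}.yaml").read_text())
    arr = np.asarray(nib.load(directory / f"{stem}.nii.gz").dataobj,
                     dtype=float)
    return DoseGrid(arr, np.array(sidecar["origin_mm"]),
                    float(sidecar["voxel_size_mm"]))


# -- models ----------------------------------------------------------------

def save_energy_model(model: EnergyModel, path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "mean": model.mean.tolist(),
        "axes": model.axes.tolist(),
        "boundary_normal": model.boundary_normal.tolist(),
        "boundary_offset": float(model.boundary_offset),
        "training_scores": model.training_scores.tolist(),
        "training_labels": list(model.training_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_energy_model(path) -> EnergyModel:
    p = json.loads(Path(path).read_text())
    if p.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported energy-model format version")
    return EnergyModel(mean=np.array(p["mean"]), axes=np.array(p["axes"]),
                       boundary_normal=np.array(p["boundary_normal"]),
                       boundary_offset=p["boundary_offset"],
                       training_scores=np.array(p["training_scores"]),
                       training_labels=p["training_labels"])


def save_fluence_model(model: FluenceModel, path) -> None:
    """Versioned binary container with an embedded schema manifest."""
    joblib.dump({"format_version": _FORMAT_VERSION,
                 "schema_version": model.schema_version,
                 "feature_names": model.feature_names,
                 "oob_score": model.oob_score,
                 "n_trees": model.n_trees,
                 "forest": model.forest}, path)


def load_fluence_model(path) -> FluenceModel:
    p = joblib.load(path)
    if p.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"fluence model schema {p.get('schema_version')!r} does not "
            f"match runtime schema {SCHEMA_VERSION!r}")
    return FluenceModel(forest=p["forest"], schema_version=p["schema_version"],
                        feature_names=tuple(p["feature_names"]),
                        oob_score=p["oob_score"], n_trees=p["n_trees"])


def save_split_model(model: SplitModel, path) -> None:
    Path(path).write_text(json.dumps({
        "format_version": _FORMAT_VERSION,
        "bin_centers_cm": model.bin_centers_cm.tolist(),
        "low_fraction": model.low_fraction.tolist()}, indent=1))


def load_split_model(path) -> SplitModel:
    p = json.loads(Path(path).read_text())
    return SplitModel(bin_centers_cm=np.array(p["bin_centers_cm"]),
                      low_fraction=np.array(p["low_fraction"]))
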