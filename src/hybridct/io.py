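"""Persistence: NIfTI-1 volumes, multi-page TIFF projections, JSON sidecars.

Volumes (phantom maps, reconstructions, label maps) are NIfTI-1 with the
voxel size in the header zooms; projection stacks are one multi-page TIFF
per channel (pages = views) plus a JSON sidecar carrying the scan geometry,
detector description, domain and flat fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .corrections import BeamHardeningModel, GainRatioProjection
from .decompose import SensitivityMatrix
from .geometry import ScanGeometry
from .phantoms import DigitalPhantom
from .recon import ReconVolumeSet
from .simulate import ProjectionSet


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def save_volume(path, data: np.ndarray, voxel_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_mm))
    img.header.set_zooms((voxel_mm,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def save_recon(path, recon: ReconVolumeSet) -> None:
    """4-D NIfTI (x, y, z, channel) plus a .json sidecar with labels."""
    path = Path(path)
    save_volume(path, recon.volumes, recon.voxel_size)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    Path(f"{sidecar}.json").write_text(json.dumps(
        {"channel_labels": list(recon.labels), "units": "cm^-1",
         "voxel_size_mm": recon.voxel_size}, indent=2))


def load_recon(path) -> ReconVolumeSet:
    path = Path(path)
    data, voxel = load_volume(path)
    sidecar = Path(f"{path.with_suffix('').with_suffix('')}.json")
    labels = tuple(json.loads(sidecar.read_text())["channel_labels"])
    return ReconVolumeSet(np.asarray(data, float), voxel, labels)


def save_phantom(directory, phantom: DigitalPhantom) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in phantom.materials.items():
        save_volume(directory / f"{name}.nii.gz", arr, phantom.voxel_size)
    if phantom.label_map is not None:
        save_volume(directory / "labels.nii.gz",
                    phantom.label_map.astype(np.int32), phantom.voxel_size)
    (directory / "phantom.json").write_text(json.dumps(
        {"voxel_size_mm": phantom.voxel_size,
         "materials": list(phantom.materials),
         "meta": _jsonable(phantom.meta)}, indent=2))


def load_phantom(directory) -> DigitalPhantom:
    directory = Path(directory)
    info = json.loads((directory / "phantom.json").read_text())
    materials = {}
    for name in info["materials"]:
        arr, _ = load_volume(directory / f"{name}.nii.gz")
        materials[name] = np.asarray(arr, float)
    labels = None
    if (directory / "labels.nii.gz").exists():
        arr, _ = load_volume(directory / "labels.nii.gz")
        labels = np.asarray(arr).astype(np.int32)
    return DigitalPhantom(materials=materials,
                          voxel_size=info["voxel_size_mm"],
                          label_map=labels, meta=info.get("meta", {}))


def save_projections(directory, proj: ProjectionSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, stack in proj.channels.items():
        tifffile.imwrite(directory / f"{label}.tif",
                         stack.astype(np.float32))
        tifffile.imwrite(directory / f"{label}_flat.tif",
                         np.asarray(proj.flat[label], np.float32))
    sidecar = {"domain": proj.domain,
               "geometry": dataclasses.asdict(proj.geometry),
               "channels": list(proj.channels),
               "meta": _jsonable(proj.meta)}
    (directory / "projections.json").write_text(json.dumps(sidecar, indent=2))


def load_projections(directory) -> ProjectionSet:
    directory = Path(directory)
    info = json.loads((directory / "projections.json").read_text())
    geometry = ScanGeometry(**info["geometry"])
    channels, flat = {}, {}
    for label in info["channels"]:
        channels[label] = np.asarray(
            tifffile.imread(directory / f"{label}.tif"), float).reshape(
                geometry.n_views, geometry.n_rows, geometry.n_cols)
        flat[label] = np.asarray(
            tifffile.imread(directory / f"{label}_flat.tif"), float)
    return ProjectionSet(channels=channels, flat=flat, domain=info["domain"],
                         geometry=geometry, meta=info.get("meta", {}))


def save_gain_ratio(directory, ratio: GainRatioProjection) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, arr in ratio.ratios.items():
        tifffile.imwrite(directory / f"ratio_{label}.tif",
                         arr.astype(np.float32))
    (directory / "gain_ratio.json").write_text(json.dumps(
        {"median_size": list(ratio.median_size),
         "column_mask": ratio.column_mask.astype(int).tolist(),
         "channels": list(ratio.ratios), "meta": _jsonable(ratio.meta)},
        indent=2))


def load_gain_ratio(directory) -> GainRatioProjection:
    directory = Path(directory)
    info = json.loads((directory / "gain_ratio.json").read_text())
    ratios = {label: np.asarray(
        tifffile.imread(directory / f"ratio_{label}.tif"), float)
        for label in info["channels"]}
    return GainRatioProjection(
        ratios=ratios, median_size=tuple(info["median_size"]),
        column_mask=np.asarray(info["column_mask"], bool),
        meta=info.get("meta", {}))


def save_sensitivity(path, sens: SensitivityMatrix) -> None:
    Path(path).write_text(json.dumps(
        {"M": sens.M.tolist(), "channel_labels": list(sens.channel_labels),
         "materials": list(sens.materials),
         "units": {"water": "cm^-1 per g/mL", "iodine": "cm^-1 per mg/mL"}},
        indent=2))


def load_sensitivity(path) -> SensitivityMatrix:
    info = json.loads(Path(path).read_text())
    return SensitivityMatrix(M=np.asarray(info["M"], float),
                             channel_labels=tuple(info["channel_labels"]),
                             materials=tuple(info["materials"]))


def save_beam_hardening(path, model: BeamHardeningModel) -> None:
    Path(path).write_text(json.dumps(
        {"coeffs": model.coeffs.tolist(),
         "mu_ref_per_mm": model.mu_ref_per_mm,
         "effective_kev": model.effective_kev,
         "meta": _jsonable(model.meta)}, indent=2))


def load_beam_hardening(path) -> BeamHardeningModel:
    info = json.loads(Path(path).read_text())
    return BeamHardeningModel(coeffs=np.asarray(info["coeffs"], float),
                              mu_ref_per_mm=info["mu_ref_per_mm"],
                              effective_kev=info["effective_kev"],
                              meta=info.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
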