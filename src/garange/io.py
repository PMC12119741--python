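"""NIfTI / CSV / JSON persistence for volumes, kernels, sinograms and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import DigitalPatient, VoxelGrid
from .projector import Sinogram, SinogramGeometry
from .range_kernel import RangeKernel

__all__ = [
    "save_volume",
    "load_volume",
    "save_patient",
    "save_kernel",
    "load_kernel",
    "save_sinogram",
    "load_sinogram",
    "cohort_manifest",
]


def _affine(spacing, origin) -> np.ndarray:
    """RAS+ affine with voxel spacing on the diagonal."""
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(path: str | Path, data: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(grid.spacing, grid.origin))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    grid = VoxelGrid(shape=data.shape,
                     spacing=tuple(float(aff[i, i]) for i in range(3)),
                     origin=tuple(float(aff[i, 3]) for i in range(3)))
    return data, grid


def save_patient(directory: str | Path, patient: DigitalPatient) -> None:
    """Write activity/mu/labels NIfTIs plus a JSON metadata sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pid = patient.meta.patient_id
    save_volume(d / f"{pid}_activity.nii", patient.activity, patient.grid)
    save_volume(d / f"{pid}_mu.nii", patient.mu_map, patient.grid)
    save_volume(d / f"{pid}_labels.nii", patient.labels.astype(np.float32),
                patient.grid)
    meta = {
        "patient_id": pid,
        "weight_kg": patient.meta.weight,
        "injected_activity_MBq": patient.meta.injected_activity,
        "seed": patient.meta.seed,
        "lesions": [
            {"center_mm": list(l.center), "volume_cm3": l.volume,
             "tissue": l.tissue, "uptake_suv": l.uptake}
            for l in patient.lesions
        ],
        "note": "synthetic digital patient; lesion uptake levels are "
                "placeholders, not clinical values",
    }
    (d / f"{pid}_meta.json").write_text(json.dumps(meta, indent=2))


def save_kernel(path: str | Path, kernel: RangeKernel) -> None:
    """Kernel as NIfTI with a JSON sidecar holding the generation metadata."""
    path = Path(path)
    img = nib.Nifti1Image(kernel.values.astype(np.float64),
                          np.diag(list(kernel.spacing) + [1.0]))
    nib.save(img, str(path))
    sidecar = {
        "radionuclide": kernel.radionuclide,
        "spacing_mm": list(kernel.spacing),
        "mean_range_mm": kernel.mean_range,
        "n_samples": kernel.n_samples,
        "seed": kernel.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_kernel(path: str | Path) -> RangeKernel:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RangeKernel(radionuclide=meta["radionuclide"],
                       spacing=tuple(meta["spacing_mm"]),
                       values=values, mean_range=meta["mean_range_mm"],
                       n_samples=meta["n_samples"], seed=meta["seed"])


def save_sinogram(path: str | Path, sino: Sinogram) -> None:
    path = Path(path)
    img = nib.Nifti1Image(sino.values.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    g = sino.geometry
    sidecar = {
        "kind": sino.kind,
        "n_angles": g.n_angles, "n_bins": g.n_bins,
        "bin_spacing_mm": g.bin_spacing, "n_slices": g.n_slices,
        "slice_scale": None if sino.slice_scale is None else list(sino.slice_scale),
        "background_flat": (None if sino.background_mean is None
                            else float(sino.background_mean.flat[0])),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    geo = SinogramGeometry(meta["n_angles"], meta["n_bins"],
                           meta["bin_spacing_mm"], meta["n_slices"])
    scale = (None if meta["slice_scale"] is None
             else np.asarray(meta["slice_scale"], dtype=float))
    bg = (None if meta["background_flat"] is None
          else np.full_like(values, meta["background_flat"]))
    return Sinogram(geo, values, kind=meta["kind"], slice_scale=scale,
                    background_mean=bg)


def cohort_manifest(patients: list[DigitalPatient]) -> pd.DataFrame:
    """Tidy per-lesion cohort manifest (one row per lesion, patients repeated)."""
    rows = []
    for p in patients:
        base = {"patient_id": p.meta.patient_id, "weight_kg": p.meta.weight,
                "injected_activity_MBq": p.meta.injected_activity,
                "seed": p.meta.seed}
        if not p.lesions:
            rows.append({**base, "lesion": None})
        for k, les in enumerate(p.lesions):
            rows.append({**base, "lesion": k, "tissue": les.tissue,
                         "volume_cm3": les.volume, "uptake_suv": les.uptake})
    return pd.DataFrame(rows)
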