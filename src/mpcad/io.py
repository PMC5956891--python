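"""NIfTI and tabular I/O for patient cases and detections."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CHANNEL_ORDER, PatientCase
from .regions import CandidateRegion


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(path, volume: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def save_mask(path, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), spacing


def save_case(case: PatientCase, out_dir) -> None:
    """Write the 9 channels, masks and a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in CHANNEL_ORDER:
        save_volume(out / f"{name}.nii.gz", case.channels[name], case.voxel_spacing)
    save_mask(out / "gland_mask.nii.gz", case.gland_mask, case.voxel_spacing)
    save_mask(out / "truth_mask.nii.gz", case.truth_mask, case.voxel_spacing)
    sidecar = {"patient_id": case.patient_id,
               "voxel_spacing": list(case.voxel_spacing),
               "bvalues": list(case.bvalues),
               "channels": list(CHANNEL_ORDER)}
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))


def load_case(case_dir) -> PatientCase:
    d = Path(case_dir)
    sidecar = json.loads((d / "case.json").read_text())
    channels = {}
    spacing = tuple(sidecar["voxel_spacing"])
    for name in CHANNEL_ORDER:
        channels[name], _ = load_volume(d / f"{name}.nii.gz")
    gland, _ = load_volume(d / "gland_mask.nii.gz")
    truth_path = d / "truth_mask.nii.gz"
    if truth_path.exists():
        truth, _ = load_volume(truth_path)
    else:
        truth = np.zeros_like(gland)
    return PatientCase(channels=channels, gland_mask=gland.astype(bool),
                       truth_mask=truth.astype(bool),
                       patient_id=sidecar["patient_id"],
                       voxel_spacing=spacing,
                       bvalues=tuple(sidecar.get("bvalues", (0, 100, 400, 1000))))


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        cr, cc = r.centroid
        rows.append({"region_id": r.region_id, "patient_id": r.patient_id,
                     "slice": r.slice_index, "area_vox": r.area,
                     "centroid_row": cr, "centroid_col": cc,
                     "label": r.label, "score": r.score})
    return pd.DataFrame(rows)


def save_detection(result, out_dir, spacing=(1.0, 1.0, 1.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(out / f"{result.stage}_mask.nii.gz", result.voxel_mask, spacing)
    regions_to_frame(result.regions).to_csv(out / f"{result.stage}_regions.csv",
                                            index=False)
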