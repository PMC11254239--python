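"""NIfTI / CSV / JSON artifact handling with content hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from habitomics.core import SEQUENCES, VolumeSet

#: column dictionary written next to every cohort CSV
COHORT_COLUMNS = {
    "patient_id": "unique patient identifier",
    "age": "age in years",
    "sex": "male | female",
    "cea": "carcinoembryonic antigen, <=5 | >5 ug/l",
    "ca19_9": "carbohydrate antigen 19-9, <=37 | >37 U/ml",
    "location": "tumor location: low | middle | high (distance from anal verge)",
    "t_stage": "radiological T stage: T1-T2 | T3-T4",
    "n_stage": "radiological N stage: N0 | N1-N2",
    "msi": "microsatellite status: 0 = MSS, 1 = MSI",
    "dfs_time": "disease-free survival time in months",
    "dfs_event": "1 = recurrence/metastasis observed, 0 = censored",
    "cohort": "training | external_test",
}


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path: Path, volume: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def save_labels(path: Path, labels: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path: Path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_cohort(
    outdir: Path,
    patients: List[Tuple[VolumeSet, np.ndarray]],
    table: pd.DataFrame,
) -> Dict:
    """Write per-patient NIfTI files, the cohort CSV, and a manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    manifest = {"patients": {}, "columns": COHORT_COLUMNS}
    for (vs, truth), pid in zip(patients, table["patient_id"]):
        pdir = outdir / "images" / pid
        pdir.mkdir(exist_ok=True)
        files = {}
        for seq in SEQUENCES:
            fname = pdir / f"{seq.replace('-', '')}.nii.gz"
            save_volume(fname, vs.sequences[seq], vs.voxel_spacing_mm)
            files[seq] = str(fname.relative_to(outdir))
        save_labels(pdir / "mask.nii.gz", vs.tumor_mask, vs.voxel_spacing_mm)
        save_labels(pdir / "truth.nii.gz", truth, vs.voxel_spacing_mm)
        files["mask"] = str((pdir / "mask.nii.gz").relative_to(outdir))
        files["truth"] = str((pdir / "truth.nii.gz").relative_to(outdir))
        manifest["patients"][pid] = files
    table.to_csv(outdir / "cohort.csv", index=False)
    manifest["cohort_csv"] = "cohort.csv"
    manifest["hashes"] = {
        p: file_hash(outdir / f)
        for files in manifest["patients"].values()
        for p, f in files.items()
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def load_cohort(outdir: Path) -> Tuple[List[Tuple[VolumeSet, np.ndarray]], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as f:
        manifest = json.load(f)
    table = pd.read_csv(outdir / manifest["cohort_csv"])
    patients = []
    for pid in table["patient_id"]:
        files = manifest["patients"][pid]
        sequences = {}
        spacing = None
        for seq in SEQUENCES:
            vol, spacing = load_volume(outdir / files[seq])
            sequences[seq] = vol
        mask, _ = load_volume(outdir / files["mask"])
        truth, _ = load_volume(outdir / files["truth"])
        vs = VolumeSet(
            sequences=sequences,
            tumor_mask=mask.astype(np.uint8),
            voxel_spacing_mm=spacing,
            patient_id=pid,
        )
        patients.append((vs, truth.astype(np.int16)))
    return patients, table
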