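"""On-disk formats: NIfTI rasters, CoR sidecars, cohort/curves/metrics CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mapping import FatFractionSlice

MASK_CODES = {"left": 1, "right": 2}


def slice_basename(subject: str, level: str, slice_index: int) -> str:
    return f"{subject}_{level}_s{slice_index}"


def write_slice(slc: FatFractionSlice, outdir: Path) -> list[Path]:
    """Write one slice as fat + integer-coded mask NIfTI pair plus a JSON
    sidecar holding the CoR and tags. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = slice_basename(slc.subject, slc.level, slc.slice_index)
    affine = np.diag([slc.pixel_spacing, slc.pixel_spacing, 1.0, 1.0])

    fat_path = outdir / f"{base}_fat.nii"
    nib.save(nib.Nifti1Image(slc.fat.astype(np.float32), affine), fat_path)

    codes = np.zeros(slc.fat.shape, dtype=np.uint8)
    for side, m in slc.masks.items():
        codes[m] = MASK_CODES[side]
    mask_path = outdir / f"{base}_mask.nii"
    nib.save(nib.Nifti1Image(codes, affine), mask_path)

    meta = {
        "subject": slc.subject,
        "level": slc.level,
        "slice_index": slc.slice_index,
        "cor": list(slc.cor),
        "pixel_spacing": slc.pixel_spacing,
    }
    meta_path = outdir / f"{base}.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return [fat_path, mask_path, meta_path]


def read_slice(outdir: Path, subject: str, level: str, slice_index: int) -> FatFractionSlice:
    base = Path(outdir) / slice_basename(subject, level, slice_index)
    meta = json.loads((base.parent / f"{base.name}.json").read_text())
    fat = np.asanyarray(nib.load(f"{base}_fat.nii").dataobj, dtype=float)
    codes = np.asanyarray(nib.load(f"{base}_mask.nii").dataobj)
    masks = {side: codes == code for side, code in MASK_CODES.items() if (codes == code).any()}
    return FatFractionSlice(
        fat=fat,
        masks=masks,
        cor=tuple(meta["cor"]),
        level=meta["level"],
        slice_index=meta["slice_index"],
        pixel_spacing=meta["pixel_spacing"],
        subject=meta["subject"],
    )


def read_cohort_slices(images_dir: Path, cohort: pd.DataFrame, levels=("L4L5", "L5S1"),
                       slice_indices=(1, 2)):
    """subject id -> level -> list of slices, for every subject in the cohort."""
    out: dict[str, dict[str, list[FatFractionSlice]]] = {}
    for sid in cohort["id"]:
        out[sid] = {
            level: [read_slice(images_dir, sid, level, k) for k in slice_indices]
            for level in levels
        }
    return out
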