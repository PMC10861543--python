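"""File interchange: NIfTI volumes with FSL-style bval/bvec sidecars,
waveform CSV/JSON export, phantom serialization, ROI stats CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .reconstruct import ROIStats, ScalarMap
from .simulate import DWIDataset
from .waveforms import GradientWaveform, gradient_moments, numerical_bvalue

__all__ = [
    "save_dwi", "load_dwi", "save_scalar_map",
    "save_waveform", "load_waveform",
    "save_phantom", "roi_stats_to_csv",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_dwi(dwi: DWIDataset, prefix: str | Path) -> dict:
    """Write ``<prefix>.nii`` + ``.bval``/``.bvec`` + ``<prefix>_mask.nii``.

    bval/bvec follow the FSL convention: one space-separated row of
    b-values, and three rows (x, y, z components) for the directions.
    Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(dwi.voxel_size)
    paths = {
        "nii": prefix.with_suffix(".nii"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
        "mask": prefix.parent / (prefix.name + "_mask.nii"),
    }
    nib.save(nib.Nifti1Image(dwi.volumes.astype(np.float32), aff), paths["nii"])
    nib.save(nib.Nifti1Image(dwi.mask.astype(np.uint8), aff), paths["mask"])
    np.savetxt(paths["bval"], dwi.bvals[None, :], fmt="%.6g")
    np.savetxt(paths["bvec"], dwi.bvecs.T, fmt="%.10g")
    return paths


def load_dwi(prefix: str | Path) -> DWIDataset:
    """Read a dataset written by :func:`save_dwi`."""
    prefix = Path(prefix)
    img = nib.load(prefix.with_suffix(".nii"))
    volumes = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T.reshape(-1, 3)
    mask_path = prefix.parent / (prefix.name + "_mask.nii")
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    else:
        mask = np.ones(volumes.shape[:3], dtype=bool)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIDataset(volumes, bvals, bvecs, mask, voxel_size=voxel_size)


def save_scalar_map(scalar_map: ScalarMap, path: str | Path,
                    voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a scalar map volume (NaN outside validity) to NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.where(scalar_map.valid, scalar_map.data, np.nan)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(voxel_size)),
             path)
    return path


def save_waveform(wf: GradientWaveform, csv_path: str | Path) -> dict:
    """Two-column CSV (time_s, amplitude_T_per_m) plus a JSON header with
    dt, refocus index, gamma, achieved b-value and moments."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": wf.times,
                  "amplitude_T_per_m": wf.samples}).to_csv(csv_path,
                                                           index=False)
    gamma = wf.meta.get("gamma")
    mom = gradient_moments(wf)
    header = {
        "dt": wf.dt,
        "n_samples": int(wf.n_samples),
        "refocus_index": wf.refocus_index,
        "gamma": gamma,
        "b_value_s_per_mm2": wf.meta.get(
            "b_value", numerical_bvalue(wf) if gamma is None
            else numerical_bvalue(wf, gamma)),
        "moments": {"m0": mom.m0, "m1": mom.m1, "m2": mom.m2},
        "design": wf.meta.get("design"),
    }
    json_path = csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(header, indent=2))
    return {"csv": csv_path, "json": json_path}


def load_waveform(csv_path: str | Path) -> GradientWaveform:
    """Read a waveform written by :func:`save_waveform`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    header = json.loads(csv_path.with_suffix(".json").read_text())
    meta = {k: header[k] for k in ("b_value_s_per_mm2", "gamma", "design")
            if header.get(k) is not None}
    if "b_value_s_per_mm2" in meta:
        meta["b_value"] = meta.pop("b_value_s_per_mm2")
    return GradientWaveform(df["amplitude_T_per_m"].to_numpy(),
                            float(header["dt"]),
                            refocus_index=header.get("refocus_index"),
                            meta=meta)


def save_phantom(phantom, prefix: str | Path) -> dict:
    """Write the region map as a NIfTI label volume and a JSON summary of
    the region table (names, ground-truth MD, motion parameters)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    label_path = prefix.parent / (prefix.name + "_labels.nii")
    nib.save(nib.Nifti1Image(phantom.region_map.astype(np.int16),
                             _affine(phantom.voxel_size)), label_path)
    summary = {
        "shape": list(phantom.shape),
        "voxel_size_mm": list(phantom.voxel_size),
        "regions": {
            str(lab): {
                "name": phantom.region_names.get(lab, f"region_{lab}"),
                "true_md_mm2_per_s": phantom.true_md.get(lab),
                "n_voxels": int((phantom.region_map == lab).sum()),
            } for lab in phantom.labels
        },
        "motion": {
            "r0_m": list(phantom.motion.r0),
            "v_m_per_s": list(phantom.motion.v),
            "a_m_per_s2": list(phantom.motion.a),
            "v_spread_m_per_s": phantom.motion.v_spread,
        },
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2))
    return {"labels": label_path, "json": json_path}


def roi_stats_to_csv(stats: Sequence[ROIStats], path: str | Path,
                     scale: float = 1.0, units: str | None = None) -> Path:
    """ROI stats as CSV (region, n_voxels, mean, sd, units).

    ``scale`` rescales mean/sd (e.g. 1e3 to report ADC in 10⁻³ mm²/s).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "region": s.name,
        "n_voxels": s.n_voxels,
        "mean": s.mean * scale,
        "sd": s.sd * scale,
        "units": units if units is not None else s.units,
    } for s in stats]).to_csv(path, index=False)
    return path
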