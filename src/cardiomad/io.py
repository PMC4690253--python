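"""Readers and writers for the pipeline's on-disk formats.

Echo series are stored as 4-D NIfTI-1 (x, y, slice, echo) with a JSON
sidecar carrying the echo times; T2 maps as float NIfTI volumes plus a
diagnostics volume and a JSON fit report; contours, models and reports as
JSON; tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .segmentation import ContourSet
from .t2fit import EchoSeries, T2Map

__all__ = [
    "save_echo_series", "load_echo_series",
    "save_t2map", "load_t2map",
    "save_labels", "load_labels",
    "save_contours", "load_contours",
    "save_table", "load_table",
    "save_json", "load_json",
]

SEGMENT_COLUMNS = ["subject_id", "segment_id", "mean_T2_ms", "pixel_SD_ms",
                   "n_pixels", "level", "ok"]
FEATURE_CSV_COLUMNS = ["subject_id", "label", "globalT2", "globalSD",
                       "maxT2", "maxSD", "madT2", "madSD"]


def _affine(pixel_spacing: float = 2.0, slice_thickness: float = 10.0) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def save_echo_series(series: EchoSeries, stem, pixel_spacing: float = 2.0,
                     slice_thickness: float = 10.0) -> tuple[Path, Path]:
    """Write ``<stem>.nii.gz`` (4-D magnitudes) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.magnitudes.astype(np.float32),
                          _affine(pixel_spacing, slice_thickness))
    nii = stem.with_suffix(".nii.gz")
    nib.save(img, nii)
    sidecar = stem.with_suffix(".json")
    meta = {"echo_times_ms": series.echo_times_ms.tolist()}
    sidecar.write_text(json.dumps(meta, indent=1))
    if series.mask is not None:
        nib.save(nib.Nifti1Image(series.mask.astype(np.uint8),
                                 _affine(pixel_spacing, slice_thickness)),
                 stem.parent / (stem.name + "_mask.nii.gz"))
    return nii, sidecar


def load_echo_series(stem) -> EchoSeries:
    stem = Path(stem)
    img = nib.load(stem.with_suffix(".nii.gz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    mask_path = stem.parent / (stem.name + "_mask.nii.gz")
    mask = np.asarray(nib.load(mask_path).dataobj).astype(bool) if mask_path.exists() else None
    return EchoSeries(magnitudes=np.asarray(img.dataobj, dtype=float),
                      echo_times_ms=np.asarray(meta["echo_times_ms"], dtype=float),
                      mask=mask)


def save_t2map(t2map: T2Map, stem, pixel_spacing: float = 2.0,
               slice_thickness: float = 10.0) -> Path:
    """Write ``<stem>.nii.gz`` (T2 in ms), a diagnostics volume and a JSON
    fit report."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(pixel_spacing, slice_thickness)
    nii = stem.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(t2map.T2_ms.astype(np.float32), aff), nii)
    diag = np.stack([t2map.A, t2map.sigma, t2map.loglik,
                     t2map.converged.astype(float)], axis=-1)
    nib.save(nib.Nifti1Image(diag.astype(np.float32), aff),
             stem.parent / (stem.name + "_diag.nii.gz"))
    nib.save(nib.Nifti1Image(t2map.mask.astype(np.uint8), aff),
             stem.parent / (stem.name + "_fitmask.nii.gz"))
    report = {
        "method": t2map.method,
        "n_fitted": int(t2map.mask.sum()),
        "n_converged": int(t2map.converged.sum()),
        "median_T2_ms": float(np.nanmedian(t2map.T2_ms[t2map.mask])),
    }
    (stem.parent / (stem.name + "_fit.json")).write_text(json.dumps(report, indent=1))
    return nii


def load_t2map(stem) -> T2Map:
    stem = Path(stem)
    t2 = np.asarray(nib.load(stem.with_suffix(".nii.gz")).dataobj, dtype=float)
    diag = np.asarray(nib.load(stem.parent / (stem.name + "_diag.nii.gz")).dataobj,
                      dtype=float)
    mask = np.asarray(nib.load(stem.parent / (stem.name + "_fitmask.nii.gz")).dataobj
                      ).astype(bool)
    report = json.loads((stem.parent / (stem.name + "_fit.json")).read_text())
    return T2Map(T2_ms=t2, A=diag[..., 0], sigma=diag[..., 1], loglik=diag[..., 2],
                 converged=diag[..., 3] > 0.5, method=report["method"], mask=mask)


def save_labels(labels: np.ndarray, path, pixel_spacing: float = 2.0,
                slice_thickness: float = 10.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.int16),
                             _affine(pixel_spacing, slice_thickness)), path)
    return path


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj).astype(np.int16)


def save_contours(contours: ContourSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(contours.to_json())
    return path


def load_contours(path) -> ContourSet:
    return ContourSet.from_json(Path(path).read_text())


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
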