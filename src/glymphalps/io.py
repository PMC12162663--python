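"""File formats: NIfTI-1 volumes, FSL-style bval/bvec, ROI JSON,
cohort CSV, and report tables.

Conventions: NIfTI-1 with RAS-positive affines; bvec in FSL image-space
convention (3 rows: x, y, z); all voxel coordinates in interfaces are
0-based with axis order x, y, z.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alps import ROI, ROISet
from .gradients import GradientScheme
from .phantom import DWIVolume, GroundTruth
from .tensorfit import DiffusivityMaps

__all__ = [
    "write_dwi",
    "read_dwi",
    "write_scheme",
    "read_scheme",
    "write_maps",
    "write_ground_truth",
    "roiset_to_json",
    "roiset_from_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "CohortValidationError",
]

# column dictionary for the cohort CSV (name -> kind used in validation)
COHORT_COLUMNS = {
    "subject_id": "id",
    "group": "group",
    "timepoint": "timepoint",
    "gender": "categorical",
    "age": "numeric",
    "education": "numeric",
    "moca": "numeric",
    "mmse": "numeric",
    "bai": "numeric",
    "bdi": "numeric",
    "psqi": "numeric",
    "ess": "numeric",
    "isi": "numeric",
    "total_sleep_time": "duration",
    "sleep_efficiency": "percent",
    "sleep_onset_latency": "duration",
    "waso": "duration",
    "n1_duration": "duration",
    "n2_duration": "duration",
    "n3_duration": "duration",
    "rem_duration": "duration",
    "arousal_index": "duration",
    "ahi": "duration",
    "odi3": "duration",
    "mean_spo2": "percent",
    "max_oa_duration": "duration",
    "plms_index": "duration",
    "alps": "numeric",
}

_REQUIRED = ("subject_id", "group", "timepoint")


class CohortValidationError(ValueError):
    """Cohort CSV violated an invariant; message names offending rows."""


def write_scheme(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """FSL-style gradient table: one row of b-values, three rows of components."""
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    b = np.loadtxt(bval_path).ravel()
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3:
        g = g.T
    return GradientScheme(b_values=b, directions=g)


def write_dwi(dwi: DWIVolume, nifti_path: str | Path, bval_path: str | Path | None = None, bvec_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine)
    img.header.set_zooms((*dwi.voxel_size, 1.0))
    nib.save(img, str(nifti_path))
    if bval_path is not None and bvec_path is not None:
        write_scheme(dwi.scheme, bval_path, bvec_path)


def read_dwi(nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DWIVolume:
    img = nib.load(str(nifti_path))
    scheme = read_scheme(bval_path, bvec_path)
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return DWIVolume(signal=data, voxel_size=tuple(float(z) for z in zooms), affine=img.affine, scheme=scheme)


def write_maps(maps: DiffusivityMaps, out_dir: str | Path) -> dict[str, Path]:
    """dxx/dyy/dzz/fa/color-FA (plus the valid mask) as NIfTI-1 maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*maps.voxel_size, 1.0])
    paths = {}
    for name, arr in (
        ("dxx", maps.dxx),
        ("dyy", maps.dyy),
        ("dzz", maps.dzz),
        ("fa", maps.fa),
        ("color_fa", maps.color_fa),
        ("valid", maps.valid.astype(np.uint8)),
    ):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        paths[name] = p
    return paths


def write_ground_truth(truth: GroundTruth, label_path: str | Path, sidecar_path: str | Path) -> None:
    """Region label map as NIfTI plus a JSON sidecar with alps_true."""
    affine = np.diag([*truth.spec.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(truth.labels.astype(np.int16), affine), str(label_path))
    sidecar = {
        "alps_true": truth.alps_true,
        "lambda_parallel": truth.spec.lambda_parallel,
        "lambda_perp": truth.spec.lambda_perp,
        "alpha": truth.spec.alpha,
        "csf_diffusivity": truth.spec.csf_diffusivity,
        "units": "1e-3 mm^2/s",
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def roiset_to_json(rois: ROISet, path: str | Path | None = None) -> str:
    payload = {
        "slice_index": rois.slice_index,
        "coordinate_convention": "0-based voxel indices, axis order x,y,z",
        "rois": [
            {
                "fiber": r.fiber,
                "hemisphere": r.hemisphere,
                "center": list(r.center),
                "diameter_mm": r.diameter_mm,
            }
            for r in rois.rois
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def roiset_from_json(source: str | Path) -> ROISet:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    rois = tuple(
        ROI(
            fiber=r["fiber"],
            hemisphere=r["hemisphere"],
            center=tuple(int(c) for c in r["center"]),
            diameter_mm=float(r.get("diameter_mm", 5.0)),
        )
        for r in payload["rois"]
    )
    return ROISet(slice_index=int(payload["slice_index"]), rois=rois)


def validate_cohort(table: pd.DataFrame) -> None:
    """Invariant checks; raises CohortValidationError naming row indices."""
    for col in _REQUIRED:
        if col not in table.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    dup = table.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise CohortValidationError(f"duplicate (subject_id, timepoint) at rows {list(table.index[dup])}")
    bad_tp = ~table["timepoint"].isin(["pre", "post"])
    if bad_tp.any():
        raise CohortValidationError(f"unknown timepoint at rows {list(table.index[bad_tp])}")
    bad_grp = ~table["group"].isin(["HC", "true_rTMS", "sham_rTMS"])
    if bad_grp.any():
        raise CohortValidationError(f"unknown group at rows {list(table.index[bad_grp])}")
    hc_post = (table["group"] == "HC") & (table["timepoint"] != "pre")
    if hc_post.any():
        raise CohortValidationError(f"HC rows must be timepoint 'pre'; offending rows {list(table.index[hc_post])}")
    for col, kind in COHORT_COLUMNS.items():
        if col not in table.columns:
            continue
        if kind == "percent":
            bad = table[col].notna() & ((table[col] < 0) | (table[col] > 100))
            if bad.any():
                raise CohortValidationError(f"{col} outside [0, 100] at rows {list(table.index[bad])}")
        elif kind == "duration":
            bad = table[col].notna() & (table[col] < 0)
            if bad.any():
                raise CohortValidationError(f"{col} negative at rows {list(table.index[bad])}")


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table)
    table.to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Typed, validated cohort table; unknown columns pass through."""
    table = pd.read_csv(path)
    validate_cohort(table)
    return table
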