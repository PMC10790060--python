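"""On-disk formats: TSV for tables, NIfTI for volumes, JSON for provenance.

All tabular round-trips are lossless for the precision written (full
``repr`` precision is used for floats), and NIfTI affines are carried
through unmodified.  Voxel indices are 0-based internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .entropy import EntropyParams, RawCSEMatrix
from .preprocess import ROITimeSeries
from .simulate import AtlasVolume
from .volumes import CSEVolume

__all__ = [
    "write_timeseries_tsv", "read_timeseries_tsv",
    "write_manifest_tsv", "read_manifest_tsv",
    "write_motion_tsv", "read_motion_tsv",
    "write_cse_matrix_tsv", "read_cse_matrix_tsv",
    "write_atlas_nifti", "read_atlas_nifti",
    "write_cse_volume_nifti", "read_cse_volume_nifti",
    "write_reference_stats", "read_reference_stats",
    "write_report", "read_report",
]

_MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                   "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def write_timeseries_tsv(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=range(ts.n_timepoints))
    df.insert(0, "roi", ts.roi_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_tsv(
    path: str | Path, subject_id: str = "", tr_seconds: float = 2.0
) -> ROITimeSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        labels = [int(v) for v in df["roi"]]
        values = df.drop(columns="roi").to_numpy(dtype=float)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed time-series TSV {path}: {exc}") from exc
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        values=values, roi_labels=labels, tr_seconds=tr_seconds,
    )


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[["subject_id", "group", "binary_target"]].to_csv(
        path, sep="\t", index=False
    )


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "binary_target"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} lacks columns {required - set(df.columns)}")
    return df


def write_motion_tsv(trace: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(trace).T, columns=_MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_motion_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV {path} lacks columns {missing}")
    return df[_MOTION_COLUMNS].to_numpy(dtype=float).T


def write_cse_matrix_tsv(matrix: RawCSEMatrix, path: str | Path) -> None:
    """Matrix as TSV with ROI-label header plus a JSON parameter sidecar."""
    path = Path(path)
    pd.DataFrame(
        matrix.values, index=matrix.roi_labels, columns=matrix.roi_labels
    ).to_csv(path, sep="\t", float_format="%.17g", index_label="roi")
    sidecar = {
        "subject_id": matrix.subject_id,
        "params": {
            "m": matrix.params.m,
            "r": matrix.params.r,
            "undefined_policy": matrix.params.undefined_policy,
            "raw_units": matrix.params.raw_units,
            "include_self_pairs": matrix.params.include_self_pairs,
        },
        "n_undefined": int(matrix.undefined_mask.sum()),
        "undefined_entries": [
            [int(i), int(k)] for i, k in zip(*np.nonzero(matrix.undefined_mask))
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_cse_matrix_tsv(path: str | Path) -> RawCSEMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="roi", float_precision="round_trip")
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed CSE matrix TSV {path}: {exc}") from exc
    sidecar = json.loads(path.with_suffix(".json").read_text())
    values = df.to_numpy(dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    for i, k in sidecar.get("undefined_entries", []):
        mask[i, k] = True
    return RawCSEMatrix(
        subject_id=sidecar["subject_id"],
        values=values,
        params=EntropyParams(**sidecar["params"]),
        undefined_mask=mask,
        roi_labels=[int(v) for v in df.index],
    )


def write_atlas_nifti(atlas: AtlasVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.data.astype(np.int16), atlas.affine), str(path))


def read_atlas_nifti(path: str | Path, atlas_id: str = "") -> AtlasVolume:
    img = nib.load(str(path))
    return AtlasVolume(
        data=np.asarray(img.dataobj).astype(np.int32),
        affine=img.affine,
        atlas_id=atlas_id or Path(path).stem,
    )


def write_cse_volume_nifti(volume: CSEVolume, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(volume.values.astype(np.float32), volume.affine), str(path)
    )


def read_cse_volume_nifti(path: str | Path, seed_roi: int = 0) -> CSEVolume:
    img = nib.load(str(path))
    return CSEVolume(
        values=np.asarray(img.dataobj, dtype=float),
        seed_roi=seed_roi,
        affine=img.affine,
    )


def write_reference_stats(stats, path: str | Path) -> None:
    """Mean/SD matrices as a TSV pair plus JSON provenance."""
    from .volumes import ReferenceStats  # noqa: F401  (type of `stats`)

    path = Path(path)
    pd.DataFrame(stats.mean_matrix).to_csv(
        path.with_suffix(".mean.tsv"), sep="\t", index=False, header=False,
        float_format="%.17g",
    )
    pd.DataFrame(stats.sd_matrix).to_csv(
        path.with_suffix(".sd.tsv"), sep="\t", index=False, header=False,
        float_format="%.17g",
    )
    path.with_suffix(".json").write_text(json.dumps({
        "n_reference": stats.n_reference,
        "reference_ids": stats.reference_ids,
        "content_hash": stats.content_hash(),
    }, indent=1))


def read_reference_stats(path: str | Path):
    from .volumes import ReferenceStats

    path = Path(path)
    mean = pd.read_csv(path.with_suffix(".mean.tsv"), sep="\t", header=None,
                       float_precision="round_trip").to_numpy(float)
    sd = pd.read_csv(path.with_suffix(".sd.tsv"), sep="\t", header=None,
                     float_precision="round_trip").to_numpy(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ReferenceStats(
        mean_matrix=mean, sd_matrix=sd,
        n_reference=meta["n_reference"], reference_ids=meta["reference_ids"],
    )


def write_report(report: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    report.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if provenance is not None:
        path.with_suffix(".json").write_text(json.dumps(provenance, indent=1))


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
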