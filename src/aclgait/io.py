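"""Plain-text external interfaces.

CSV dialect for raw recordings (one file per sensor per repetition,
columns ``t,ax,ay,az,gx,gy,gz``), a dataset manifest
(``subject,cohort,trial,direction,sensor,path``), ground-truth event
tables, stride tables, feature matrices, registry manifests and
alignment reports (JSON).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import AlignedRepetition, ImuRecording, Repetition
from .features import FeatureRegistry
from .synth import Dataset

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_dataset_csvs",
    "write_stride_table",
    "read_stride_table",
    "write_feature_matrix",
    "write_registry_manifest",
    "write_alignment_report",
]

RAW_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def write_recording_csv(rec: ImuRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel, rec.gyro]), columns=RAW_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording_csv(path, sensor_id: str, nominal_rate: float = 100.0) -> ImuRecording:
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    return ImuRecording(
        sensor_id,
        df["t"].to_numpy(float),
        df[["ax", "ay", "az"]].to_numpy(float),
        df[["gx", "gy", "gz"]].to_numpy(float),
        nominal_rate,
    )


def write_dataset_csvs(dataset: Dataset, out_dir) -> Path:
    """Write one CSV per sensor per repetition plus manifest and truth.

    Returns the manifest path.  Ground-truth programmed events go to
    ``ground_truth.csv`` (one row per stride unit per limb).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows: List[dict] = []
    truth_rows: List[dict] = []
    for rep in dataset.iter_repetitions():
        stem = f"{rep.subject_id}_t{rep.trial_index:02d}"
        for sensor_id, rec in rep.recordings.items():
            rel = f"{stem}_{sensor_id}.csv"
            write_recording_csv(rec, out / rel)
            manifest_rows.append({
                "subject": rep.subject_id,
                "cohort": rep.cohort,
                "trial": rep.trial_index,
                "direction": rep.direction,
                "sensor": sensor_id,
                "path": rel,
            })
        if rep.truth is not None:
            for limb in ("left", "right"):
                ic = rep.truth.ic[limb]
                tc = rep.truth.tc[limb]
                for k in range(len(ic)):
                    truth_rows.append({
                        "subject": rep.subject_id,
                        "trial": rep.trial_index,
                        "limb": limb,
                        "stride": k,
                        "initial_contact": ic[k],
                        "terminal_contact": tc[k],
                    })
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return manifest


def write_stride_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_stride_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(X: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Feature matrix CSV: metadata columns first, then named features."""
    pd.concat([meta.reset_index(drop=True), X.reset_index(drop=True)], axis=1).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_registry_manifest(registry: FeatureRegistry, path) -> None:
    with open(path, "w") as fh:
        json.dump({"n_features": len(registry), "features": registry.manifest()},
                  fh, indent=1)


def write_alignment_report(aligned: AlignedRepetition, path) -> None:
    """Offsets, rotations and axis-fit diagnostics as JSON."""
    report = {
        "rate": aligned.rate,
        "n_samples": int(aligned.t.size),
        "offsets_s": {k: float(v) for k, v in aligned.offsets.items()},
        "rotations": {k: np.asarray(v).tolist() for k, v in aligned.rotations.items()},
        "seel": aligned.meta.get("seel", {}),
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
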