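"""File formats: NRRD/NIfTI volumes, CSV tables and JSON sidecars.

Volumes go through SimpleITK so spacing metadata survives round-trips in
either NRRD or NIfTI (chosen by file extension). Tables are plain UTF-8 CSV
with '.' decimals; feature-group labels live in a JSON sidecar next to the
feature CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .image import ImageVolume, TumorMask
from .features.extract import FEATURE_GROUPS, FeatureTable

__all__ = [
    "write_volume",
    "read_volume_pair",
    "write_feature_table",
    "read_feature_table",
    "write_clinical",
    "read_clinical",
    "write_assignment_csv",
    "read_assignment_csv",
]


def write_volume(path, values: np.ndarray, spacing) -> None:
    """Write a 3D array as NRRD or NIfTI (by extension) with spacing metadata."""
    img = sitk.GetImageFromArray(np.asarray(values, dtype=float))
    # SimpleITK spacing is (x, y, z) while arrays are indexed (z, y, x)
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    sitk.WriteImage(img, str(path))


def _read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), tuple(img.GetSpacing())[::-1]


def read_volume_pair(image_path, mask_path) -> tuple[ImageVolume, TumorMask]:
    """Read and validate an image/mask pair on the same grid.

    The mask must be binary up to a rounding tolerance of 1e-6.
    """
    values, spacing = _read_volume(image_path)
    mvalues, mspacing = _read_volume(mask_path)
    if values.shape != mvalues.shape or not np.allclose(spacing, mspacing, rtol=1e-6):
        raise ValueError(
            f"image and mask grids differ: image shape={values.shape} spacing={spacing}; "
            f"mask shape={mvalues.shape} spacing={mspacing}"
        )
    rounded = np.round(mvalues)
    if np.abs(mvalues - rounded).max() > 1e-6 or not np.all(np.isin(rounded, [0, 1])):
        raise ValueError(f"mask {mask_path} is not binary")
    return ImageVolume(values, spacing), TumorMask(rounded.astype(bool))


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV (patients x features) plus a `<name>.groups.json` sidecar."""
    path = Path(path)
    table.data.to_csv(path, index_label="patient_id")
    sidecar = path.with_suffix(path.suffix + ".groups.json")
    sidecar.write_text(json.dumps(dict(table.groups), indent=0))


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    data = pd.read_csv(path, index_col="patient_id")
    sidecar = path.with_suffix(path.suffix + ".groups.json")
    if sidecar.exists():
        groups = pd.Series(json.loads(sidecar.read_text()))
    else:
        groups = pd.Series(FEATURE_GROUPS)
    return FeatureTable(data=data, groups=groups)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df.set_index("patient_id", drop=False)


def write_assignment_csv(assignment, path) -> None:
    pd.DataFrame(
        {"feature": assignment.labels.index, "cluster": assignment.labels.to_numpy()}
    ).to_csv(path, index=False)


def read_assignment_csv(path):
    from .consensus import ClusterAssignment

    df = pd.read_csv(path)
    labels = pd.Series(df["cluster"].to_numpy(), index=df["feature"])
    return ClusterAssignment(labels=labels, k=int(labels.max()))
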