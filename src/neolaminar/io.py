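"""Readers and writers for the standard neuroimaging formats.

Surfaces, metrics and labels use GIFTI; volumes use NIfTI-1; tables use
CSV.  All functions round-trip losslessly up to the container's own
precision (GIFTI coordinate arrays are float32 on disk).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import gifti

from .equivolume import SurfaceMesh
from .errors import FormatError
from .phantom import COHORT_COLUMNS, validate_cohort
from .sampling import Volume

__all__ = [
    "read_surface", "write_surface",
    "read_volume", "write_volume",
    "read_metric", "write_metric",
    "read_labels", "write_labels",
    "read_cohort", "write_cohort",
]


def write_surface(path, mesh: SurfaceMesh) -> None:
    """Write a mesh as a GIFTI surface (.surf.gii)."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def read_surface(path) -> SurfaceMesh:
    """Read a GIFTI surface; requires pointset and triangle arrays."""
    img = nib.load(str(path))
    if not isinstance(img, gifti.GiftiImage):
        raise FormatError(f"{path} is not a GIFTI file")
    points = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
    if not points:
        raise FormatError(f"{path}: missing NIFTI_INTENT_POINTSET array")
    if not tris:
        raise FormatError(f"{path}: missing NIFTI_INTENT_TRIANGLE array")
    return SurfaceMesh(points[0].data.astype(np.float64),
                       tris[0].data.astype(np.int64))


def write_volume(path, volume: Volume) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz)."""
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI volume; raises on a singular affine."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data=data, affine=np.asarray(img.affine, dtype=np.float64))


def write_metric(path, values: np.ndarray, names=None) -> None:
    """Write per-vertex values (one or more columns) as a GIFTI metric."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float32))
    if values.shape[0] < values.shape[1] and values.ndim == 2 and len(values) == 1:
        values = values.T if values.shape[0] == 1 else values
    darrays = []
    for i in range(values.shape[1]):
        da = gifti.GiftiDataArray(np.ascontiguousarray(values[:, i]),
                                  intent="NIFTI_INTENT_NONE")
        if names is not None:
            da.meta = gifti.GiftiMetaData(Name=str(names[i]))
        darrays.append(da)
    nib.save(gifti.GiftiImage(darrays=darrays), str(path))


def read_metric(path) -> np.ndarray:
    """Read a GIFTI metric as an (n_vertices, n_columns) array."""
    img = nib.load(str(path))
    if not isinstance(img, gifti.GiftiImage) or not img.darrays:
        raise FormatError(f"{path}: no data arrays")
    return np.column_stack([d.data.astype(np.float64) for d in img.darrays])


def write_labels(path, labels: np.ndarray) -> None:
    """Write per-vertex integer labels (GIFTI .label.gii or CSV)."""
    labels = np.asarray(labels, dtype=np.int32)
    if str(path).endswith(".csv"):
        pd.DataFrame({"label": labels}).to_csv(path, index=False)
        return
    da = gifti.GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL")
    nib.save(gifti.GiftiImage(darrays=[da]), str(path))


def read_labels(path) -> np.ndarray:
    """Read per-vertex labels from GIFTI or CSV."""
    if str(path).endswith(".csv"):
        return pd.read_csv(path)["label"].to_numpy(dtype=np.int64)
    img = nib.load(str(path))
    if not isinstance(img, gifti.GiftiImage) or not img.darrays:
        raise FormatError(f"{path}: no data arrays")
    return img.darrays[0].data.astype(np.int64)


def write_cohort(path, cohort: pd.DataFrame) -> None:
    """Write a cohort table with the canonical column order."""
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df
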