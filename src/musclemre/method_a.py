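"""Per-muscle stiffness from a precomputed (vendor) stiffness map.

The map's own validity mask removes voxels where wave propagation was not
clearly measurable; on top of that, a symmetric trim (default 5% per tail,
per muscle ROI) discards residual outliers before averaging. Label maps
drawn on another acquisition are brought into the stiffness-map grid by
nearest-neighbour resampling through the shared world frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from nibabel import Nifti1Image
from nibabel.processing import resample_from_to

from .core import PA_PER_KPA, GeometryError, LabelMap, StiffnessMap, Volume

__all__ = ["resample_labels", "trimmed_muscle_mean"]


def resample_labels(labelmap: LabelMap, target: Volume) -> LabelMap:
    """Nearest-neighbour resample of the labels onto ``target``'s grid.

    Both affines are taken to map into the same world frame (rigid
    co-registration already applied); no label values are invented.
    """
    if abs(np.linalg.det(np.asarray(target.affine)[:3, :3])) < 1e-12:
        raise GeometryError("target affine is singular")
    src = Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    out = resample_from_to(
        src, (target.values.shape, target.affine), order=0, cval=0
    )
    labels = np.asarray(out.get_fdata()).astype(np.int32)
    return LabelMap(
        labels=labels,
        affine=np.asarray(target.affine, dtype=float),
        legend=dict(labelmap.legend),
    )


def _trimmed_mean(values: np.ndarray, trim: float) -> tuple[float, int]:
    """Symmetric trimmed mean: drop floor(trim*n) voxels from each tail."""
    n = values.size
    k = int(np.floor(trim * n))
    kept = np.sort(values, kind="stable")[k: n - k]
    return float(kept.mean()), int(kept.size)


def trimmed_muscle_mean(
    smap: StiffnessMap, labels: LabelMap, trim: float = 0.05
) -> pd.DataFrame:
    """Average stiffness per muscle after masking and trimming.

    Returns one row per legend entry with ``mean_stiffness_kpa`` plus the
    voxel bookkeeping (total / valid / used). A muscle without any valid
    voxel reports a missing mean rather than raising.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    if smap.stiffness.values.shape != labels.labels.shape or not np.allclose(
        smap.stiffness.affine, labels.affine
    ):
        raise GeometryError("stiffness map and labels are not aligned")
    rows = []
    for label in sorted(labels.legend):
        mask = labels.labels == label
        n_total = int(mask.sum())
        vox = smap.stiffness.values[mask & smap.valid]
        n_valid = int(vox.size)
        if n_valid:
            mean_pa, n_used = _trimmed_mean(vox, trim)
            mean_kpa = mean_pa / PA_PER_KPA
        else:
            mean_kpa, n_used = np.nan, 0
        rows.append(
            {
                "label": label,
                "muscle": labels.legend[label],
                "mean_stiffness_kpa": mean_kpa,
                "n_voxels_total": n_total,
                "n_voxels_valid": n_valid,
                "n_voxels_used": n_used,
            }
        )
    return pd.DataFrame(rows)
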