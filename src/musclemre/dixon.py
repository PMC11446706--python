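"""Proton-density fat fraction (PDFF) and volume quantification.

PDFF is the voxelwise ratio fat/(fat + water) of the Dixon fat and water
images, held as a fraction in [0, 1] (reported as % externally). Voxels
whose summed signal falls at or below a noise floor are marked missing
(NaN) rather than producing unstable ratios. Per-muscle summaries average
over the non-missing voxels of each label.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .core import GeometryError, LabelMap, Volume

__all__ = [
    "compute_pdff",
    "muscle_pdff",
    "muscle_volume",
    "total_thigh_pdff",
    "normal_pdff_cutoff",
    "normal_pdff_cutoff_from_summary",
]

#: Default signal floor as a fraction of the nominal signal scale.
DEFAULT_FLOOR_FRACTION = 0.01


def compute_pdff(
    fat: Volume,
    water: Volume,
    signal_floor: float = 0.0,
    precorrection: Callable[[np.ndarray, np.ndarray],
                            tuple[np.ndarray, np.ndarray]] | None = None,
) -> Volume:
    """Voxelwise PDFF = fat/(fat + water), missing below the signal floor.

    ``precorrection`` is an optional hook applied to the raw (fat, water)
    arrays before the ratio, e.g. a T1-bias correction; the default is the
    identity.
    """
    if not fat.same_geometry(water):
        raise GeometryError(
            f"fat/water geometry mismatch: {fat.values.shape} vs "
            f"{water.values.shape}"
        )
    if signal_floor < 0:
        raise ValueError("signal_floor must be >= 0")
    f = np.asarray(fat.values, dtype=float)
    w = np.asarray(water.values, dtype=float)
    if precorrection is not None:
        f, w = precorrection(f, w)
    total = f + w
    pdff = np.full(total.shape, np.nan)
    defined = total > signal_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        pdff[defined] = f[defined] / total[defined]
    pdff = np.clip(pdff, 0.0, 1.0)
    return fat.like(pdff)


def _check_aligned(pdff: Volume, labelmap: LabelMap) -> None:
    if pdff.values.shape != labelmap.labels.shape or not np.allclose(
        pdff.affine, labelmap.affine
    ):
        raise GeometryError("PDFF map and label map are not aligned")


def muscle_pdff(pdff: Volume, labelmap: LabelMap) -> pd.DataFrame:
    """Mean PDFF over non-missing voxels per label.

    Returns one row per legend entry with columns ``label``, ``muscle``,
    ``mean_pdff``, ``n_voxels``, ``n_used``; labels with no usable voxel
    report NaN.
    """
    _check_aligned(pdff, labelmap)
    rows = []
    for label in sorted(labelmap.legend):
        mask = labelmap.labels == label
        vox = pdff.values[mask]
        usable = vox[np.isfinite(vox)]
        rows.append(
            {
                "label": label,
                "muscle": labelmap.legend[label],
                "mean_pdff": float(usable.mean()) if usable.size else np.nan,
                "n_voxels": int(mask.sum()),
                "n_used": int(usable.size),
            }
        )
    return pd.DataFrame(rows)


def muscle_volume(labelmap: LabelMap) -> pd.DataFrame:
    """Muscle volume in cc: voxel count times voxel volume."""
    voxel_mm3 = float(
        abs(np.linalg.det(np.asarray(labelmap.affine)[:3, :3]))
    )
    rows = []
    for label in sorted(labelmap.legend):
        n = int((labelmap.labels == label).sum())
        rows.append(
            {
                "label": label,
                "muscle": labelmap.legend[label],
                "n_voxels": n,
                "volume_cc": n * voxel_mm3 / 1000.0,
            }
        )
    return pd.DataFrame(rows)


def total_thigh_pdff(
    pdff: Volume, labelmap: LabelMap, weighted: bool = True
) -> float:
    """Total-thigh PDFF across all segmented muscles.

    ``weighted=True`` pools all in-muscle voxels (volume-weighted mean);
    ``weighted=False`` averages the per-muscle means.
    """
    _check_aligned(pdff, labelmap)
    if weighted:
        mask = labelmap.labels > 0
        vox = pdff.values[mask]
        usable = vox[np.isfinite(vox)]
        return float(usable.mean()) if usable.size else float("nan")
    means = muscle_pdff(pdff, labelmap)["mean_pdff"]
    return float(means.mean())


def normal_pdff_cutoff(control_values, n_sd: float = 2.5) -> float:
    """Normality cutoff: control mean plus ``n_sd`` sample SDs.

    Total-thigh PDFF at or below this value is considered a normal Dixon
    scan; with the conventional 2.5 SDs and the healthy-control reference
    data this lands just under a 10% fat fraction.
    """
    values = np.asarray(control_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two control values")
    return float(values.mean() + n_sd * values.std(ddof=1))


def normal_pdff_cutoff_from_summary(
    mean: float, sd: float, n_sd: float = 2.5
) -> float:
    """Same cutoff from a published mean/SD summary of the controls."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return float(mean + n_sd * sd)
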