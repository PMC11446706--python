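"""Shared data model and standard-format I/O.

Images of every kind (Dixon fat/water, wave images, stiffness maps, label
maps) live on a 3D scalar grid with a 4x4 voxel-to-world affine in mm (RAS
orientation, 0-based voxel indices). Wave data are carried as an ordered
stack of eight phase-offset volumes sampled over one vibration cycle.
Stiffness is held in Pa internally and converted to kPa at every external
surface (files, tables, CLI output).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "WaveSeries",
    "StiffnessMap",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "read_wave_series",
    "write_wave_series",
    "read_stiffness_map",
    "write_stiffness_map",
]

#: Number of phase offsets sampled over one vibration cycle.
N_PHASES = 8

PA_PER_KPA = 1000.0


class GeometryError(ValueError):
    """Raised when image grids or affines violate a geometric contract."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with world geometry.

    Parameters
    ----------
    values
        3D array of voxel values.
    affine
        4x4 matrix mapping 0-based voxel indices to world coordinates in mm.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(
                f"expected a 3D grid, got shape {self.values.shape}"
            )
        if self.values.size == 0:
            raise GeometryError("empty grid")
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm, the column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @classmethod
    def from_spacing(
        cls,
        values: np.ndarray,
        spacing,
        origin=(0.0, 0.0, 0.0),
    ) -> "Volume":
        """Build a volume on an axis-aligned grid from spacing and origin."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
        affine[:3, 3] = np.asarray(origin, dtype=float)
        return cls(values=values, affine=affine)

    def same_geometry(self, other: "Volume", rtol: float = 1e-6) -> bool:
        return self.values.shape == other.values.shape and np.allclose(
            self.affine, other.affine, rtol=rtol, atol=1e-6
        )

    def like(self, values: np.ndarray) -> "Volume":
        """New volume with these values on this grid (affine propagated)."""
        return Volume(values=values, affine=self.affine.copy())

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.indices(self.values.shape, dtype=float)
        coords = np.stack([idx[0], idx[1], idx[2], np.ones_like(idx[0])])
        world = np.einsum("ij,j...->i...", self.affine, coords)[:3]
        return np.moveaxis(world, 0, -1)


def _check_same_geometry(a: Volume, b: Volume, what: str) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"{what}: geometry mismatch, shapes {a.values.shape} vs "
            f"{b.values.shape}"
        )


@dataclasses.dataclass
class LabelMap:
    """Integer segmentation aligned to a volume geometry.

    Label 0 is background; every nonzero label present in the grid must
    appear in ``legend`` (label -> muscle name).
    """

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise GeometryError(
                f"label grid must be 3D, got shape {self.labels.shape}"
            )
        if 0 in self.legend:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels missing from legend: {sorted(missing)}")

    @property
    def volume(self) -> Volume:
        """Geometry carrier for the label grid."""
        return Volume(values=self.labels.astype(float), affine=self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask(self, label: int) -> np.ndarray:
        if label not in self.legend:
            raise KeyError(f"label {label} not in legend")
        return self.labels == label


@dataclasses.dataclass
class WaveSeries:
    """Eight phase-offset snapshots of the propagating shear-wave field.

    The phases sample one vibration cycle at 0, 45, ..., 315 degrees, in
    that fixed order.
    """

    phases: list[Volume]
    frequency_hz: float

    def __post_init__(self) -> None:
        if len(self.phases) != N_PHASES:
            raise ValueError(
                f"wave series needs exactly {N_PHASES} phase volumes, "
                f"got {len(self.phases)}"
            )
        first = self.phases[0]
        for k, vol in enumerate(self.phases[1:], start=1):
            _check_same_geometry(first, vol, f"wave phase {k}")
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be positive")

    @property
    def affine(self) -> np.ndarray:
        return self.phases[0].affine


@dataclasses.dataclass
class StiffnessMap:
    """Voxelwise stiffness image with a validity mask.

    ``stiffness`` holds Pa internally; voxels where ``valid`` is False were
    flagged by the producing inversion as unreliable (unclear wave
    propagation) and are excluded from any statistic.
    """

    stiffness: Volume
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.stiffness.values.shape:
            raise GeometryError(
                f"validity mask shape {self.valid.shape} does not match "
                f"stiffness grid {self.stiffness.values.shape}"
            )
        if not np.all(np.isfinite(self.stiffness.values[self.valid])):
            raise ValueError("stiffness must be finite wherever valid")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise OSError(f"could not read NIfTI file {path}: {exc}") from exc
    return img


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1/2 image. Spacing derives from the affine."""
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise GeometryError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    return Volume(values=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64),
                          volume.affine)
    nib.save(img, str(path))


def read_labelmap(path, legend_path) -> LabelMap:
    """Read a label image plus its two-column legend CSV (label,name)."""
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise GeometryError(
            f"{path}: expected a 3D label image, got shape {data.shape}"
        )
    labels = np.rint(data).astype(np.int32)
    legend: dict[int, str] = {}
    with open(legend_path) as fh:
        header = fh.readline()
        if header.strip().lower().replace(" ", "") != "label,name":
            raise ValueError(f"{legend_path}: expected header 'label,name'")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, name = line.split(",", 1)
            legend[int(key)] = name
    return LabelMap(labels=labels, affine=np.asarray(img.affine),
                    legend=legend)


def write_labelmap(labelmap: LabelMap, path, legend_path) -> None:
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.affine)
    nib.save(img, str(path))
    with open(legend_path, "w") as fh:
        fh.write("label,name\n")
        for label in sorted(labelmap.legend):
            fh.write(f"{label},{labelmap.legend[label]}\n")


def read_wave_series(path, frequency_hz: float) -> WaveSeries:
    """Read a 4D NIfTI with the 8 phase offsets along the 4th axis."""
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 4 or data.shape[3] != N_PHASES:
        raise GeometryError(
            f"{path}: expected 4D image with {N_PHASES} phase volumes, "
            f"got shape {data.shape}"
        )
    affine = np.asarray(img.affine)
    phases = [Volume(values=data[..., k], affine=affine)
              for k in range(N_PHASES)]
    return WaveSeries(phases=phases, frequency_hz=frequency_hz)


def write_wave_series(series: WaveSeries, path) -> None:
    data = np.stack([p.values for p in series.phases], axis=-1)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), series.affine)
    nib.save(img, str(path))


def read_stiffness_map(path, valid_path=None) -> StiffnessMap:
    """Read a stiffness map stored in kPa, with an optional validity image.

    Without a validity image every finite voxel is treated as valid.
    """
    vol = read_volume(path)
    values_pa = vol.values * PA_PER_KPA
    if valid_path is not None:
        valid_vol = read_volume(valid_path)
        valid = valid_vol.values > 0.5
    else:
        valid = np.isfinite(values_pa)
    return StiffnessMap(stiffness=vol.like(values_pa), valid=valid)


def write_stiffness_map(smap: StiffnessMap, path, valid_path) -> None:
    """Write the stiffness image in kPa plus a 0/1 validity image."""
    write_volume(smap.stiffness.like(smap.stiffness.values / PA_PER_KPA),
                 path)
    img = nib.Nifti1Image(smap.valid.astype(np.uint8),
                          smap.stiffness.affine)
    nib.save(img, str(valid_path))
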