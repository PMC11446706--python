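"""Shear stiffness from wavelength measurements on the wave images.

For each muscle the pipeline (i) finds the main proximo-distal axis as the
first principal component of the segmentation's world coordinates, (ii)
picks the sagittal slice with maximum overlap between segmentation and
measurable wave data, (iii) samples a 1D displacement profile along the
in-plane projection of that axis, (iv) takes the dominant wavelength of
the profile from a zero-padded Fourier power spectrum, discarding
measurements whose prevalent wavelength exceeds 50 mm as artefacts, and
(v) averages the wavelength over the eight phase offsets before applying

    mu = rho * (f * lambda)^2

with rho the tissue density (1000 kg/m^3 by convention) and f the driver
frequency. Waves propagate along the muscle fibres, so measuring along the
muscle's own long axis avoids the stiffness overestimation that oblique
wave fronts would otherwise cause.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import N_PHASES, PA_PER_KPA, LabelMap, Volume, WaveSeries

__all__ = [
    "MuscleAxis",
    "Profile",
    "WavelengthEstimate",
    "principal_axis",
    "select_slice",
    "extract_profile",
    "dominant_wavelength",
    "wavelength_over_phases",
    "shear_stiffness",
    "estimate_muscle_stiffness",
]

#: Axis 0 is the slice-select (sagittal stack) axis by convention.
SLICE_AXIS = 0

#: Principal/secondary extent ratio below which a shape has no clear
#: proximo-distal axis.
MIN_ELONGATION = 1.5

MIN_PROFILE_SAMPLES = 4
MIN_VALID_PHASES = 4
PAD_FACTOR = 8


@dataclasses.dataclass
class MuscleAxis:
    """Main proximo-distal direction of one muscle, in world mm."""

    label: int
    muscle: str
    direction: np.ndarray
    centroid: np.ndarray
    elongation: float
    qc: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class Profile:
    """1D displacement samples along a line, uniformly spaced in mm."""

    positions_mm: np.ndarray
    values: np.ndarray

    @property
    def spacing(self) -> float:
        return float(self.positions_mm[1] - self.positions_mm[0])


@dataclasses.dataclass
class WavelengthEstimate:
    """Per-muscle wavelength and stiffness with QC bookkeeping."""

    label: int
    muscle: str
    slice_index: int | None
    per_phase_mm: list[float | None]
    mean_wavelength_mm: float | None
    stiffness_kpa: float | None
    qc: list[str] = dataclasses.field(default_factory=list)


def principal_axis(
    labels: LabelMap, label: int, min_voxels: int = 10
) -> MuscleAxis:
    """First principal component of the muscle's voxel world coordinates.

    The sign is fixed to a positive superior (world z) component; an
    elongation ratio below 1.5 flags a near-isotropic shape whose axis is
    poorly determined.
    """
    mask = labels.mask(label)
    idx = np.argwhere(mask)
    if idx.shape[0] < min_voxels:
        raise ValueError(
            f"label {label} has {idx.shape[0]} voxels, "
            f"need at least {min_voxels} for an axis"
        )
    hom = np.column_stack([idx.astype(float), np.ones(idx.shape[0])])
    world = hom @ np.asarray(labels.affine).T
    coords = world[:, :3]
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1]
    second = max(evals[-2], 0.0)
    elongation = float(np.sqrt(evals[-1] / second)) if second > 0 else np.inf
    # orient towards superior; fall back to first nonzero component
    if abs(direction[2]) > 1e-9:
        if direction[2] < 0:
            direction = -direction
    else:
        nz = np.flatnonzero(np.abs(direction) > 1e-9)
        if nz.size and direction[nz[0]] < 0:
            direction = -direction
    qc = [] if elongation >= MIN_ELONGATION else ["near_isotropic"]
    return MuscleAxis(
        label=label,
        muscle=labels.legend[label],
        direction=direction,
        centroid=centroid,
        elongation=elongation,
        qc=qc,
    )


def select_slice(
    labels: LabelMap,
    label: int,
    measurable: np.ndarray | None = None,
    slice_axis: int = SLICE_AXIS,
) -> int | None:
    """Slice with maximum overlap between muscle and measurable region.

    Ties break to the lowest index; returns None when no slice overlaps.
    """
    mask = labels.mask(label)
    if measurable is not None:
        if measurable.shape != mask.shape:
            raise ValueError("measurable mask shape mismatch")
        mask = mask & measurable.astype(bool)
    axes = tuple(a for a in range(3) if a != slice_axis)
    counts = mask.sum(axis=axes)
    if counts.max() == 0:
        return None
    return int(np.argmax(counts))


def extract_profile(
    wave: Volume,
    slice_index: int,
    axis: MuscleAxis,
    labels: LabelMap,
    label: int,
    slice_axis: int = SLICE_AXIS,
    step_mm: float | None = None,
) -> Profile | None:
    """Sample the wave along the in-plane projected muscle axis.

    The line passes through the in-slice centroid of the muscle, sampled
    by linear interpolation at the finest in-plane spacing, restricted to
    the longest contiguous in-muscle run, and mean-centred. Returns None
    (caller records a QC flag) when the axis has no in-plane component or
    the run is shorter than four samples.
    """
    affine = np.asarray(wave.affine)
    normal = affine[:3, slice_axis]
    normal = normal / np.linalg.norm(normal)
    d = np.asarray(axis.direction, dtype=float)
    d_in = d - (d @ normal) * normal
    norm = np.linalg.norm(d_in)
    if norm < 1e-6:
        return None
    d_in /= norm

    mask = labels.mask(label)
    sl = [slice(None)] * 3
    sl[slice_axis] = slice_index
    slice_mask = mask[tuple(sl)]
    vox = np.argwhere(slice_mask)
    if vox.shape[0] == 0:
        return None
    idx3 = np.insert(vox.astype(float), slice_axis, float(slice_index),
                     axis=1)
    hom = np.column_stack([idx3, np.ones(idx3.shape[0])])
    coords = (hom @ affine.T)[:, :3]
    centroid = coords.mean(axis=0)

    in_plane_axes = [a for a in range(3) if a != slice_axis]
    spacing = wave.spacing
    if step_mm is None:
        step_mm = float(min(spacing[a] for a in in_plane_axes))
    t = (coords - centroid) @ d_in
    ts = np.arange(t.min(), t.max() + step_mm / 2, step_mm)
    points = centroid + ts[:, None] * d_in

    inv = np.linalg.inv(affine)
    hom_pts = np.column_stack([points, np.ones(points.shape[0])])
    vox_pts = (hom_pts @ inv.T)[:, :3]
    vox_pts[:, slice_axis] = float(slice_index)  # keep exactly in-plane

    values = ndimage.map_coordinates(
        np.asarray(wave.values, dtype=float), vox_pts.T, order=1,
        mode="constant", cval=0.0,
    )
    membership = ndimage.map_coordinates(
        mask.astype(np.uint8), vox_pts.T, order=0, mode="constant", cval=0
    ).astype(bool)

    start, length = _longest_run(membership)
    if length < MIN_PROFILE_SAMPLES:
        return None
    run = slice(start, start + length)
    vals = values[run] - values[run].mean()
    return Profile(positions_mm=ts[run], values=vals)


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    best_start, best_len, start = 0, 0, None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def dominant_wavelength(
    profile: Profile,
    max_wavelength_mm: float = 50.0,
    pad_factor: int = PAD_FACTOR,
) -> float | None:
    """Most prevalent wavelength of the profile by Fourier power analysis.

    The profile is zero-padded to at least ``pad_factor`` times its length
    (next power of two) to reduce wavelength quantisation. The peak of the
    power spectrum over nonzero frequencies gives the prevalent
    wavelength; a tie prefers the longer wavelength. When that prevalent
    wavelength exceeds ``max_wavelength_mm`` the measurement is deemed an
    artefact and reported missing.
    """
    values = np.asarray(profile.values, dtype=float)
    if values.size < MIN_PROFILE_SAMPLES:
        raise ValueError("profile needs at least 4 samples")
    steps = np.diff(np.asarray(profile.positions_mm, dtype=float))
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("profile positions must be uniformly spaced")
    spacing = float(steps[0])
    power, freqs = _power_spectrum(values, spacing, pad_factor)
    # argmax returns the first (lowest-frequency) index on exact ties,
    # which is the longer wavelength
    peak = int(np.argmax(power))
    wavelength = 1.0 / freqs[peak]
    if wavelength > max_wavelength_mm:
        return None
    return float(wavelength)


def _power_spectrum(
    values: np.ndarray, spacing: float, pad_factor: int
) -> tuple[np.ndarray, np.ndarray]:
    centred = values - values.mean()
    n_fft = 1 << int(np.ceil(np.log2(pad_factor * centred.size)))
    spectrum = np.fft.rfft(centred, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=spacing)
    return np.abs(spectrum[1:]) ** 2, freqs[1:]


def wavelength_over_phases(
    series: WaveSeries,
    slice_index: int,
    axis: MuscleAxis,
    labels: LabelMap,
    label: int,
    max_wavelength_mm: float = 50.0,
    density_kg_m3: float = 1000.0,
    min_valid_phases: int = MIN_VALID_PHASES,
    mode: str = "per_phase",
) -> WavelengthEstimate:
    """Average the dominant wavelength over the eight phase offsets.

    ``mode='per_phase'`` (default) takes one dominant wavelength per phase
    and averages the non-missing ones, requiring at least
    ``min_valid_phases``; ``mode='pooled'`` averages the power spectra of
    all phases and takes a single peak.
    """
    if mode not in ("per_phase", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    qc: list[str] = list(axis.qc)
    profiles = [
        extract_profile(phase, slice_index, axis, labels, label)
        for phase in series.phases
    ]
    per_phase: list[float | None] = []
    if mode == "pooled":
        usable = [p for p in profiles if p is not None]
        if len(usable) < min_valid_phases:
            qc.append("too_few_profiles")
            return _missing_estimate(axis, slice_index, qc)
        pooled = None
        for p in usable:
            power, freqs = _power_spectrum(p.values, p.spacing, PAD_FACTOR)
            pooled = power if pooled is None else pooled + power
        peak = int(np.argmax(pooled))
        lam = 1.0 / freqs[peak]
        mean_lam = float(lam) if lam <= max_wavelength_mm else None
        per_phase = [mean_lam] * len(usable)
    else:
        for p in profiles:
            if p is None:
                per_phase.append(None)
                continue
            per_phase.append(
                dominant_wavelength(p, max_wavelength_mm=max_wavelength_mm)
            )
        valid = [lam for lam in per_phase if lam is not None]
        n_dropped = N_PHASES - len(valid)
        if n_dropped:
            qc.append(f"dropped_phases:{n_dropped}")
        if len(valid) < min_valid_phases:
            qc.append("too_few_valid_phases")
            return _missing_estimate(axis, slice_index, qc, per_phase)
        mean_lam = float(np.mean(valid))
    if mean_lam is None:
        qc.append("wavelength_artefact")
        return _missing_estimate(axis, slice_index, qc, per_phase)
    stiffness = shear_stiffness(
        mean_lam, frequency_hz=series.frequency_hz, density=density_kg_m3
    )
    return WavelengthEstimate(
        label=axis.label,
        muscle=axis.muscle,
        slice_index=slice_index,
        per_phase_mm=per_phase,
        mean_wavelength_mm=mean_lam,
        stiffness_kpa=stiffness,
        qc=qc,
    )


def _missing_estimate(
    axis: MuscleAxis,
    slice_index: int | None,
    qc: list[str],
    per_phase: list[float | None] | None = None,
) -> WavelengthEstimate:
    return WavelengthEstimate(
        label=axis.label,
        muscle=axis.muscle,
        slice_index=slice_index,
        per_phase_mm=per_phase if per_phase is not None else [None] * N_PHASES,
        mean_wavelength_mm=None,
        stiffness_kpa=None,
        qc=qc,
    )


def shear_stiffness(
    wavelength_mm: float | None,
    frequency_hz: float = 60.0,
    density: float = 1000.0,
) -> float | None:
    """Shear stiffness mu = rho (f lambda)^2 in kPa; missing in, missing out."""
    if wavelength_mm is None:
        return None
    if wavelength_mm <= 0:
        raise ValueError("wavelength must be positive")
    lam_m = wavelength_mm / 1000.0
    mu_pa = density * (frequency_hz * lam_m) ** 2
    return mu_pa / PA_PER_KPA


def estimate_muscle_stiffness(
    series: WaveSeries,
    labels: LabelMap,
    label: int,
    measurable: np.ndarray | None = None,
    max_wavelength_mm: float = 50.0,
    density_kg_m3: float = 1000.0,
    mode: str = "per_phase",
) -> WavelengthEstimate:
    """Full per-muscle pipeline: axis, slice, profiles, wavelength, mu.

    ``measurable`` restricts slice selection to the region with usable
    wave data; by default the whole wave-image footprint is eligible.
    """
    axis = principal_axis(labels, label)
    slice_index = select_slice(labels, label, measurable=measurable)
    if slice_index is None:
        return _missing_estimate(axis, None, axis.qc + ["no_overlap"])
    return wavelength_over_phases(
        series,
        slice_index,
        axis,
        labels,
        label,
        max_wavelength_mm=max_wavelength_mm,
        density_kg_m3=density_kg_m3,
        mode=mode,
    )
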