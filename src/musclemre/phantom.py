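"""Seeded synthetic thigh phantom with known ground truth.

The phantom stands in for patient MRI data: a sagittal multi-slice grid
(slice-select along axis 0, thick slices; fine in-plane sampling on axes
1-2) holding a handful of cylindrical/ellipsoidal muscle compartments whose
long axes run superior-inferior. Each compartment carries a true fat
fraction and a true shear stiffness, from which every simulated modality is
derived:

* Dixon fat/water pairs with ``fat = S*pdff``, ``water = S*(1 - pdff)`` and
  additive Gaussian noise,
* eight phase-offset shear-wave snapshots whose in-muscle wavelength is the
  plane-wave value ``lambda = sqrt(mu/rho)/f``, optionally contaminated by a
  45-degree oblique wave of shorter wavelength,
* a vendor-style stiffness map with Gaussian scatter, heavy-tailed outliers
  (x10 / x0.1) and randomly invalidated voxels.

All generation is deterministic in (spec, seed); each modality draws from
its own child stream so that the products can be generated independently.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .core import N_PHASES, PA_PER_KPA, LabelMap, StiffnessMap, Volume, WaveSeries

__all__ = [
    "Compartment",
    "PhantomSpec",
    "SessionPair",
    "default_phantom_spec",
    "wavelength_mm_from_stiffness",
    "make_labelmap",
    "simulate_dixon",
    "simulate_waves",
    "simulate_vendor_map",
    "truth_table",
    "make_session_pair",
]

# Independent RNG streams per simulated product.
_STREAM_DIXON = 1
_STREAM_WAVES = 2
_STREAM_VENDOR = 3
_STREAM_SESSION = 4


def wavelength_mm_from_stiffness(
    stiffness_kpa: float, frequency_hz: float, density_kg_m3: float = 1000.0
) -> float:
    """Plane shear-wave wavelength lambda = sqrt(mu/rho)/f, in mm."""
    mu_pa = stiffness_kpa * PA_PER_KPA
    return float(np.sqrt(mu_pa / density_kg_m3) / frequency_hz * 1000.0)


@dataclasses.dataclass
class Compartment:
    """One muscle belly as a geometric primitive.

    ``extents_mm`` is (radius, half_length) for a cylinder and the three
    semi-axes (a, b, c) for an ellipsoid, with the last extent measured
    along ``axis``.
    """

    name: str
    shape: Literal["cylinder", "ellipsoid"]
    center_mm: tuple[float, float, float]
    axis: tuple[float, float, float]
    extents_mm: tuple[float, ...]
    true_pdff: float
    true_stiffness_kpa: float
    side: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_pdff <= 1.0:
            raise ValueError(
                f"{self.name}: true_pdff must be in [0, 1], "
                f"got {self.true_pdff}"
            )
        if not self.true_stiffness_kpa > 0:
            raise ValueError(f"{self.name}: true_stiffness_kpa must be > 0")
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError(f"{self.name}: zero-length axis")
        self.axis = tuple(axis / norm)
        if self.shape == "cylinder" and len(self.extents_mm) != 2:
            raise ValueError("cylinder needs (radius, half_length) extents")
        if self.shape == "ellipsoid" and len(self.extents_mm) != 3:
            raise ValueError("ellipsoid needs three semi-axis extents")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for points of shape (..., 3) in world mm."""
        rel = points - np.asarray(self.center_mm)
        d = np.asarray(self.axis)
        along = rel @ d
        if self.shape == "cylinder":
            radius, half_length = self.extents_mm
            radial = rel - along[..., None] * d
            return (np.abs(along) <= half_length) & (
                np.linalg.norm(radial, axis=-1) <= radius
            )
        a, b, c = self.extents_mm
        u, v = _orthonormal_complement(d)
        return (
            (rel @ u / a) ** 2 + (rel @ v / b) ** 2 + (along / c) ** 2
        ) <= 1.0


def _orthonormal_complement(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


@dataclasses.dataclass
class PhantomSpec:
    """Complete description of one synthetic dataset.

    Noise levels are per modality because the image units differ: Dixon
    noise in signal units (signal scale ``signal_scale``), wave noise in
    units of the wave amplitude, stiffness-map scatter in kPa.
    """

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    compartments: list[Compartment]
    signal_scale: float = 100.0
    noise_sd: float = 5.0
    wave_amplitude: float = 1.0
    wave_noise_sd: float = 0.1
    oblique_fraction: float = 0.1
    stiffness_noise_kpa: float = 0.3
    outlier_fraction: float = 0.02
    invalid_fraction: float = 0.1
    frequency_hz: float = 60.0
    density_kg_m3: float = 1000.0
    max_wavelength_mm: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValueError("phantom needs at least one compartment")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if not 0.0 <= self.oblique_fraction < 1.0:
            raise ValueError("oblique_fraction must be in [0, 1)")
        if not 0.0 <= self.outlier_fraction <= 0.05:
            raise ValueError("outlier_fraction must be in [0, 0.05]")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.wave_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        wavelengths = [
            wavelength_mm_from_stiffness(
                c.true_stiffness_kpa, self.frequency_hz, self.density_kg_m3
            )
            for c in self.compartments
        ]
        if min(wavelengths) > self.max_wavelength_mm:
            raise ValueError(
                "no compartment has a wavelength within the "
                f"{self.max_wavelength_mm} mm measurable range"
            )

    @property
    def affine(self) -> np.ndarray:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing_mm)
        return affine

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def wavelength_mm(self, compartment: Compartment) -> float:
        return wavelength_mm_from_stiffness(
            compartment.true_stiffness_kpa,
            self.frequency_hz,
            self.density_kg_m3,
        )


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Four-muscle sagittal thigh phantom mirroring the acquisition grid.

    Slice-select axis 0 with 11.6 mm centre-to-centre spacing (10 mm
    slices plus gap), 1.5 mm in-plane sampling; muscle long axes run
    superior-inferior (axis 2). Fat fractions span healthy muscle to
    marked fatty replacement; stiffness values sit in the 1.8-4 kPa range
    reported for relaxed thigh muscle at 60 Hz.
    """
    compartments = [
        Compartment(
            name="rectus_femoris", shape="cylinder",
            center_mm=(46.0, 30.0, 82.0), axis=(0.0, 0.0, 1.0),
            extents_mm=(14.0, 65.0), true_pdff=0.05,
            true_stiffness_kpa=3.24,
        ),
        Compartment(
            name="vastus_lateralis", shape="cylinder",
            center_mm=(23.0, 60.0, 82.0), axis=(0.0, 0.0, 1.0),
            extents_mm=(16.0, 70.0), true_pdff=0.08,
            true_stiffness_kpa=2.3,
        ),
        Compartment(
            name="biceps_femoris", shape="cylinder",
            center_mm=(70.0, 60.0, 82.0), axis=(0.0, 0.0, 1.0),
            extents_mm=(15.0, 60.0), true_pdff=0.20,
            true_stiffness_kpa=4.0,
        ),
        Compartment(
            name="semimembranosus", shape="cylinder",
            center_mm=(46.0, 90.0, 82.0), axis=(0.0, 0.0, 1.0),
            extents_mm=(13.0, 55.0), true_pdff=0.35,
            true_stiffness_kpa=1.8,
        ),
    ]
    params = dict(
        grid_shape=(8, 80, 110),
        spacing_mm=(11.6, 1.5, 1.5),
        compartments=compartments,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    vol = Volume(values=np.zeros(spec.grid_shape), affine=spec.affine)
    return vol.world_coordinates()


def make_labelmap(spec: PhantomSpec) -> LabelMap:
    """Rasterize the compartments; later compartments overwrite earlier."""
    points = _grid_points(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    legend: dict[int, str] = {}
    for i, comp in enumerate(spec.compartments, start=1):
        inside = comp.contains(points)
        if not inside.any():
            raise ValueError(
                f"compartment {comp.name!r} lies entirely outside the grid"
            )
        labels[inside] = i
        legend[i] = comp.name
    return LabelMap(labels=labels, affine=spec.affine, legend=legend)


def simulate_dixon(
    labelmap: LabelMap, spec: PhantomSpec
) -> tuple[Volume, Volume]:
    """Noisy Dixon fat/water pair: fat = S*pdff, water = S*(1-pdff)."""
    if labelmap.labels.shape != spec.grid_shape:
        raise ValueError("label map geometry does not match spec")
    fat = np.zeros(spec.grid_shape, dtype=float)
    water = np.zeros(spec.grid_shape, dtype=float)
    for i, comp in enumerate(spec.compartments, start=1):
        inside = labelmap.labels == i
        fat[inside] = spec.signal_scale * comp.true_pdff
        water[inside] = spec.signal_scale * (1.0 - comp.true_pdff)
    rng = spec.rng(_STREAM_DIXON)
    if spec.noise_sd > 0:
        fat = fat + rng.normal(0.0, spec.noise_sd, size=fat.shape)
        water = water + rng.normal(0.0, spec.noise_sd, size=water.shape)
    fat = np.clip(fat, 0.0, None)
    water = np.clip(water, 0.0, None)
    affine = spec.affine
    return Volume(fat, affine), Volume(water, affine)


def _oblique_direction(d: np.ndarray) -> np.ndarray:
    """Rotate the propagation direction by 45 degrees within the slice
    plane (axes 1-2), the plane the 2D acquisition samples."""
    in_plane = np.array([0.0, d[1], d[2]])
    norm = np.linalg.norm(in_plane)
    if norm < 1e-9:
        in_plane = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    in_plane /= norm
    perp = np.array([0.0, -in_plane[2], in_plane[1]])
    c = np.cos(np.pi / 4)
    return c * in_plane + c * perp


def simulate_waves(labelmap: LabelMap, spec: PhantomSpec) -> WaveSeries:
    """Eight phase snapshots of per-muscle plane waves.

    Inside muscle m the displacement at phase k is
    ``A sin(2 pi t/lambda_m + 2 pi k/8)`` with t the coordinate along the
    muscle axis, plus an oblique contaminant at 45 degrees with
    ``lambda' = 0.7 lambda`` scaled by ``oblique_fraction``.
    """
    points = _grid_points(spec)
    rng = spec.rng(_STREAM_WAVES)
    base = []
    for i, comp in enumerate(spec.compartments, start=1):
        inside = labelmap.labels == i
        lam = spec.wavelength_mm(comp)
        d = np.asarray(comp.axis)
        rel = points - np.asarray(comp.center_mm)
        t_main = rel @ d
        arg_main = 2.0 * np.pi * t_main / lam
        d_obl = _oblique_direction(d)
        t_obl = rel @ d_obl
        arg_obl = 2.0 * np.pi * t_obl / (0.7 * lam)
        base.append((inside, arg_main, arg_obl))
    affine = spec.affine
    phases = []
    for k in range(N_PHASES):
        offset = 2.0 * np.pi * k / N_PHASES
        field = np.zeros(spec.grid_shape, dtype=float)
        for inside, arg_main, arg_obl in base:
            wave = spec.wave_amplitude * (
                np.sin(arg_main + offset)
                + spec.oblique_fraction * np.sin(arg_obl + offset)
            )
            field[inside] = wave[inside]
        if spec.wave_noise_sd > 0:
            field = field + rng.normal(
                0.0, spec.wave_noise_sd, size=field.shape
            )
        phases.append(Volume(field, affine))
    return WaveSeries(phases=phases, frequency_hz=spec.frequency_hz)


def simulate_vendor_map(labelmap: LabelMap, spec: PhantomSpec) -> StiffnessMap:
    """Vendor-style stiffness map: truth + scatter, outliers, invalid voxels.

    A fraction ``outlier_fraction`` of each muscle's voxels is replaced by
    extreme values (x10 or x0.1 the truth); a fraction ``invalid_fraction``
    is flagged not-measurable. Background voxels are never valid.
    """
    rng = spec.rng(_STREAM_VENDOR)
    values = np.zeros(spec.grid_shape, dtype=float)
    valid = np.zeros(spec.grid_shape, dtype=bool)
    for i, comp in enumerate(spec.compartments, start=1):
        inside_idx = np.flatnonzero(labelmap.labels == i)
        n = inside_idx.size
        truth_pa = comp.true_stiffness_kpa * PA_PER_KPA
        vox = truth_pa + rng.normal(
            0.0, spec.stiffness_noise_kpa * PA_PER_KPA, size=n
        )
        n_out = int(round(spec.outlier_fraction * n))
        if n_out:
            which = rng.choice(n, size=n_out, replace=False)
            factors = rng.choice([10.0, 0.1], size=n_out)
            vox[which] = truth_pa * factors
        flat = values.reshape(-1)
        flat[inside_idx] = vox
        ok = np.ones(n, dtype=bool)
        n_invalid = int(round(spec.invalid_fraction * n))
        if n_invalid:
            bad = rng.choice(n, size=n_invalid, replace=False)
            ok[bad] = False
        valid.reshape(-1)[inside_idx] = ok
    stiff = Volume(values, spec.affine)
    return StiffnessMap(stiffness=stiff, valid=valid)


def truth_table(spec: PhantomSpec) -> pd.DataFrame:
    """Ground-truth values per compartment, for recovery tests."""
    rows = []
    for i, comp in enumerate(spec.compartments, start=1):
        rows.append(
            {
                "label": i,
                "muscle": comp.name,
                "side": comp.side,
                "true_pdff": comp.true_pdff,
                "true_stiffness_kpa": comp.true_stiffness_kpa,
                "true_wavelength_mm": spec.wavelength_mm(comp),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SessionPair:
    """Two phantom datasets emulating scans one week apart.

    The second session keeps the geometry but perturbs every per-muscle
    truth multiplicatively by ``1 + N(0, between_session_sd)`` and draws
    fresh noise. Both truths are retained for recovery tests.
    """

    session1: PhantomSpec
    session2: PhantomSpec
    between_session_sd: float


def make_session_pair(
    spec: PhantomSpec, between_session_sd: float, seed: int
) -> SessionPair:
    if between_session_sd < 0:
        raise ValueError("between_session_sd must be >= 0")
    rng = np.random.default_rng([int(seed), _STREAM_SESSION])
    session1 = dataclasses.replace(spec, seed=int(seed) * 2 + 1)
    perturbed = []
    for comp in spec.compartments:
        f_pdff = 1.0 + rng.normal(0.0, between_session_sd)
        f_mu = 1.0 + rng.normal(0.0, between_session_sd)
        perturbed.append(
            dataclasses.replace(
                comp,
                true_pdff=float(np.clip(comp.true_pdff * f_pdff, 0.0, 1.0)),
                true_stiffness_kpa=float(
                    max(comp.true_stiffness_kpa * f_mu, 1e-3)
                ),
            )
        )
    session2 = dataclasses.replace(
        spec, compartments=perturbed, seed=int(seed) * 2 + 2
    )
    return SessionPair(
        session1=session1,
        session2=session2,
        between_session_sd=between_session_sd,
    )
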