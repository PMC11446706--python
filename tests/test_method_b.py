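"""Wavelength-based stiffness: axis, slice choice, profiles, spectra."""

import dataclasses

import numpy as np
import pytest

from musclemre.core import LabelMap, Volume, WaveSeries
from musclemre.method_b import (
    MuscleAxis,
    Profile,
    dominant_wavelength,
    estimate_muscle_stiffness,
    extract_profile,
    principal_axis,
    select_slice,
    shear_stiffness,
    wavelength_over_phases,
)
from musclemre.phantom import (
    Compartment,
    PhantomSpec,
    make_labelmap,
    simulate_waves,
)

from test_phantom import single_cylinder_spec


def _axis_labelmap(mask, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(
        labels=mask.astype(np.int32),
        affine=np.diag(list(spacing) + [1.0]),
        legend={1: "m"},
    )


class TestPrincipalAxis:
    def test_z_cylinder(self, clean_labels):
        axis = principal_axis(clean_labels, 1)
        np.testing.assert_allclose(
            np.abs(axis.direction), [0.0, 0.0, 1.0], atol=1e-6
        )
        assert axis.direction[2] > 0
        assert axis.elongation > 1.5 and not axis.qc

    def test_rotated_ellipsoid_direction(self):
        theta = np.deg2rad(30)
        direction = (np.sin(theta), 0.0, np.cos(theta))
        spec = single_cylinder_spec(
            grid_shape=(80, 40, 80),
            compartments=[
                Compartment(
                    name="m", shape="ellipsoid",
                    center_mm=(40.0, 20.0, 40.0), axis=direction,
                    extents_mm=(8.0, 8.0, 30.0), true_pdff=0.1,
                    true_stiffness_kpa=3.24,
                )
            ],
        )
        labels = make_labelmap(spec)
        axis = principal_axis(labels, 1)
        angle = np.degrees(
            np.arccos(np.clip(abs(axis.direction @ direction), 0, 1))
        )
        assert angle < 1.0

    def test_sphere_flags_degenerate_axis(self):
        spec = single_cylinder_spec(
            grid_shape=(40, 40, 40),
            compartments=[
                Compartment(
                    name="ball", shape="ellipsoid",
                    center_mm=(20.0, 20.0, 20.0), axis=(0, 0, 1),
                    extents_mm=(12.0, 12.0, 12.0), true_pdff=0.1,
                    true_stiffness_kpa=3.24,
                )
            ],
        )
        labels = make_labelmap(spec)
        axis = principal_axis(labels, 1)
        assert "near_isotropic" in axis.qc

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, :3] = True
        with pytest.raises(ValueError, match="voxels"):
            principal_axis(_axis_labelmap(mask), 1)


class TestSelectSlice:
    @staticmethod
    def _varying_mask():
        # muscle on slices 3-10, widest cross-section on slice 6
        mask = np.zeros((12, 20, 20), dtype=bool)
        for s, half in zip(range(3, 11), [2, 3, 4, 8, 5, 4, 3, 2]):
            mask[s, 10 - half:10 + half, 10 - half:10 + half] = True
        return mask

    def test_max_overlap_slice(self):
        labels = _axis_labelmap(self._varying_mask())
        assert select_slice(labels, 1) == 6

    def test_unmeasurable_best_slice_falls_back(self):
        mask = self._varying_mask()
        labels = _axis_labelmap(mask)
        measurable = np.ones_like(mask)
        measurable[6] = False
        assert select_slice(labels, 1, measurable=measurable) == 7

    def test_single_slice_muscle(self):
        mask = np.zeros((12, 8, 8), dtype=bool)
        mask[5, 2:6, 2:6] = True
        assert select_slice(_axis_labelmap(mask), 1) == 5

    def test_zero_overlap_returns_missing(self):
        labels = _axis_labelmap(self._varying_mask())
        measurable = np.zeros(labels.labels.shape, dtype=bool)
        assert select_slice(labels, 1, measurable=measurable) is None


class TestExtractProfile:
    @staticmethod
    def _sinus_setup(lam=30.0, nz=101):
        # symmetric in-slice mask so the centroid sits on a voxel centre
        mask = np.zeros((3, 9, nz), dtype=bool)
        mask[1, 2:7, :] = True
        labels = _axis_labelmap(mask, spacing=(1.0, 1.5, 1.5))
        z = np.arange(nz) * 1.5
        values = np.zeros((3, 9, nz))
        values[:, :, :] = np.sin(2 * np.pi * z / lam)[None, None, :]
        wave = Volume(values, labels.affine)
        axis = MuscleAxis(
            label=1, muscle="m", direction=np.array([0.0, 0.0, 1.0]),
            centroid=np.zeros(3), elongation=10.0,
        )
        return wave, labels, axis

    def test_sinusoid_profile_recovered(self):
        wave, labels, axis = self._sinus_setup()
        profile = extract_profile(wave, 1, axis, labels, 1)
        z = profile.positions_mm - profile.positions_mm[0]
        expected = np.sin(2 * np.pi * z / 30.0)
        expected -= expected.mean()
        np.testing.assert_allclose(profile.values, expected, atol=1e-6)

    def test_constant_image_detrends_to_zero(self):
        wave, labels, axis = self._sinus_setup()
        flat = Volume(np.full(wave.values.shape, 5.0), wave.affine)
        profile = extract_profile(flat, 1, axis, labels, 1)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_split_mask_uses_longer_run(self):
        wave, labels, axis = self._sinus_setup()
        arr = labels.labels.copy()
        arr[:, :, 60:70] = 0  # split: run of 60 vs run of 31
        labels2 = LabelMap(labels=arr, affine=labels.affine,
                           legend=labels.legend)
        profile = extract_profile(wave, 1, axis, labels2, 1)
        assert profile.values.size == pytest.approx(60, abs=1)
        assert profile.positions_mm[-1] < 60 * 1.5

    def test_out_of_plane_axis_is_missing(self):
        wave, labels, _ = self._sinus_setup()
        axis = MuscleAxis(
            label=1, muscle="m", direction=np.array([1.0, 0.0, 0.0]),
            centroid=np.zeros(3), elongation=10.0,
        )
        assert extract_profile(wave, 1, axis, labels, 1) is None


class TestDominantWavelength:
    @staticmethod
    def _profile(values, spacing=1.5):
        positions = np.arange(len(values)) * spacing
        return Profile(positions_mm=positions, values=np.asarray(values))

    def test_pure_sinusoid_within_one_bin(self):
        x = np.arange(128) * 1.5
        lam = dominant_wavelength(self._profile(np.sin(2 * np.pi * x / 30)))
        # one spectral bin at the padded resolution
        bin_mm = 30.0**2 / (1024 * 1.5)
        assert abs(lam - 30.0) <= bin_mm + 1e-9

    def test_larger_amplitude_component_wins(self):
        x = np.arange(128) * 1.5
        values = 2 * np.sin(2 * np.pi * x / 24) + np.sin(2 * np.pi * x / 40)
        lam = dominant_wavelength(self._profile(values))
        assert lam == pytest.approx(24.0, rel=0.03)

    def test_wavelength_above_cutoff_is_artefact(self):
        x = np.arange(128) * 1.5
        lam = dominant_wavelength(self._profile(np.sin(2 * np.pi * x / 60)))
        assert lam is None

    def test_nonuniform_spacing_rejected(self):
        profile = Profile(
            positions_mm=np.array([0.0, 1.0, 2.5, 3.0, 4.0]),
            values=np.zeros(5),
        )
        with pytest.raises(ValueError, match="uniform"):
            dominant_wavelength(profile)

    def test_sign_and_offset_invariance(self):
        x = np.arange(100) * 1.5
        base = np.sin(2 * np.pi * x / 28)
        lam0 = dominant_wavelength(self._profile(base))
        assert dominant_wavelength(self._profile(-base)) == lam0
        assert dominant_wavelength(self._profile(base + 3.7)) == (
            pytest.approx(lam0, rel=1e-9)
        )


class TestWavelengthOverPhases:
    def test_noiseless_phantom_all_phases_agree(self):
        spec = single_cylinder_spec()
        labels = make_labelmap(spec)
        series = simulate_waves(labels, spec)
        axis = principal_axis(labels, 1)
        est = wavelength_over_phases(series, 25, axis, labels, 1)
        lams = [lam for lam in est.per_phase_mm if lam is not None]
        assert len(lams) == 8
        np.testing.assert_allclose(lams, 30.0, rtol=0.03)
        assert est.mean_wavelength_mm == pytest.approx(30.0, rel=0.03)

    def test_opposite_phase_pairs_match(self):
        spec = single_cylinder_spec()
        labels = make_labelmap(spec)
        series = simulate_waves(labels, spec)
        axis = principal_axis(labels, 1)
        est = wavelength_over_phases(series, 25, axis, labels, 1)
        assert est.per_phase_mm[0] == pytest.approx(est.per_phase_mm[4])

    def test_artefact_phases_dropped_with_flag(self):
        spec = single_cylinder_spec()
        labels = make_labelmap(spec)
        series = simulate_waves(labels, spec)
        flat = Volume(np.zeros(spec.grid_shape), series.affine)
        phases = series.phases[:5] + [flat, flat, flat]
        tampered = WaveSeries(phases=phases, frequency_hz=60.0)
        axis = principal_axis(labels, 1)
        est = wavelength_over_phases(tampered, 25, axis, labels, 1)
        assert est.mean_wavelength_mm == pytest.approx(30.0, rel=0.03)
        assert sum(lam is None for lam in est.per_phase_mm) == 3
        assert any(f.startswith("dropped_phases") for f in est.qc)

    def test_too_few_valid_phases_is_missing(self):
        spec = single_cylinder_spec()
        labels = make_labelmap(spec)
        series = simulate_waves(labels, spec)
        flat = Volume(np.zeros(spec.grid_shape), series.affine)
        phases = series.phases[:3] + [flat] * 5
        tampered = WaveSeries(phases=phases, frequency_hz=60.0)
        axis = principal_axis(labels, 1)
        est = wavelength_over_phases(tampered, 25, axis, labels, 1)
        assert est.mean_wavelength_mm is None
        assert est.stiffness_kpa is None
        assert "too_few_valid_phases" in est.qc


class TestShearStiffness:
    @pytest.mark.parametrize(
        "lam,expected", [(50.0, 9.0), (30.0, 3.24), (20.0, 1.44)]
    )
    def test_formula_values(self, lam, expected):
        assert shear_stiffness(lam, 60.0, 1000.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_quadratic_in_wavelength(self):
        assert shear_stiffness(44.0) == pytest.approx(
            4 * shear_stiffness(22.0)
        )

    def test_missing_propagates(self):
        assert shear_stiffness(None) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            shear_stiffness(-1.0)


class TestEndToEnd:
    def test_rotation_equivariance_in_plane(self):
        # rotating the muscle and its wave together within the slice
        # plane leaves the estimated wavelength essentially unchanged
        theta = np.deg2rad(20)
        direction = (0.0, np.sin(theta), np.cos(theta))
        spec = single_cylinder_spec(
            grid_shape=(3, 90, 110),
            spacing_mm=(11.6, 1.5, 1.5),
            compartments=[
                Compartment(
                    name="m", shape="cylinder",
                    center_mm=(11.6, 67.0, 82.0), axis=direction,
                    extents_mm=(15.0, 50.0), true_pdff=0.1,
                    true_stiffness_kpa=3.24,
                )
            ],
        )
        labels = make_labelmap(spec)
        series = simulate_waves(labels, spec)
        est = estimate_muscle_stiffness(series, labels, 1)
        assert est.mean_wavelength_mm == pytest.approx(30.0, rel=0.05)

    def test_oblique_contamination_bias_bounded(self):
        clean = single_cylinder_spec()
        dirty = dataclasses.replace(clean, oblique_fraction=0.3)
        labels = make_labelmap(clean)
        est_clean = estimate_muscle_stiffness(
            simulate_waves(labels, clean), labels, 1
        )
        est_dirty = estimate_muscle_stiffness(
            simulate_waves(labels, dirty), labels, 1
        )
        # contaminant wavelength is 0.7 lambda: the estimate may move but
        # must stay inside the envelope set by the two plane waves
        lam = est_dirty.mean_wavelength_mm
        assert 0.7 * 30.0 * 0.9 <= lam <= 30.0 * 1.1
        assert est_clean.stiffness_kpa == pytest.approx(3.24, rel=0.05)
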