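# musclemre

Quantitative analysis of thigh-muscle MR elastography (MRE) and Dixon
fat-fraction MRI, built for researchers studying muscle diseases with
progressive fatty replacement (e.g. Becker muscular dystrophy) who need
reproducible per-muscle outcome measures and their test–retest
reliability.

## What it computes

MRE measures tissue displacement from externally induced vibration waves
(here a 60 Hz driver, eight phase-offset snapshots per slice). Under the
plane shear-wave approximation the shear stiffness of muscle is

    mu = rho * (f * lambda)^2

with density rho = 1000 kg/m3 by convention, driver frequency f and
shear-wave wavelength lambda. The package implements two complementary
per-muscle stiffness estimators plus the surrounding quantification and
statistics:

- **Stiffness-map ROI statistics ("Method A")** — average stiffness per
  muscle from a voxelwise stiffness map produced by a scanner vendor's
  inversion, after masking the map's own invalid regions and discarding
  the 5% lowest and 5% highest voxel values per muscle.
- **Wavelength-based estimation ("Method B")** — fully automated: the
  muscle's main proximo-distal axis from PCA of its 3D segmentation, the
  sagittal slice with maximum muscle overlap, a 1D displacement profile
  along the in-plane-projected axis, the dominant wavelength from a
  zero-padded Fourier power spectrum (wavelengths above 50 mm rejected
  as artefacts), the mean over the eight phases, then mu = rho (f lambda)^2.
- **Dixon quantification** — voxelwise proton-density fat fraction
  PDFF = fat/(fat + water), per-muscle mean PDFF and volume (cc), and the
  normality cutoff mean + 2.5 SD of healthy-control total-thigh PDFF.
- **Reliability statistics** — ICC(A,1) (two-way model, absolute
  agreement, single measurement) with its F-test, Shapiro–Wilk-gated
  Pearson/Spearman correlations, Holm step-down multiple-testing
  correction, normality-gated paired/two-sample tests, and the
  standardized response mean (SRM) for longitudinal sensitivity.
- **Synthetic phantom** — a seeded generator of label maps, Dixon
  fat/water pairs, 8-phase wave images and vendor-style stiffness maps
  with known ground truth, including paired "sessions" and whole cohorts
  for end-to-end test–retest simulation.

## Worked example

```python
import musclemre as m

spec = m.default_phantom_spec(seed=1)          # 4-muscle sagittal phantom
labels = m.make_labelmap(spec)
waves = m.simulate_waves(labels, spec)         # 8 phase offsets at 60 Hz
truth = m.truth_table(spec).set_index("label")
for label in sorted(labels.legend):
    est = m.estimate_muscle_stiffness(waves, labels, label)
    print(f"{est.muscle:<18} slice {est.slice_index}  "
          f"lambda {est.mean_wavelength_mm:5.2f} mm  "
          f"mu {est.stiffness_kpa:5.2f} kPa  "
          f"(truth {truth.loc[label, 'true_stiffness_kpa']:.2f} kPa)")
```

prints

```
rectus_femoris     slice 4  lambda 30.05 mm  mu  3.25 kPa  (truth 3.24 kPa)
vastus_lateralis   slice 2  lambda 25.18 mm  mu  2.28 kPa  (truth 2.30 kPa)
biceps_femoris     slice 6  lambda 33.39 mm  mu  4.01 kPa  (truth 4.00 kPa)
semimembranosus    slice 4  lambda 22.34 mm  mu  1.80 kPa  (truth 1.80 kPa)
```

i.e. the wavelength pipeline recovers each muscle's implanted stiffness
to within a few percent despite image noise and an oblique contaminating
wave. A 30 mm wavelength at 60 Hz corresponds to
mu = 1000 * (60 * 0.030)^2 = 3240 Pa = 3.24 kPa.

The same stages are available from the shell:

```bash
musclemre simulate --seed 7 --out phantom/
musclemre pdff --fat phantom/fat.nii --water phantom/water.nii \
    --labels phantom/labels.nii --legend phantom/labels_legend.csv \
    --out pdff.csv
musclemre stiffness-a --map phantom/stiffness_map.nii \
    --validity phantom/stiffness_valid.nii --labels phantom/labels.nii \
    --legend phantom/labels_legend.csv --out stiff_a.csv
musclemre stiffness-b --waves phantom/waves.nii --labels phantom/labels.nii \
    --legend phantom/labels_legend.csv --out stiff_b.csv
```

`musclemre reliability` and `musclemre longitudinal` consume long-format
measurement CSVs (subject, group, session, muscle, side, metric, value)
and emit the ICC/correlation and change/SRM reports.

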