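# Methods

## Data model and conventions

All images are 3D scalar grids with a 4x4 voxel-to-world affine in mm
(RAS, 0-based indices); voxel spacing is read off the affine column
norms. The sagittal slice stack runs along grid axis 0; in-plane sampling
is along axes 1 (anterior-posterior) and 2 (superior-inferior), so a
muscle's proximo-distal direction is dominantly the world z axis. Wave
data travel as one 4D NIfTI with the eight phase offsets (0deg to 315deg
in 45deg steps, fixed order) on the fourth axis. Stiffness is stored in
Pa internally and converted to kPa at every file, table and CLI surface.
Shared constants (driver frequency 60 Hz, density 1000 kg/m3, trim
fraction 0.05, maximum credible wavelength 50 mm) live in an
`AnalysisConfig` that can be overridden from YAML.

## Synthetic phantom

The phantom emulates the thigh acquisition the pipeline targets: a
sagittal grid of 8 slices at 11.6 mm centre-to-centre spacing (10 mm
slices plus gap) with 1.5 mm in-plane sampling, holding four
parallel cylindrical muscle compartments (rectus femoris, vastus
lateralis, biceps femoris, semimembranosus proxies) whose long axes run
superior-inferior. Each compartment carries a true fat fraction
(0.05-0.35, spanning healthy muscle to marked fatty replacement) and a
true shear stiffness (1.8-4.0 kPa, the range of relaxed thigh muscle at
60 Hz).

* **Dixon pair** — inside muscle m, fat = S*pdff(m) and
  water = S*(1-pdff(m)) for a fixed signal scale S = 100, plus
  independent zero-mean Gaussian noise clipped at zero; the default
  noise SD of S/20 corresponds to SNR 20. Background is noise only.
* **Wave images** — a scalar displacement component (matching a
  single-direction motion-encoding acquisition): per muscle a plane wave
  A sin(2 pi t/lambda + 2 pi k/8) along the muscle axis, with
  lambda = sqrt(mu/rho)/f, plus an oblique contaminant rotated 45deg in
  the slice plane with lambda' = 0.7 lambda and amplitude
  `oblique_fraction * A`. This reproduces, with a controllable knob, the
  known failure mode that oblique wave fronts bias wavelength readings.
  Wave noise is white Gaussian in units of A (no Rician magnitude bias —
  wave images are signed displacement estimates).
* **Vendor-style stiffness map** — per-voxel truth plus Gaussian scatter
  (default SD 0.3 kPa), a fraction of voxels replaced by extreme
  outliers (x10 or x0.1 of truth) and a fraction flagged invalid, per
  muscle; background is never valid, mimicking the shaded
  "not measurable" regions of vendor inversions.

Noise levels for the wave and stiffness maps are free parameters (no
published characterisation exists for this acquisition); tests sweep
them rather than fixing a single value. Per-modality noise parameters
are kept separate because the image units differ.

Every product is deterministic in (spec, seed); each modality draws from
its own child RNG stream so products can be generated independently and
still reproduce bit-identically (the CLI `simulate` command is tested
for byte-identical re-runs).

**Session pairs and cohorts.** A session pair models two scans one week
apart: session 2 keeps the geometry, perturbs every per-muscle truth
multiplicatively by 1 + N(0, sd) and draws fresh noise. The perturbation
is relative so that one knob covers fat fractions and stiffness values
alike. A simulated cohort draws each subject's truths around the
population means with a relative between-subject SD of 0.2 (and a 5%
geometric jitter), a realistic order for adult thigh-muscle
heterogeneity; cohort runs use a reduced 3-muscle grid (6 x 48 x 64
voxels) so that scanning tens of subjects remains cheap while every
muscle keeps >500 voxels. Because session 1 carries the subject's truths
and only session 2 is perturbed, a drift SD equal to the between-subject
SD yields an expected ICC near 0.65, not 0.5; ICC falls below 0.5 once
the drift SD is about twice the between-subject SD.

What the phantom does **not** model: wave refraction, attenuation and
mode conversion at muscle boundaries, viscoelastic dispersion,
anisotropy, MR acquisition physics (k-space, B0/B1 bias, Rician
magnitude noise), segmentation error, and inter-scan repositioning.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated wave and signal models, not clinical
performance on real thigh data, where the wavelength method is known to
be far less reliable than on clean plane waves.

## Dixon quantification

PDFF = fat/(fat+water) voxelwise, clipped to [0, 1]; voxels with
fat+water at or below a signal floor are missing (NaN) rather than
unstable ratios. The floor defaults to 1% of the phantom signal scale —
enough to exclude pure-noise background while keeping all muscle voxels.
An optional pre-correction hook (identity by default) lets users apply a
voxelwise T1-bias correction to the raw fat/water images before the
ratio without the package prescribing a specific formula. Per-muscle
PDFF is the mean over non-missing voxels (median available upstream of
nothing — mean matches the reference workflow); muscle volume is voxel
count times voxel volume, in cc. Total-thigh PDFF pools all in-muscle
voxels (volume-weighted) by default, with an unweighted per-muscle
average as an option. The normality cutoff is control mean + 2.5 sample
SDs, computable from raw control values or from a published mean/SD
summary.

## Stiffness from the vendor map ("Method A")

Label maps drawn on the Dixon acquisition are brought into the
stiffness-map grid by nearest-neighbour resampling through the composed
affines (shared world frame; rigid co-registration is assumed done, and
no deformable registration is attempted since the phantom shares frames
by construction). Within each muscle ROI the map's invalid voxels are
dropped, the remaining values sorted, floor(trim*n) voxels removed from
each tail (trim default 0.05) and the rest averaged. Trimming is
per-muscle, not per-map — a global trim would bias small muscles whose
values sit in the map's tails. floor() tail counts with stable sorting
make the result platform-deterministic. A muscle with no valid voxel
reports a missing mean, and the count bookkeeping (total/valid/used) is
returned alongside.

## Stiffness from wavelength measurement ("Method B")

1. **Axis** — first principal component of the muscle's voxel world
   coordinates, sign fixed towards superior. An elongation ratio
   (sqrt of the leading two eigenvalue ratio) below 1.5 flags a
   near-isotropic shape with an unstable axis.
2. **Slice** — the sagittal slice maximising overlap between the muscle
   and the measurable region (by default the whole wave-image
   footprint); ties break to the lowest index for determinism.
3. **Profile** — the axis is projected into the slice plane (the
   measurement is 2D in-slice); a line through the in-slice centroid is
   sampled by linear interpolation at the finest in-plane spacing,
   restricted to the longest contiguous in-muscle run, and
   mean-centred. Runs under 4 samples are rejected.
4. **Wavelength** — the profile is zero-padded to the next power of two
   at or above 8x its length and the Fourier power spectrum evaluated
   over nonzero frequencies. The spectral peak gives the prevalent
   wavelength; an exact tie prefers the longer wavelength (the
   artefact-conservative choice). If that prevalent wavelength exceeds
   50 mm the measurement is treated as an artefact and reported missing
   — the cutoff is applied to the dominant wavelength itself, so a
   long-wavelength artefact can never masquerade as a plausible
   short-wavelength reading through spectral leakage. No lower bound
   beyond the profile's Nyquist limit is imposed.
5. **Phase averaging** — one dominant wavelength per phase offset,
   missing phases dropped; at least 4 of 8 valid phases are required,
   otherwise the muscle is reported missing with a QC flag. The
   arithmetic mean of the valid wavelengths enters
   mu = rho (f lambda)^2. A pooled mode (average the eight power
   spectra, take one peak) is available behind a flag for sensitivity
   analysis; per-phase averaging is the default as the most literal
   reading of "average wavelength over the eight phases".

All QC failures (degenerate axis, no overlap, short profile, too few
valid phases, artefact wavelength) yield missing values with named
flags, never silent numbers.

With 8x zero-padding, a 100-sample profile at 1.5 mm spacing resolves a
40 mm wavelength to about 1 mm (2.6%), which is why noiseless recovery
is specified at 5% and noisy recovery (wave noise 0.2 A, oblique
fraction 0.2) at 15%.

## Reliability statistics

**ICC(A,1)** is computed from the two-way ANOVA mean squares
(subjects x sessions):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with rows dropped listwise when incomplete. The p-value uses the
subject-effect F test MSR/MSE with (n-1, (n-1)(k-1)) degrees of freedom
— the standard choice for this ICC family. A zero-variance matrix is
perfect agreement by convention (ICC 1, flagged degenerate). Qualitative
bands: >0.90 excellent, >0.75 good, 0.50–0.75 moderate, <0.50 poor.

**Correlations and group tests** are gated on Shapiro–Wilk normality at
alpha = 0.05 applied symmetrically to both variables (or both groups /
the paired differences): normal data get Pearson / t-tests (Welch for
two samples), otherwise Spearman / Wilcoxon (signed-rank paired,
rank-sum unpaired; exact null distributions for n <= 25 without ties).
Zero-variance paired differences return p = 1 with a flag.

**Holm correction** is the step-down adjustment
adj_(i) = max_{j<=i} (m-j+1) p_(j), capped at 1, applied within one
report family: the muscles of one (metric, side) table for reliability
reports, the muscles of one group for longitudinal reports, matching
per-table significance marking.

**SRM** = mean(change) / SD(change) (sample SD), missing when the
changes have zero spread. Longitudinal reports average left/right
observations per subject before the paired tests.

## Verification strategy

Every estimator is checked against an independent oracle: hand ANOVA
and a brute-force loop implementation (plus pingouin) for ICC, the
step-down definition and statsmodels for Holm, direct FFT oracles for
implanted wavelengths, analytic cylinder volumes for rasterisation, and
closed-form stiffness values (50 mm -> 9.0 kPa, 30 mm -> 3.24 kPa). The
end-to-end cohort simulation confirms that ICC is high (>0.9) for
drift-free repeat scans and decreases monotonically as between-session
drift grows relative to the between-subject spread.

Problem sizes used by the test suite and the acceptance script — the
8 x 80 x 110 phantom, 20-subject cohorts on the reduced grid, 20-seed
noise sweeps — were chosen as the smallest sizes at which rasterisation
error, spectral resolution and Monte-Carlo error are comfortably below
the tolerances being checked.
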