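# Methods

This document describes the generative model behind the digital mouse
phantom, the statistical workflow, the parameter choices, and the known
limitations.

## 1. Generative model

### Signal model

Each subject *i* in group *g* has a noise-free concentration image (in
Bq per gram of tissue)

```
C_i(r) = f_b(r) · B_i + s_g · E(r) · ID_i · u
```

where

- `f_b(r)` is the per-voxel blood volume fraction from the atlas
  (1.0 inside the heart blood pool and carotid, organ-typical values
  elsewhere, 0 in background),
- `B_i` is the subject's whole-blood activity concentration (Bq/g),
- `s_g` is the group's specific-binding scale (nonzero for wild type,
  zero for knockout),
- `E(r)` is the per-voxel target-expression level from the atlas,
- `ID_i` is the injected dose (Bq), and
- `u` is a fixed uptake-coupling constant (1.0): specific uptake is
  proportional to dose at matched expression.

Blood activity is coupled to dose with lognormal clearance
variability:

```
B_i = k_blood · ID_i · LN_i(clearance_cv)
```

where `LN_i(cv)` is a unit-mean lognormal deviate with the given
coefficient of variation. Doses are lognormal around their mean with
`injected_dose_cv`. The knockout group's blood level carries a fixed
multiplier (1.3): antibody tracers to a clearance-relevant target are
retained longer in blood when the target is absent.

### Measurement model

1. Bq/g is converted to Bq/mL with the whole-blood density
   1.057 g/mL (the same factor the analysis later inverts).
2. The image is blurred with an isotropic Gaussian PSF
   (`scipy.ndimage.gaussian_filter`, `mode="constant"`), approximating
   scanner resolution; blur is skipped when sigma is 0.
3. Gaussian noise with standard deviation
   `noise_scale · sqrt(max(signal, ε))` is added — the
   variance-proportional-to-mean behaviour of count data.
4. The ex vivo blood assay returns `B_i · (1 + N(0, assay_cv))`,
   clipped at zero (with a warning if clipping occurs).

All randomness flows from one `numpy.random.default_rng(seed)`, so a
cohort is bit-reproducible from its seed.

### Atlas

A 13-region geometric mouse: heart blood pool, myocardium with an
infarct sector, carotid segment, lungs, liver, spleen, vertebral bone
with a bone-marrow core, brain (cortex, white matter, hippocampi) and
background. Regions are painted in a fixed priority order into a single
integer label map, so they are disjoint by construction. Geometry is
specified in grid fractions and radii are clamped to a minimum voxel
count, so every region is present on grids down to 16 voxels per axis.

## 2. Statistical workflow

1. **Analysis mask** — voxels finite and above a floor value in every
   subject.
2. **Blood-VOI derivation** — a voxelwise OLS regression of uptake
   against the ex vivo blood values gives a t-map (`t = slope / SE`,
   `dof = n − 2`). Voxels with `t` above the one-sided p = 0.005
   critical value form clusters at 18-connectivity; clusters with more
   than 50 voxels (strict inequality) survive. Their union is then
   *slope-refined*: only voxels whose regression slope is at least
   `slope_refine_frac` (default 0.7) times the blood density are kept.
   A voxel that is pure blood must have slope ≈ 1.057 (Bq/mL per
   Bq/g); partial-volume voxels have proportionally smaller slopes, so
   the refinement removes the diluted rim that would otherwise bias the
   blood level downward. In the no-noise, no-blur limit the refined VOI
   equals the true pure-blood set exactly.
3. **Blood extraction** — the VOI mean in Bq/mL divided by
   1.057 g/mL gives the image-derived blood level in Bq/g.
4. **Normalization** — blood ratio
   `(image / 1.057) / blood_level` (dimensionless), or
   `%ID/g = (image / 1.057) / dose · 100`.
5. **Group contrast** — pooled-variance two-sample t-maps
   (`dof = nA + nB − 2`) on the normalized images, thresholded
   one-sided at p = 0.05 with the same cluster-extent rule; per-organ
   mean and peak t summaries; regional fold changes with per-subject
   VOI means and a two-sample t-test.
6. **Method agreement** — linear fit (slope with t-based 95% CI, R²),
   Bland–Altman (differences `reference − test`, so a positive bias
   means the image underestimates; limits `bias ± 1.96 · SD`), and
   Pearson correlation.

## 3. Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `n_per_group` | 11 | subjects | typical immunoPET group size |
| `injected_dose_mean_Bq` | 3.4e7 | Bq | ~0.9 MBq-scale tracer dose ×ROI scaling |
| `injected_dose_cv` | 0.18 | – | realistic injection variability |
| `clearance_cv` | 0.25 | – | slow-clearing antibody: large between-subject blood spread |
| `blood_per_dose_per_g` (`k_blood`) | 0.02 | 1/g | blood carries ~2% of dose per gram at scan time |
| KO blood multiplier | 1.3 | – | higher blood retention without target-mediated clearance |
| WT `specific_binding_scale` | 0.001 | – | specific signal modest relative to blood background |
| KO `specific_binding_scale` | 0.0 | – | no target |
| `psf_sigma_mm` | 0.8 | mm | preclinical PET resolution |
| `noise_scale` | 100 | √Bq/mL | visible but not dominant noise |
| `blood_assay_cv` | 0.03 | – | gamma-counter precision |
| blood density | 1.057 | g/mL | whole-blood density |
| VOI threshold | p = 0.005, > 50 voxels | – | uncorrected cluster-extent convention |
| contrast threshold | p = 0.05, > 50 voxels | – | map-level convention |
| connectivity | 18 | – | standard 3-D face+edge neighbourhood |
| `slope_refine_frac` | 0.7 | – | keeps voxels ≥ 70% blood by the slope criterion |

All generative parameters were fixed from the physiological reasoning
above before the validation experiments were run.

## 4. Numerical and design choices

- Voxelwise statistics are vectorized (einsum over subject stacks) but
  are validated against per-voxel scalar closed forms to 1e-10
  relative tolerance, and the cluster extractor against a recursive
  flood-fill labeller.
- Degenerate voxels (zero residual variance) map to ±inf or 0 and are
  flagged on the t-map rather than silently dropped.
- Clusters are ordered by peak t (descending), then size, then
  lexicographic peak index, so reports are deterministic.
- "More than 50 voxels" is read strictly: a 50-voxel cluster does not
  survive.
- NIfTI volumes are written as float32 scalars (int16 for labels) with
  an RAS+ diagonal affine; spacing round-trips at float32 header
  precision.
- Volumes carry a units tag (`Bq/mL`, `Bq/g`, `ratio`, `%ID/g`, `t`,
  `label`) and operations check it, so a %ID/g image cannot be fed
  where a raw image is expected.
- Validation experiments use a 48×48×96 grid at 0.5 mm and 20-seed
  sweeps — large enough for all regions to have stable statistics,
  small enough that the full evaluation runs in well under a minute
  per cohort.

## 5. Limitations

- **Partial-volume effects on thin structures.** With the default
  0.8 mm PSF, the thin bone-marrow cylinder loses contrast to blur, so
  its organ-level t ranks below the liver's even though its expression
  is higher. The expression-rank ordering of organ t-values holds in
  the blur-free regime; with blur it is confounded by structure size.
  The same effect produces the sub-unity agreement slope and positive
  Bland–Altman bias: the image-derived blood level tracks the true one
  tightly but underestimates its magnitude.
- **Degenerate covariates.** If between-subject blood variability is
  (near) zero, the regression against ex vivo blood has no signal and
  VOI derivation correctly fails with `NoClusterError` rather than
  returning an arbitrary region.
- **The phantom is geometric, not anatomical.** It emulates the
  statistical structure of the problem (blood-fraction confound,
  dose/clearance variability, PSF, noise), not mouse anatomy, kinetics
  over time, scatter, attenuation or reconstruction artefacts.
- **Static single-time-point model.** Tracer kinetics are collapsed
  into per-subject scalars; the model cannot address time-activity
  questions.
- **Uncorrected thresholds.** Cluster-extent filtering at uncorrected
  p-values is a pragmatic convention, not familywise error control.
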