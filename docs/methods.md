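# Methods

## Scope and data model

The package quantifies three readouts of lysosomal catabolic activation:
per-organelle fluorescence (segmentation and ROI measures on multi-channel
fields), absolute lysosomal pH (ratiometric dual-emission plate reads), and
organelle-proteomics differential abundance (protein-group intensity
matrices for a lysosomal fraction versus whole lysate). Raw experimental
data are not bundled; seeded generators produce synthetic datasets whose
planted ground truth encodes the study conditions, so every pipeline is
validated as parameter recovery.

## Imaging quantification

Lysosomal ROIs are identified on the organelle-marker channel by background
subtraction, Gaussian blur (σ = 1 px default), a global threshold and
8-connected component labelling with an area filter (4–2000 px² default).
The ROI deliberately covers the whole organelle including the lumen, which
is why a blur precedes thresholding. Per-ROI *integrated density* is the
sum of background-subtracted pixel values; *recruitment* is integrated
density per particle area (the per-particle normalization used for
V1-subunit recruitment to marker-defined lysosomes).

Design choices where common practice varies:

- **Background estimate**: a per-field constant at the 20th intensity
  percentile (reproducible and adequate for flat cytosolic backgrounds); a
  morphological rolling-ball estimate is available as an option.
- **Auto-threshold**: iterative intermeans (IsoData), computed on the probe
  values restricted to lysosomal ROIs of the positive-control (reference)
  condition and averaged across reference fields, then propagated unchanged
  to every condition of the experiment. Pixels equal to the threshold count
  as below it, so a constant probe channel yields an active fraction of 0.
- **Active organelle**: the primary output is the *area percentage* of
  lysosomal ROI pixels above the propagated threshold; an organelle is
  additionally *called* active when more than 50 % of its own pixels exceed
  it. The per-organelle call is a derived quantity.
- **Cell number** is the Hoechst nuclei count (blur σ = 4 px, nucleus-scale
  area filter). Nuclei closer than about one radius merge into one
  component and are counted once.
- **Time courses** re-segment each frame by default (organelles move); a
  frozen-t0-ROI mode exists for low-motion data. The initial quench rate is
  minus the least-squares slope of the t0-normalized curve over the first
  three frames.

Mander's coefficients follow the standard definition (M1 = fraction of
channel-1 intensity in pixels where channel 2 is positive, and symmetrically
M2) on background-subtracted rasters; no statistical-significance
(randomization) correction is applied.

## pH calibration

Calibration wells clamp lysosomal pH to acetate buffers (six levels,
pH 4.2–5.2 by default, three technical replicates); sample wells are free.
The emission ratio R = I440/I540 falls monotonically with rising pH.
Replicate ratios are averaged per buffer pH; the default calibration model
is monotone piecewise-linear interpolation through the per-pH means — over
a one-unit pH span this avoids any functional-form assumption — with a
Boltzmann sigmoid fit as an option. The ratio orientation (rising or
falling with pH) is detected from the data, not hard-coded. Sample ratios
outside the calibrated span are clamped to the boundary pH and flagged
rather than refused, so a plate outlier cannot abort a run. Non-monotone
mean calibration ratios abort with a diagnostic listing the per-pH means.

## Proteomics statistics

All statistics operate on log₂ intensities (LFQ mode) or log₂ ratios
centred on 0 (SILAC mode). The pipeline order is fixed: validity filter →
quantile normalization → imputation → moderated t → Benjamini–Hochberg.

- **Validity filter**: keep a protein if it is quantified in ≥ 70 % of the
  samples of at least one condition, the fraction computed against that
  condition's own sample count and compared with ≥ (4/5 passes, 3/5 fails).
- **Quantile normalization** equalizes column marginals to the across-column
  mean quantile function; missing entries stay missing and observed values
  are mapped through their fractional ranks with ties averaged. When the
  design contrasts biologically different fraction types (lysosomal
  fraction vs whole lysate), normalization runs *within* fraction type:
  the enriched compartment **is** the upper tail of the fraction's marginal,
  and forcing identical marginals across fraction types would flatten that
  tail and systematically compress the very enrichment being measured.
  With no groups given, the classic global normalization is performed.
- **Imputation** models left-censoring of low-abundance proteins: missing
  entries in sample *s* are drawn from Normal(μ_s − 1.8 σ_s, (0.3 σ_s)²)
  in LFQ mode and Normal(0, (0.3 σ_s)²) in SILAC mode, with μ_s, σ_s from
  the observed values of that sample after normalization. A fixed seed
  makes the draw bit-reproducible.
- **Moderated t**: two-group comparison with the per-protein pooled
  variance shrunk toward an ensemble prior. The prior (d₀, s₀²) is
  estimated by moment-matching the scaled-F model on log s²_g (digamma/
  trigamma closed forms with Newton inversion of the trigamma). Zero excess
  variance yields d₀ = ∞ (complete shrinkage, normal reference
  distribution); if every residual variance is zero the prior is
  unidentifiable and the computation falls back to the ordinary t (d₀ = 0).
  The implementation agrees with the reference R implementation to
  ≈1 × 10⁻¹³ in t, p and hyperparameters on shared fixtures.
- **Class enrichment**: per-protein enrichment e_g is the mean log₂
  difference between fraction and lysate samples; a class's fold is
  2^(mean_class e − mean_background e) with the non-lysosomal ("other")
  proteins as background. The operational lysosomal call applies the
  log₂FC > 2 cut-off. Because enrichment is measured relative to the
  background class, column-level location shifts cancel.
- **Densitometry**: a target band is divided by the mean of ubiquitous
  reference-protein bands within each condition, then normalized to the
  control condition (control ≡ 1). A one-sample t against a hypothetical
  mean of 1 is provided for such normalized replicate ratios.

Whether imputation precedes or follows normalization is genuinely open in
common practice; normalization-first is used here (imputed values then
never influence the normalization target) and the order is fixed by the
pipeline rather than configurable per call site.

## Synthetic-data generators

Everything is driven by named presets; identical (preset, seed) gives
bit-identical output, and every planted object appears exactly once in the
returned ground truth.

**Microscopy fields** (512 × 512 px at 0.2 µm/px): organelles are placed by
rejection sampling with a clearance margin so puncta never merge; the count
is validated as feasible for the field size, and an impossible request
raises an error rather than silently truncating. The marker channel renders
each organelle as a Gaussian punctum (σ = radius/2, diffraction-limited);
the probe channel renders a flat-topped (supergaussian) lumen-filling disc,
because the dequenched probe product distributes through the organelle
lumen — with a Gaussian probe profile only ~35 % of a marker-defined ROI
can exceed any threshold between the inactive and active amplitudes, and a
">50 % of pixels" organelle call would be structurally unattainable. Each
organelle's active flag is Bernoulli with the preset's active fraction
(0.18 resting, 0.60 torin1); probe amplitude is drawn from the active or
inactive distribution accordingly. Nuclei are larger flat-topped discs.
Constant cytosolic background plus additive Gaussian read noise completes
each channel. Intensity scales and their spreads are free parameters chosen
for test power, not biological claims.

**Plates**: the generating ratio(pH) is a Boltzmann sigmoid, near-linear
over pH 4.2–5.2, falling ~3-fold across that span — emulating the steep
ratiometric response of the dual-emission probe around its pKa. The
observed ratio carries multiplicative log-normal noise of the preset CV
(5 % default); the absolute I540 level carries an independent well-scale
factor that cancels in the ratio. Presets plant true sample pH 4.7
(resting) and 4.5 (torin1).

**Proteomes**: 2000 proteins × 5 replicates per fraction by default.
Protein base abundance is log-normal (log₂ mean 25, SD 2); annotated
compartment classes (10 % lysosomal, 1 % V-ATPase, 0.5 % mTORC1) are offset
+1.5 log₂ above the bulk, emulating abundant, consistently quantified
complexes whose lysate values sit clear of the censoring tail — without
this, occasional class members are fully censored in the lysate and their
recovered fold is capped at the imputation floor. In fraction samples the
classes are shifted by log₂ of the planted folds (45 / 62 / 80). Entries
are deleted with probability logistic in −intensity (steepness 2 per log₂
unit), the intercept solved so the overall deletion rate matches the preset
(8 %); steep left-censoring is the regime that justifies downshift
imputation. Replicate noise is 0.25 log₂ units.

What the generators do **not** emulate — and hence what passing recovery
tests cannot certify on real data: optical point-spread functions and
out-of-focus light, cell boundaries and spatially varying background,
organelle motion between frames, peptide-level quantification effects
(shared peptides, match-between-runs), correlated replicate structure, and
batch effects. Recovery results certify the correctness of the analysis
pipelines under the stated generative model, not the biology.

## Desk-scale reproduction and determinism

`lysoquant.pipeline.reproduce` runs simulate → quantify → report for all
presets: two plates, 20 fields per imaging condition (enough for ±1 % pooled
binomial error on ~2400 organelles per condition), and one proteome. Every
output file is a deterministic function of the configuration and seed —
reports record seeds and versions but no wall-clock times — so repeat runs
are byte-identical. The whole run takes well under a minute on one CPU.

## Known limitations

- The piecewise-linear calibration inverts the generating sigmoid with up
  to ~0.02 pH interpolation error between knots; the sigmoid model removes
  this at the cost of a parametric assumption.
- The per-organelle active call is threshold-quantized: organelles whose
  probe amplitude falls near the propagated threshold flip between calls
  under read noise. The area-percentage output degrades more gracefully.
- Quantile normalization with tie-averaging maps tied observed values
  through their mean rank, which differs from exact tie handling by at most
  the local curvature of the reference quantile function.
- The MNAR intercept is solved on the pooled value distribution, so the
  realized per-sample missing rate varies around the preset value.
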