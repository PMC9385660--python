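# lysoquant

Quantitative analysis of lysosomal catabolic activation, for cell biologists
studying how nutrient signalling (mTORC1) controls lysosome acidification and
protease activity. The package implements three analysis layers that such
studies rely on, plus seeded synthetic-data generators that make every layer
testable as parameter recovery without access to raw microscopy or mass-
spectrometry data:

- **Per-organelle fluorescence quantification** (`lysoquant.imaging`):
  lysosome segmentation by background subtraction → Gaussian blur → global
  threshold → particle analysis; integrated density per region of interest;
  Mander's colocalization coefficients; normalization of probe signal to
  cell number (Hoechst nuclei); the *active-lysosome fraction* — the share of
  marker-defined organelles whose probe (e.g. cathepsin Magic Red) signal
  exceeds an IsoData auto-threshold derived from a positive-control condition
  and propagated to all conditions; recruitment summaries (probe integrated
  density per particle area, median ± IQR); and fluorescence-quenching time
  courses with initial-rate estimation.
- **Ratiometric lysosomal pH calibration** (`lysoquant.phcal`): dual-emission
  plate reads (I440/I540) of a lysosome-targeted ratiometric probe, calibrated
  against wells whose lysosomal pH is clamped to buffers spanning pH 4.2–5.2;
  the fitted monotone ratio(pH) curve inverse-maps sample ratios to absolute
  pH (piecewise-linear by default, Boltzmann sigmoid optional).
- **Organelle-proteomics statistics** (`lysoquant.protstats`): the fixed
  pipeline *70 %-valid filter → quantile normalization → downshifted
  missing-not-at-random imputation (μ − 1.8 σ, width 0.3 σ, per sample) →
  empirical-Bayes moderated t → Benjamini–Hochberg adjustment*, plus
  compartment fold-enrichment and western-blot densitometry normalization.

The moderated t shrinks each protein's residual variance
`s²_g` (with `d_g` degrees of freedom) toward a prior `s₀²` estimated from
the whole ensemble:

    s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t_g = log₂FC_g / (s_post √(1/n_A + 1/n_B)),  df = d₀ + d_g

with `(d₀, s₀²)` obtained by moment-matching the scaled-F model on
`log s²_g`; the implementation reproduces the reference R implementation
(limma) to 1 × 10⁻¹³ on shared fixtures.

## Worked example

`examples/` contains one narrative script per capability. For instance,

```sh
python examples/calibrate_lysosomal_ph.py
```

prints

```
mef_control: recovered pH 4.72 +/- 0.04 (n=3 wells, true pH 4.7)
mef_torin1: recovered pH 4.51 +/- 0.04 (n=3 wells, true pH 4.5)
```

— the calibration pipeline recovers, from noisy synthetic plate reads, the
resting lysosomal pH (≈4.7) and the ≈0.2-unit acidification caused by one
hour of mTOR-kinase inhibition. Similarly
`examples/score_active_lysosomes.py` prints

```
auto-threshold from 6 torin1 reference fields: 429.6 a.u.

control: 19.4% of 720 lysosomes active
torin1: 59.2% of 720 lysosomes active
```

— under 20 % of lysosomes in resting cells show discernible cathepsin
activity, versus ≈60 % after mTOR-kinase inhibition — and
`examples/proteomics_enrichment.py` recovers the planted compartment
enrichments (lysosomal ≈45-fold, V-ATPase ≈62-fold, mTORC1 ≈80-fold over the
non-lysosomal background) through the full statistical pipeline.

A thin CLI wraps the same functions
(`lysoquant simulate|measure|active-fraction|ph|proteomics|reproduce`);
`lysoquant reproduce --out DIR` runs the whole desk-scale analysis and exits
nonzero if any recovery check fails.

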