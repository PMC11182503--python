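# microftir

Chemometric analysis of high-throughput FTIR (Fourier transform infrared)
spectra of microbial biomass — for microbiologists and spectroscopists who
profile bacterial culture collections grown under varying conditions
(medium, temperature, cultivation time) and need a tested, reproducible
pipeline from raw transmittance exports to publication-grade multivariate
results.

## What it computes

Whole-cell mid-IR spectra (4000–400 cm⁻¹) fingerprint the total cellular
biochemistry: lipids (3050–2800 and 1800–1700 cm⁻¹), proteins
(1700–1500 cm⁻¹), a mixed region (1500–1200 cm⁻¹) and polysaccharides
(1200–700 cm⁻¹). The package implements the standard analysis chain of
such studies:

* **Preprocessing** — spectral quality test, technical-replicate
  averaging, Savitzky–Golay second derivative (order-2 polynomial,
  region-specific windows: 11 points for lipids and the whole region,
  21 for proteins, 15 for the mixed region, 13 for carbohydrates), region
  selection, and extended multiplicative signal correction (EMSC) with
  linear and quadratic terms:

  ```
  z(ν) = a + b·m(ν) + d·ν̃ + e·ν̃² + r(ν),   ν̃ ∈ [−1, 1]
  ```

  fitted per spectrum by least squares against a reference `m` (the set
  mean); the corrected spectrum is `(z − a − d·ν̃ − e·ν̃²)/b`.

* **Chemical variability** — the Pearson-distance statistic on raw
  spectra: within each group, the median over members of
  `1 − PCC(member, group mean)`, averaged over groups per category
  (technical/biological replicates, cultivation time, strain, species,
  genus) and reported as `(1 − PCC)·10³` per spectral region, in a
  three-panel table (broth at 18 °C, agar at 18 °C, agar across
  temperatures).

* **PCA and correlation loadings** — mean-centered (unscaled) principal
  component analysis of the preprocessed matrices, and correlation-loading
  plots: Pearson correlations of spectral variables and *supplementary*
  design variables (temperature-level and strain indicators) with the
  PC1/PC2 scores, read against the 0.5 and 1.0 radius circles.

* **Band detection and assignment** — minima of the second-derivative
  spectra, refined by parabolic interpolation and matched against a curated
  band library that includes the Gram-specific pairs (CH₃ stretch 2960
  vs 2962 cm⁻¹, ester C=O 1741 vs 1743 cm⁻¹, amide I β-sheet 1636 vs
  1640 cm⁻¹), plus Gram-group shift and intensity-contrast tables.

* **Synthetic cohorts with ground truth** — a generator emulating a
  29-strain / 17-species culture-collection study: hierarchical log-normal
  band-height perturbations (genus > species > strain > biological >
  technical), temperature/medium/day condition effects, and a measurement
  model adding baseline, slope, curvature, multiplicative gain and white
  noise. Every stage of the pipeline is verified against this ground truth.

## Worked example

```python
import microftir as mf

cfg = mf.CohortConfig.media_study(seed=1)      # 29 strains, 2 media, 18 °C
cohort, truth = mf.generate_cohort(cfg)        # 522 spectra + ground truth

# Gram-group band shifts from group-mean second derivatives
shifts = mf.gram_shift_table(cohort).set_index("assignment")
print(shifts.loc[["ch3_asym_str", "ester_co"]].round(1))

# chemical variability per grouping category (agar panel, whole region)
agar = cohort.subset((cohort.metadata["medium"] == "BHIA").values)
for cat in ("technical", "biological", "strain", "species", "genus"):
    print(f"{cat:12s} {mf.category_variability(agar, cat, 'whole'):8.2f}")

# preprocess and fit a two-component PCA on the whole region
pm = mf.preprocess_pipeline(cohort, region="whole")
model = mf.SpectralPCA(n_components=2).fit(pm.X)
print(" / ".join(f"{p:.1f}%" for p in model.explained_variance_pct_))
```

prints

```
              position_gram_negative  position_gram_positive  shift
assignment
ch3_asym_str                  2960.0                  2962.0    2.0
ester_co                      1741.0                  1743.0    2.0
technical        0.53
biological       0.73
strain           1.04
species          2.33
genus           32.47
75.0% / 7.5%
```

The CH₃ and ester bands recover the +2 cm⁻¹ Gram-positive shifts encoded
in the band library; the variability column rises strictly through the
taxonomic hierarchy (values are `(1−PCC)·10³`, so 32.47 means a median
Pearson correlation of 0.968 between a spectrum and the all-cohort mean);
and the two leading components carry 75.0 % and 7.5 % of the variance of
this synthetic cohort.

The transformer stages (`SavitzkyGolayDerivative`, `RegionSelector`,
`EMSC`, `SpectralPCA`) are scikit-learn estimators and compose with
`sklearn.pipeline.Pipeline`. A CLI mirrors the library:
`microftir generate | preprocess | variability | pca | corrloadings |
peaks | run`.

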