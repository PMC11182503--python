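# Methods

This note documents the models, defaults and numerical choices behind
`microftir`, and what the synthetic-data-based tests do and do not show
about real measurements.

## Spectral conventions

Wavenumber axes are stored ascending in cm⁻¹; descending instrument
exports are reversed on read. The default grid descends from
4000 cm⁻¹ in 1.928 cm⁻¹ steps to 400 cm⁻¹ (1868 points), the digital
spacing of a high-throughput FTIR unit at 6 cm⁻¹ optical resolution.
Transmittance is converted to absorbance (A = −log₁₀ T) before any
processing; all analysis happens on absorbance or its second derivative.
The analysis range is 700–3100 cm⁻¹; 4000–400 cm⁻¹ is kept only for
storage. Spectral regions are closed intervals — lipids
2800–3050 ∪ 1700–1800, proteins 1500–1700, mixed 1200–1500,
polysaccharides 700–1200 cm⁻¹ — and a grid point on a boundary belongs to
the region. The union of disjoint lipid windows makes an extracted grid
non-uniform at the seam; grid validation therefore tolerates spacings
≥1.5× the median as window gaps while requiring <1 % uniformity
elsewhere.

## Preprocessing chain

The stage order is part of the contract: quality test → technical-replicate
averaging (on absorbance) → Savitzky–Golay second derivative → region
selection → EMSC. A regression test pins this order; swapping derivative
and EMSC demonstrably changes the output.

**Quality test.** The screening criteria are configurable and chosen for
auditability, since published quality tests for this instrument class do
not disclose exact thresholds: maximum absorbance in 1800–900 cm⁻¹
within [0.25, 2.0] (too little biomass vs detector saturation); the SD of
the linearly detrended signal in the band-free 2100–1900 cm⁻¹ window
below 2 % of the maximum signal; no single point in that window exceeding
10× the robust (MAD) noise; and no dominant periodic component
(periodogram maximum >10× the median bin *and* implied amplitude >5×
the noise SD), which flags interference fringes. Spike and fringe checks
are gated on a relative noise floor of 10⁻⁹ so numerically silent
synthetic spectra never trigger them. The test is report-only; the
pipeline drops failures and logs the reasons.

**Savitzky–Golay second derivative.** Order-2 local polynomial, window
sizes fixed per region (11 lipids/whole, 21 proteins, 15 mixed, 13
carbohydrates), scaled by the actual grid spacing (units A·cm²). Edge
points where the centered window does not fit are dropped (the spectrum
shortens by window−1 points) rather than padded: padding would fabricate
data that feeds EMSC. The true derivative sign is kept, so absorbance
bands appear as *minima*; all "peak" language downstream means local
minima. Order-2 SG reproduces quadratics exactly and annihilates affine
signals — both are asserted for every window size.

**EMSC.** Each spectrum is decomposed as
`z = a·1 + b·m + d·ν̃ + e·ν̃² + r` by ordinary least squares, with ν̃ the
wavenumber axis affinely mapped onto [−1, 1] (a Legendre-style basis
chosen for conditioning; coefficients are reported in that basis). The
reference `m` defaults to the mean of the analysis set — per-analysis-set,
not global, when analyses run per species. Correction returns
`(z − a − d·ν̃ − e·ν̃²)/b = m + r/b`. Samples with |b| < 10⁻⁸ are flagged
uncorrectable and excluded; a constant reference makes the design
rank-deficient and is rejected. The synthetic measurement model uses the
same ν̃ convention, so on noise-free input EMSC recovers the generator's
(a, b, d, e) to machine precision — verified against an independent
normal-equations solve.

## Chemical variability

The variability of a group of spectra is the median over members of
`1 − PCC(member, group mean)`; the mean includes the member being
measured (no leave-one-out — the plainest reading of "distance to the
center of the group"). It is computed on **raw** absorbance spectra
restricted to a region: the Pearson correlation is invariant to
per-spectrum offsets and positive scaling, which is precisely why
constant-baseline and multiplicative artifacts need no correction first
(property-tested to 10⁻¹²). Categories average their groups' values
unweighted and report ×10³.

Grouping scheme: each category names the replication level being
assessed, and its groups are the units one level above — technical
replicates within a biological sample; biological replicates within a
strain × condition; cultivation days within strain × temperature; strains
within a species; species within a genus; and a single all-samples group
for the genus row. Each category's spread thus accumulates the variance
components from its level downward, which is what makes the nested
ordering technical < biological < strain < species < genus diagnostic of
a correctly specified hierarchy. The per-temperature rows of the
multi-temperature panel are genus-level (single-group) variability within
that temperature's samples, which is why the 18 °C row reproduces the
agar panel's genus row when the data coincide. Supernatant and
medium-blank samples never enter the table.

## PCA and correlation loadings

PCA mean-centers but never scales variables: second-derivative + EMSC
output is already commensurate, and unit-variance scaling would inflate
quiet spectral windows. Components come from a full SVD; a deterministic
sign convention (the largest-magnitude element of each loading vector is
positive) makes outputs reproducible across runs and platforms.
Correlation loadings are plain Pearson correlations of variables with the
PC1/PC2 score vectors. Design variables — one 0/1 indicator per
temperature level or strain, never a single numeric temperature axis —
are supplementary: they are correlated with the scores but take no part
in the fit (asserted bit-identical with and without them). Radii
√(r₁²+r₂²) are read against the conventional 0.5 (moderate) and 1.0
circles plus a configurable near-center threshold (default 0.3)
operationalizing "no effect". Constant variables have undefined
correlation and are reported as missing, never as zero.

Note a sign subtlety: because bands are minima in the second derivative,
a variable that *grows* with a condition (e.g. the 993 cm⁻¹ carbohydrate
band under heat) correlates *negatively* with that condition's indicator;
association strength, not sign, is the meaningful readout.

## Band detection and assignment

Peaks are local minima of the second derivative below a depth threshold,
refined by 3-point parabolic interpolation (clipped to ±half a step;
sub-0.5 cm⁻¹ accuracy on noise-free bands vs up to 0.96 cm⁻¹ at grid
resolution). The default threshold is self-scaling: 5× the median
absolute second derivative in the band-free 2100–1900 cm⁻¹ zone.
Assignment matches peaks to the Gram-resolved band library greedily by
|offset| within a tolerance of 4 cm⁻¹ (between the 1.928 cm⁻¹ digital
spacing and the 6 cm⁻¹ resolution); each band claims at most one peak,
ties break toward the lower wavenumber. Gram-shift tables are computed on
group-mean spectra, not per sample, mirroring how averaged spectra are
compared in practice.

## Synthetic cohort generator

The generator is the package's ground-truth instrument. It emulates a
culture-collection screening study: 29 strains in 17 species and 11
genera across two Gram groups (a regular synthetic taxonomy is available
for controlled experiments), grown on agar and broth at 4–37 °C with
biological × technical replication.

**Spectra.** Each clean spectrum is a sum of Gaussian bands
`h·exp(−4 ln2 (ν−c)²/w²)` from the packaged library (Gaussians chosen for
closed-form derivatives, making oracles exact). Centers are the assigned
band positions, including the Gram pairs 2960/2962, 1741/1743, 1636/1640
and the presence/absence pair 1466 (Gram−) vs 1453 (Gram+). Heights and
widths are fixture values: plausible relative intensities (amide I
strongest; Gram-negative lipid bands at 3006/2925/2853/1741 elevated
~1.5×), widths 10–14 cm⁻¹ except the amide I components at 6 cm⁻¹ —
the instrument-resolution lower bound, required for the 16 cm⁻¹-spaced
1640/1656 pair to remain resolvable to the nearest integer under the
window-11 derivative kernel. The range-only "1045–1025" glycogen entry is
kept as an annotation row without a synthesizable center.

**Hierarchy.** Band heights carry multiplicative log-normal perturbations
(log-SDs: genus 0.20 > species 0.10 > strain 0.06 > biological 0.03 >
technical 0.01, strict ordering enforced) — log-normal so spectra stay
nonnegative. The magnitudes are chosen so the Pearson-distance table
reproduces the qualitative pattern of real cohorts: replicate rows in
single-digit ×10⁻³, taxonomy rows rising steeply to the genus level.

**Condition effects.** Temperature multiplies component-class heights by
`1 + k₁u + k₂u²`, `u = (T−18)/19`, neutral at 18 °C — the temperature at
which real profiles change least. Signs encode the qualitative
physiology: heat raises polysaccharides most (k₁ = 0.35), cold raises
protein and phosphodiester/mixed bands (k₁ = −0.12, −0.15), lipids
respond least (k₁ = 0.03). A purely even response was rejected: it would
make the 18 °C level the extreme of the effect scale and its indicator
maximally informative rather than central. Broth cultivation applies a
fixed composition shift (polysaccharides ×1.2, proteins ×0.95) and
doubles the replicate-level sigmas, artifact scales and noise
(dispersion ×2), reflecting that shaken liquid culture is less
reproducible than static agar growth. Cultivation day adds a mild linear
trend (2 %/day around day 3).

**Measurement model.** `m(ν) = a + b·s(ν) + d·ν̃ + e·ν̃² + ε(ν)` with
a ~ N(0, 0.02), d ~ N(0, 0.01), e ~ N(0, 0.005), log b ~ N(0, 0.1) (b
within ~×[0.8, 1.25]), ε white with SD 10⁻³ A — visually plausible
baseline and gain variation of well-behaved spectra. Setting all scales
to zero makes the model the identity exactly. Supernatant spectra are a
broth-blank base (bands at 1645, 1570, 1400, 1083 cm⁻¹) plus
genus-specific secreted-product bands through the same measurement model.

Everything is deterministic given the config seed; regenerating
reproduces collections bit-for-bit.

**What the generator does not emulate** — and hence what passing tests do
not establish for real data: Mie and resonant-Mie scattering, water-vapor
and CO₂ lines, detector nonlinearity, band-shape asymmetry
(Lorentzian/Voigt profiles), correlated (pink) noise, and biological
covariance between band heights beyond the shared hierarchy. Results on
real spectra additionally depend on the uncataloged behavior of the
instrument's own quality screening.

## Problem sizes and runtime choices

Tests and the acceptance script use the study-shaped defaults where the
design matters (29-strain cohorts, 522 spectra for the media design) and
compact regular taxonomies (e.g. 1 species × 2 strains, 144 spectra) for
the per-species temperature analysis; the variability-ordering check runs
20 independent seeds of the agar-panel cohort (261 spectra each). The
eigendecomposition, normal-equations and closed-form-derivative oracles
are exact, so their tolerances (10⁻⁸ and tighter) are numerical, not
statistical.

## Known limitations

* The quality-test thresholds are reasoned defaults, not a reimplementation
  of any published screening method; real datasets may need tuning.
* EMSC here is the polynomial-basis variant; no resonant-Mie extension.
* Band assignment is nearest-center matching; overlapping bands are not
  deconvolved, and strongly shifted real bands (>4 cm⁻¹) come back
  unassigned rather than guessed.
* JCAMP-DX support covers fixed/AFFN XYDATA tables only (no compressed
  SQZ/DIF forms).
* The variability table's cultivation-time row requires multi-day data;
  single-day cohorts leave it absent (NaN), never zero.
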