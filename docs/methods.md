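# Methods

## Assay reduction

Potential enzyme activities are measured by incubating a soil suspension
(1 g fresh soil in 125 mL deionized water) with a fluorogenic substrate
(200 µL suspension + 50 µL of 200 µM substrate per well; 4 h dark at
25 °C; 365/450 nm). Substrates release 4-MUB on hydrolysis (AMC for the
LAP substrate). The plate design carries five well roles per
sample × enzyme: 6 assay wells, 3 homogenate controls (sample + water),
3 substrate controls (substrate + water), 6 quench standards
(standard + sample) and 6 reference standards (standard + water).

Reduction follows the corrected scheme of German et al. (2011):

```
emission  = mean(reference std) / standard amount          [fluorescence nmol⁻¹]
quench    = (mean(quench std) − mean(homogenate)) / mean(reference std)
net       = (mean(assay) − mean(homogenate)) / quench − mean(substrate ctrl)
activity  = net × suspension / (emission × aliquot × time × soil mass)
```

with the standard amount 0.5 nmol (50 µL × 10 µM, configurable).
Choices the protocol leaves open, resolved here:

* **Aggregation** — arithmetic mean per well group; the assay CV is
  computed on assay wells only.
* **Negative net fluorescence** is retained and flagged (`below-blank`),
  never clamped to zero, so that downstream log-based stoichiometry
  fails loudly on bad plates.
* **Mass basis** — fresh-soil mass as assayed; an optional
  `moisture_fraction` converts to dry-mass basis.
* **No volume correction** between the homogenate control (200 µL + 50
  µL) and substrate control (50 µL + 50 µL): the two roles are
  asymmetric in total volume, and the protocol describes none. Their
  means are subtracted as read.
* **QC thresholds** — replicate counts are checked against the 6/3/3/6/6
  design; assay CV above 0.30 and quench outside (0.2, 1.2] are flagged.
  These are report-only: flags never drop samples.

## Stoichiometry and the vector model

EES ratios divide logs of summed activities (see README). Two
formula-level decisions:

* **EES C:P uses ln(βG) alone** while the vector x-component uses
  ln(βG + CBH). The asymmetry is intentional and preserved; a test pins
  it (raising CBH moves EES C:N but not EES C:P).
* **Vector length is √(x² + y²)** and the **angle** is the polar angle of
  (x, y) measured from the abscissa, i.e. `degrees(atan2(y, x))` in
  math-library argument order. Spreadsheet `ATAN2` takes the abscissa
  first; only this orientation makes ACP dominance produce angles above
  45° = phosphorus limitation, which is the behaviour the classifier and
  tests encode.

**Log-domain rule.** Every log argument (βG, βG+CBH, NAG+LAP, ACP) must
exceed 1 nmol g⁻¹ h⁻¹. At or below 1 the logarithms reach zero or flip
sign and the ratios become meaningless; such samples are emitted with
missing stoichiometry plus a `log-domain` flag naming the offending
enzyme, never silently dropped or propagated as NaN. Because the ratios
use unnormalised logs they are unit-sensitive: rescaling all activities
by a common factor changes the values. Activities outside [10, 10⁵]
nmol g⁻¹ h⁻¹ attract a `unit-scale-warning` flag.

**Limitation classification** is by strict inequality around 45° with a
tolerance band (default 10⁻⁹ degrees) reported as `threshold` — the
boundary case is not forced into either class.

**Soil ratios** default to a mass basis (SOC/TN, SOC/TP, TN/TP in
mg g⁻¹); a molar toggle divides by atomic masses 12.011/14.007/30.974.

## Comparison statistics

* **t tests** are two-sided, Welch by default (pooled variance
  available). Zero-variance degeneracies resolve by convention: equal
  means → t = 0, p = 1; unequal means → flagged infinite statistic.
* **Homogeneity of variance** uses the Brown–Forsythe variant of
  Levene's test (absolute deviations from group medians), heterogeneous
  at p < 0.05; all-constant data are homogeneous by convention. When
  heterogeneous and all values positive, the natural log is applied and
  the check repeated (`auto_transform`); non-positive values block the
  transform with a flag.
* **Two-way ANOVA** (season × management, with interaction): balanced
  designs use the classical orthogonal partition, whose conservation
  (SS_A + SS_B + SS_AB + SS_resid = SS_total) is asserted to 1e-9
  relative in tests; unbalanced designs use Type-II sums of squares via
  statsmodels. On balanced data the two coincide, which a test verifies
  against statsmodels directly. Interaction estimation requires every
  cell to hold n ≥ 2; an empty cell is an error naming the cell.
* **LSD post hoc** uses pairwise t statistics on the one-way residual
  mean square and df, protected by the omnibus F: when the omnibus is
  not significant at α all groups share letter "a". Letters are
  assigned greedily in descending-mean order, so groups sharing a letter
  do not differ significantly; the display is deterministic.
* p-values are not corrected across metrics; each metric's battery is
  reported as-is.

## Synthetic data generator

The generator emulates a two-season, three-management field survey.
Every variable (five enzymes, SOC, TN, TP) is drawn lognormally:
`value = geometric_mean × exp(N(0, σ_ln))`, with one geometric mean per
season × management cell and a shared σ_ln (default 0.15). Lognormal
noise reflects strict positivity and the right skew of enzyme data;
σ_ln = 0.15 keeps the coded directional effects detectable at the
field-scale n = 5 per cell while n = 30 makes them robust for
confidence-interval checks.

Default geometric means — spring: βG 40, CBH 20, NAG 25, LAP 15, ACP
150 (nmol g⁻¹ h⁻¹), SOC 26, TN 1.9, TP 0.55 (mg g⁻¹); autumn: βG 65,
CBH 30, NAG 45, LAP 18, ACP 170, SOC 20, TN 1.8, TP 0.62. Organic
management (HY) carries a ×1.15 bump on all enzymes and TN. These
encode, in expectation: higher C-enzyme activity in autumn; higher soil
C:N and C:P in spring; ACP dominance (every cell's expected vector angle
above 45°); EES C:N above 1 in both seasons; spring EES C:P and N:P
below 1. TP is set slightly higher in autumn — the seasonal TP direction
is an assumption of the generator, chosen so the spring C:P elevation is
carried by both SOC and TP.

Reproducibility: each cell draws from an independent substream derived
from the global seed and a CRC32 of the "season:management" label via
`numpy.random.SeedSequence`, so adding or reordering cells never
perturbs other cells' draws.

**Forward plate simulation** inverts the reduction formulas exactly
(instrument model: true quench 0.8, emission 500 fluorescence/nmol,
background 20, optional additive Gaussian reading noise), so zero-noise
plates round-trip through `activity_from_plate` to 1e-9 relative and
noisy plates give unbiased recovery in expectation.

**What passing tests show — and do not.** The generator's samples are
independent lognormals with exact cell structure. Real soil data carry
spatial autocorrelation between field replicates, enzyme–enzyme
correlation within a sample, assay batch effects and occasional plate
failures, none of which are simulated (plate failures can be induced
manually via `PlateSimConfig`). Pipeline correctness and statistical
calibration established here therefore transfer to real data only in so
far as those data approximate independent lognormal variation.

## Problem sizes

Default test and acceptance runs use 30 samples per cell (180 total) for
regime-level claims, 1,000 random profiles for the formula oracle, 200
plates for noisy recovery, and 2,000 simulations for type-I-error
calibration; these sizes give stable estimates at the asserted
tolerances while keeping a full run in seconds.

## Known limitations

* Single-timepoint assays only: no kinetic (multi-read) reduction, no
  substrate-saturation (Km/Vmax) modelling, no vendor plate-reader file
  parsing.
* No Threshold Elemental Ratio or carbon-use-efficiency models; the
  vector model is the only limitation metric.
* The multivariate battery of a full survey analysis (NMDS, ANOSIM, RDA,
  Mantel, random forest, SEM) is out of scope; outputs are tidy CSVs
  ready for those tools.
* EES values depend on the activity unit (see log-domain rule); inputs
  must be in nmol g⁻¹ h⁻¹.
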