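# Methods

`nirscalib` implements the chemometric calibration workflow used to turn
near-infrared (NIR) reflectance spectra of plant stalk material into
predictions of mechanical-strength traits — rind penetrometer resistance
(RPR, N·mm⁻²) and breaking force (N) — together with the laboratory
reference-value processing that produces the trait values being calibrated
against, and a synthetic-data generator that makes every stage testable
without instrument data.

## The calibration model

The core model is PLS1 (partial least squares regression with a single
response), computed by NIPALS. With column-centered spectra
X (n × p) and centered reference values y:

for each latent variable a = 1..A:
w_a = Xᵀy/‖Xᵀy‖, t_a = Xw_a, p_a = Xᵀt_a/t_aᵀt_a, q_a = yᵀt_a/t_aᵀt_a,
then X ← X − t_a p_aᵀ and y ← y − q_a t_a. The regression vector is
B = W(PᵀW)⁻¹q, and predictions are ŷ = ȳ + (x − x̄)ᵀB. PLS1 is
deterministic — no random initialization — and successive score vectors are
mutually orthogonal, which the test suite asserts. At full rank (A = p) the
solution collapses to ordinary least squares; this equivalence, and exact
agreement of the segmented cross-validation machinery with a brute-force
leave-one-out loop, are the two numerical oracles anchoring the
implementation. A fit is rejected with an error naming the failing
component if the requested rank exceeds the data rank (zero-norm weight).

## Model statistics

For a scored stage (calibration, cross-validation, external validation):

- RMSE = √(Σ(ŷᵢ−yᵢ)²/n) — RMSEC/RMSECV/RMSEP by stage;
- R² = 1 − SS_res/SS_tot against the observed values of that stage;
- RPD = SD_ref/RMSE, reported at two decimals, where SD_ref is always the
  calibration-set reference SD (ddof = 1). The CV-stage arithmetic of the
  published statistics this convention was checked against is exact
  (7.62/0.74 → 10.30; 6.08/2.51 → 2.42); external-stage conventions differ
  between software packages, so ours is declared rather than
  reverse-engineered. RPD > 2.5 is the conventional "fair / adequate for
  screening" threshold.
- A perfect fit (RMSE = 0) reports RPD = +∞ rather than erroring.

## Pretreatment

Ten per-spectrum operators (COE, SSL, SNV, MMN, MSC, FD, SED, FD+SSL,
FD+SNV, FD+MSC) are available ahead of PLS; combination methods apply the
derivative first, then the scatter step, matching the naming order.
Defining properties (all property-tested): SNV output has mean 0 and sample
SD 1; MSC regresses a spectrum on a reference and inverts the fitted affine
map, making it invariant under x → αx + β (α > 0); COE subtracts the
minimum; MMN rescales to [0, 1]; SSL removes the least-squares straight
line in wavenumber; FD/SED are Savitzky–Golay derivatives (window 17
points, polynomial order 2 by default — configurable; the underlying filter
is exact for polynomials up to the fitting order and preserves grid length
via polynomial-fit edge handling).

Only MSC carries fitted state: its reference is the calibration-set mean
spectrum (of the derivative spectra for FD+MSC), frozen into the model so
prediction never uses new-data statistics. Inside cross-validation the
pretreatment is refit on every training fold for the same reason.

On multi-interval wavelength selections, grid-dependent operators (FD, SED,
SSL) act per contiguous grid block — a derivative across a window gap is
meaningless — while amplitude operators (SNV, MMN, COE, MSC) act on the
whole selected vector. Window bounds are closed intervals matched
inclusively against the grid, so range labels like "5669.7–9626.9" have no
off-by-one ambiguity. Spectra are stored on an ascending wavenumber grid
regardless of file order (FT-NIR exports are often descending); conversion
happens at the I/O boundary. The pipeline operates on intensities as given
(reflectance or absorbance); log10(1/R) conversion is offered as an explicit
option since vendor software does not always document which representation
it models.

## Spectral QC: PCA and GH

Population structure and outliers are screened by PCA on the
column-centered (unscaled — spectral variables share units) matrix, k = 10
components by default. The GH ("global distance") of a sample is its
squared Mahalanobis distance in the k-dimensional score space divided by k,
using the fitting-set score covariance (n−1 denominator); with that
convention the mean GH over the fitting set is exactly (n−1)/n, a trace
identity the tests assert. Samples with GH > 3.0 (standard NIRS practice)
are flagged and reported; removal is an explicit pipeline option, never
silent.

A note on detectability: GH screening operates in the retained score space,
so a corruption is only visible if it is large relative to the population's
own variation along the retained components. Under the generator's default
scatter (offset SD 0.1 absorbance) an offset of 0.02 absorbance — ten times
the default instrument noise — is *within* normal scatter variation and is
correctly not flagged. The outlier-recovery tests therefore use either the
generator's gross default corruption (0.5 absorbance offset + tilt + a
random broad bump per sample) against the full scattered population, or a
scatter-free population with instrument noise SD 0.05 where ten times the
noise SD is genuinely gross; both yield recall ≥ 0.9 at GH > 3 with no
false flags, and both conditions were fixed from this analysis before the
tests were frozen.

## Splitting, model search, global modeling

The sample set is split into calibration and external-validation sets at a
4:1 ratio (seeded uniform split, counts by rounding). The samples carrying
the global minimum and maximum reference values are then swapped into the
calibration set (exchanging with random validation members to preserve
counts), so external validation never asks the model to extrapolate beyond
its calibrated range.

Model search evaluates every candidate pretreatment × wavelength-window
pair: rank is selected by segmented cross-validation (default 10 segments;
leave-one-out available) with a parsimony rule — the smallest rank whose
RMSECV is within 2% of the minimum (pure argmin by flag) — since vendor
rank heuristics are undocumented; candidates are ranked by RMSECV (ties:
higher R²cv, then lower rank) and the full leaderboard is returned. The
default window-candidate generator splits the grid into 10 equal blocks and
forms all unions of at most two disjoint block runs, covering the
two-interval selections typical of published models; exhaustive vendor-style
region optimization is out of scope. Rank selection costs one NIPALS fit
per fold: the fold is fitted once at the maximum rank and coefficient
vectors for all smaller ranks are extracted from it.

"Global" modeling merges calibration and validation sets and reruns rank
selection + cross-validation on the union with the chosen
pretreatment/windows, reported as a separate stage.

## Laboratory reference layer

An RPR replicate is five position readings reduced to the mean of the three
left after removing one maximum and one minimum (exactly one instance each
under ties); breaking force records a single peak per replicate. Six
replicates per genotype aggregate to mean, sample SD, SE = SD/√n, and a
relative deviation expressed as the replicate coefficient of variation
(SD/mean·100) — the definition consistent with the published summary values
for both traits. The genotype mean is the reference value used for
calibration, matching spectra that are themselves genotype-level averages.
Trait–trait association uses Pearson correlation on shared genotypes with a
two-sided t-test at α = 0.01.

## Synthetic data generator

The generator encodes the study conditions so tests have known truth:

- **Reference traits**: truncated normal on the observed trait range
  (RPR: mean 42.0, SD 7.62, range 22.8–79.7 N·mm⁻²; breaking force: 20.3,
  6.08, 6.6–32.8 N), plus a separate measurement-error layer (SD 0.94 and
  1.15 respectively) — so the latent trait and the irreducible error floor
  are both known exactly.
- **Spectra**: generated in absorbance, where Beer–Lambert mixing is
  linear: a baseline plus 5 informative Gaussian bands whose concentrations
  are affine in the standardized latent trait (slopes ±U(0.4, 1.0), small
  concentration noise) and 8 independent interferent bands; then a
  per-sample scatter distortion m·A + o + t·ν̃ (multiplicative SD 0.2,
  offset SD 0.1, tilt SD 0.05 on a [−1, 1]-normalized wavenumber axis) and
  white noise (SD 0.002). The grid is 4000–12000 cm⁻¹ at 1038 points
  (≈7.7 cm⁻¹ spacing, FT-NIR-like). A reflectance export (10^−A) exercises
  the log10(1/R) path.
- **Replicates**: between-replicate SD 2.2 and within-replicate (position)
  SD 1.2 N·mm⁻² for RPR (single-peak SD 2.8 N for breaking force), chosen
  so genotype standard errors fall in the observed 0.57–1.19 band with the
  published means (≈0.94/1.15) and relative deviations (≈5.5%/14%).
- **Outliers**: a seeded fraction of spectra receives gross offset + tilt +
  random-center bump corruption (default 0.5 absorbance) with ground-truth
  flags for QC recall tests.

What the generator does *not* emulate: real band assignments of stalk
chemistry, wavelength-dependent noise, instrument drift between seasons,
nonlinear detector effects, or genotype population structure. Passing tests
therefore demonstrate that the machinery recovers a known linear
latent-trait signal under realistic scatter and noise — not that any
particular field dataset will reach the same statistics.

## Problem sizes and determinism

Simulation-backed tests run at desk scale chosen as the package's own
defaults: parameter-recovery at n = 500 spectra × 1038 variables over 20
seeds; pretreatment-benefit comparisons at n = 150 × 300 over 50 seeds; QC
recall at n = 200 × 300. Typical results: cross-validated R² ≈ 0.97,
RPD ≈ 5–6, |R²cv − R²ev| < 0.02 — consistent with a population whose
irreducible reference error (0.94) is small against its spread (7.62). All
randomness flows from integer seeds through `numpy.random.default_rng`;
identical configurations reproduce byte-identical leaderboard CSVs.

## Known limitations

- PLS1 only (one trait per model); PLS2 multi-response is not implemented.
- The window search is a block heuristic, not exhaustive region
  optimization; optimal published intervals need not be representable.
- External-stage RPD conventions vary across software; comparisons to
  values computed with other conventions can differ in the second decimal.
- GH screening shares the usual Mahalanobis masking caveat: heavy outlier
  contamination inflates the score covariance and shrinks distances; the
  flagged-not-removed default keeps this visible to the analyst.
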