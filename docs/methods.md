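# Methods

This note documents the models and numerical choices behind the package:
what the synthetic generators emulate, how the lipidome cohort is
calibrated, how each processing stage is defined where the underlying
workflow left details open, and what the passing test suite does and does
not demonstrate about real data.

## Synthetic lipidome cohort

### Composition model

A sample's lipidome is represented as a joint molar composition over
(total acyl carbons C ∈ {30, 32, …, 44}) × (double bonds DB ∈ {0…7}),
restricted to chemically plausible cells (short chain pairs cannot carry
many double bonds; the allowed maximum DB rises from 2 at C30 to 7 at
C40–44). Three tissue groups — plaque, surrounding, control — each have a
target joint table summing to 100 mol%.

The marginal targets are anchored to published group-level values:
saturated lipids average 11 mol% over all 24 samples, monounsaturated
36 mol%, tri-unsaturated 1.3 mol% (the least abundant unsaturated bin);
plaque UFA 88.6% vs surrounding 90.2%; mean chain length 36.76 C
(plaque) vs 37.02 C (surrounding); C30 bin 0.85 mol% on average; paired
plaque-minus-surrounding effects of +1.6 pp for saturated lipids, −1.8 pp
for DB2, +1.9 pp for C32, +1.8 pp for the species PC 32:0. The published
group means (UFA 88 ± 1 vs 91 ± 1) and the paired saturated effect
(+1.6 ± 0.5) cannot hold simultaneously as exact equalities; the default
calibration places the group means at 88.6/90.2 — inside both printed
SDs — so that the paired effect is exact. The unprinted bins are free
parameters chosen once for a realistic gray-matter lipidome (abundant
monounsaturated species, polyunsaturated mass concentrated in
arachidonoyl/docosahexaenoyl 36–40 C species) and shipped as the
documented default configuration.

Calibration is deterministic and happens at run time:

1. the across-group mean joint table is obtained by iterative
   proportional fitting (IPF) of a plausibility seed to the mean carbon
   and double-bond marginals (convergence tolerance 1e-12);
2. the paired-difference table D (row sums = carbon-bin effects, column
   sums = DB-bin effects) and the control-offset table G are mass-weighted
   minimum-norm least-squares solutions — minimizing Σ x²/m so
   well-populated cells absorb the reallocation — with the (C32, DB0)
   cell pinned to `species_effect / within-cell weight` = 1.8/0.9 = 2.0
   so that PC 32:0 carries exactly the configured species effect;
3. group tables are mean ∓ (D+G)/2 etc.; any negative cell raises a
   configuration error.

Each joint cell is split into species by a fixed class rule (PC
dominant, PE second, sphingomyelin/ceramide only at DB ≤ 3, PS/PI only at
C ≥ 36, a small ether-PC share; the (32, 0) cell is 0.9 PC 32:0 +
0.1 PE 32:0). Within-cell weights are identical across groups, so species
effects are cell effects times the weight.

### Noise model

Per-sample compositions are logistic-normal perturbations of the target
cell masses: mass ∝ target · exp(σ·z), renormalized to 100. AD cases use
a case-level log-SD of 0.035 shared between the paired plaque and
surrounding samples plus a within-sample log-SD of 0.02; control samples
use a single scale of 0.12 — deliberately several times larger, emulating
the broad spread of manually selected control gray-matter regions versus
the machine-guided plaque/surrounding extraction. The plaque sample adds
g·D to its (renormalized) base masses with a per-case scalar effect size
g ~ N(1, 0.33) truncated to [0, 2], so expected paired differences equal
the calibrated effects while per-bin paired SDs land near the published
±0.5 to ±0.9 pp. One global `noise_sd_scale` multiplies every noise
source; at zero each sample reproduces its group target to machine
precision. Expected aggregates match targets up to second-order
logistic-normal bias (≲ 0.05 pp at the default scales). Species
concentrations are reported in pmol (lognormal per-sample totals around
2000 pmol); small lysophospholipid and labeled-standard spikes are added
so the exclusion stage is exercised.

Limitations: species within a joint cell are perfectly correlated (noise
acts at cell level); class proportions do not vary between groups beyond
the calibrated bin effects; no missing species, no censoring at detection
limits, no isotope or ion-suppression artifacts. Passing recovery tests
therefore show that the pipeline's arithmetic and statistics are correct
under the stated composition model, not that real cohorts will reproduce
the printed values.

## Synthetic IR scenes

Absorbance cubes are additive Gaussian bands (peak height above zero
baseline) at tissue-typical positions: C–H stretches 2850/2920/2960,
alkene =C–H 3012 (height 0.05), ester C=O 1738 (0.30), amide I 1655
(0.80) and its β-sheet component 1630 (0.30), amide II 1545. FTIR grids
span 948–3700 cm⁻¹ at 1.9 cm⁻¹ (1449 points); QCL grids 948–1800 cm⁻¹ at
2 cm⁻¹ (427 points). Circular lesions multiply the alkene amplitude by
`alkene_scale` ∈ (0, 1] and the 1630 cm⁻¹ amplitude by
`amide1630_scale` ≥ 1. The scatter baseline is a per-pixel random-phase
sinusoid-plus-slope — a smooth stand-in for Mie ripple, not a physical
Mie model — and noise is i.i.d. Gaussian per sample point. Ground truth
(lesion mask, core/corona stain stand-ins, per-pixel scale maps) is
returned with each scene.

## Spectral preprocessing choices

* **SNR** (definition unspecified upstream): maximum absorbance in the
  amide-I window (1600–1700 cm⁻¹) divided by the SD of the residual after
  linear detrending in a band-free window (1900–2100 cm⁻¹ on FTIR grids,
  1000–1300 cm⁻¹ on QCL grids); noiseless spectra return +inf. Pixels
  with SNR < 100 are excluded.
* **Scatter exclusion** (criterion unspecified upstream): the score is
  the EMSC additive-coefficient energy ‖a‖₂ relative to the
  multiplicative coefficient b; by default pixels above
  median + 5 scaled-MAD are flagged, so homogeneous scenes keep all
  pixels while isolated high-scatter pixels are removed. This is a
  documented stand-in, configurable via an absolute cutoff.
* **EMSC**: ordinary least squares against a reference (the mean of the
  pixels unless supplied) with a Legendre polynomial baseline, default
  order 2; extra basis vectors (e.g. Mie extinction curves) are accepted
  but none are shipped. b ≤ 1e-8 is a degenerate fit. Resonant-Mie
  iteration is out of scope.
* **Band quantification**: baseline-corrected peak height — maximum in
  center ± halfwidth minus the line through the mean absorbance of two
  flanking anchor windows, floored at 0; integrated area is available
  behind a flag. The alkene anchors (2988–3000 / 3024–3036 cm⁻¹) sit
  close to the measurement window so that both flanks see essentially
  only the alkene band's own tails, which scale with its amplitude:
  ratios of alkene heights (lesion vs background) are then unbiased by
  the neighbouring C–H bands. Peak-height maxima are noise-biased
  per pixel (max of ~11 noisy samples); quantitative ratio estimates
  should be computed on region mean spectra, which is what the original
  workflow does and what the tests assert (recovery of `alkene_scale`
  within 5% at noise SD ≤ 0.005 AU).
* Wavenumber grids are stored ascending internally; file order is
  preserved on write.

## Registration and region masks

Affine transforms are least-squares fits of user point pairs (exact for
three non-collinear pairs); collinear geometry is rejected. IF channels
are resampled onto the IR grid by nearest neighbour after the transform,
with pixels assigned by the center-point rule. Otsu thresholds use 256
uniform bins over the observed range and the convention mask = values ≥
threshold; scores can tie exactly across empty histogram bins, where any
threshold in the plateau induces the same mask. The surrounding ring is
grown outward from the combined core∪corona mask by a Euclidean disc
(default 9 px ≈ 10 µm at FTIR pixel size), inner edge flush with the
plaque boundary. There is no computable criterion for the original
visual overlay check; the affine fit reports residual RMS instead.

## Detection, morphology, shapes

Tiles are anchored every `tile_size − overlap` pixels with the final
row/column flush to the image edge (extra overlap, no padding).
Reassembly takes the per-pixel maximum over covering tiles. The trained
segmentation network of the original workflow is not redistributable, so
scoring is an interface; the reference scorer rescales the 1630/1655
band-height ratio linearly between 0.72 (tissue-like) and 0.84 (strongly
β-sheet-shifted), clipped to [0, 1].

Morphology radii in µm are converted to pixels by rounding (minimum
1 px): at 4.25 µm pixels the 15 µm dilation and 10 µm erosion become 4 px
and 2 px, a net +2 px (8.5 µm) margin for the nominal +5 µm; the disc
margin property is therefore asserted in pixel units. Components use
8-connectivity, holes 4-connectivity; structuring elements are Euclidean
discs. Shape criteria default to eccentricity ≤ 0.95 and solidity ≥ 0.7
(thresholds unspecified upstream, configurable). Because the margin is
intentional, detection precision is evaluated against the truth mask
dilated by the same net margin, while recall is evaluated against the
raw truth mask; both exceed 0.9 at lesion contrast `amide1630_scale` ≥
1.5 and noise SD ≤ 0.005 over 20 seeds.

Object outlines are traced exactly along pixel edges (union of pixel
squares, collinear vertices removed), so polygon area equals pixel count
× pixel area; border-touching components are excluded with a warning.
Stage coordinates come from a least-squares 4-parameter Helmert
(similarity) transform, solved in closed form via complex least squares
(exact for two pairs). Pixel centers are at (i+0.5, j+0.5)·pixel_size
with x = column, y = row, origin top-left.

## Lipidomics statistics

* Double-bond counting includes the sphingoid-base C=C of sphingolipids
  (`Cer 18:1;O2/14:0` has 1 DB); switchable at parse level by treating
  classes separately if ever needed — the choice is documented because
  sum notation does not distinguish base from N-acyl unsaturation.
* Carbon bins are the even sums 30–44; species outside the range stay in
  an overflow bucket and are *not* renormalized away (profiles plus
  overflow always sum to 100).
* Plaque-vs-surrounding uses paired per-case differences (mean ± SD over
  cases); cross-group comparisons use Welch's t-test with
  Welch–Satterthwaite degrees of freedom and no multiple-testing
  adjustment; significance stars follow the usual
  0.05/0.01/0.001/0.0001 convention.
* PCA standardizes features to mean 0, SD 1 (ddof = 1) and decomposes by
  SVD — the PCA of the correlation matrix; zero-variance features are
  dropped with a warning; component signs make each component's
  largest-magnitude loading positive.
* The linear separator tries a numerically hard margin first (C = 1e6)
  and falls back to a soft margin with penalty 1.0 when the classes are
  not separable, reporting training accuracy either way.
* Species correlations are Pearson R with two-sided p-values; the
  intended reading of the published correlation-figure caption is
  |R| ≥ 0.6 for "strong" and p ≤ 0.05 for "significant" (the printed
  inequalities are inverted); self-correlations and zero-variance
  species are masked.
* Neutral lipids (TG/DG/CE) are not part of the default panel or totals.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
problem sizes chosen as adequate for their statistical assertions:
cohorts of 8+8 cases (64+64 for the aggregate-recovery property), IR
scenes of 48²–160² pixels, 20-seed Monte-Carlo loops, and 10⁴-replicate
null calibration of Welch's test. Every stochastic step flows from a
single integer seed through `numpy.random.default_rng`; the same seed
reproduces outputs bit for bit.
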