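# Methods

This note documents the models, parameters and numerical choices
behind `retimorph`, including which defaults are surrogates for
quantities that the underlying laboratory workflow fixes only
qualitatively, and what the synthetic-data suite does and does not
demonstrate.

## Image model and conventions

Images are single-channel 2-D intensity grids with a physical scale
(µm per pixel, default 0.636 — a typical 10× wholemount acquisition).
Internally all operators work on floats in [0, 1]; the readers
normalise 8/16-bit integer data by the dtype maximum.  Coordinates
are 0-based with the origin at the top-left, x = column, y = row;
areas are in px² and converted to µm² by the squared scale.  An
`analysed_mask` marks non-artefact pixels: oversaturated regions
(optic nerve head, retina edges) are zeroed and excluded from density
denominators.

## Preprocessing chain

Order: gamma → despeckle → remove outliers → attribute top-hat →
local threshold → cleanup.  The classical workflow names these
operators but not their numeric settings; the defaults here are
surrogates chosen to work on the synthetic suite and are all
configurable (`PreprocessConfig`, YAML-mirrored):

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.8 | mild mid-tone boost; endpoints fixed |
| `despeckle_radius` | 1 | 3×3 median, reflect edges |
| `outlier_radius` / `outlier_threshold` | 2 px / 50 (8-bit units) | bright pixel replaced by disc median iff excess > threshold |
| `tophat_area_lambda` | 10 000 px² | area-opening scale; must exceed the largest cell body (~2 000 px²) |
| `threshold_method` | `moments` | or `isodata` |
| `threshold_radius` | 15 px | half-side of the local histogram window |
| `threshold_min_contrast` | 0.1 | degenerate-window extension (below) |

**Local thresholding.**  Intensities are quantised to 256 bins over
the image's global range (this makes IsoData binarisation invariant
to affine intensity rescaling), per-pixel window histograms are
accumulated by box filtering one indicator image per bin, and a
threshold bin is computed per pixel: IsoData iterates the intermeans
recursion t ← ⌊(µ_below(t)+µ_above(t))/2 + ½⌋ to a fixed point
(initialised at the occupied-range midpoint, clipped into it);
Moments solves the Tsai moment-preserving equations for the target
below-threshold fraction p₀ and takes the first bin whose cumulative
fraction exceeds p₀.  Foreground is strictly `bin > t`.  Constant
windows are background; `threshold_min_contrast` extends this rule to
noisy floats — windows whose occupied bin range is below that
fraction of the global range are also background, since both
histogram rules otherwise split pure background noise into arbitrary
halves.  Windowed operators use reflect padding throughout.

**Cleanup.**  The raw binary mask is hole-filled (windows wholly
inside a large bright body are low-contrast and threshold to
background) and opened with the 3×3 cross.  The opening removes
1-px-wide residues of microglial processes attached to the body —
without it, a surviving process stub can stretch a ramified body's
F_max past the classification cut-off.

## Particle analysis

Cell bodies are 8-connected components (the classical default) with
area filters (default min 20 px², max unbounded) and optional border
exclusion (default on); labels follow raster order of each
component's first pixel.

The 34-parameter record comprises: area; mean, stddev, mode (8-bit
quantised), min, max, median, skewness, kurtosis of the intensities;
integrated density (µm²·mean) and raw integrated density (sum); x, y
(centroid of pixel centres) and xm, ym (intensity-weighted);
perimeter; bx, by, width, height (bounding box); major, minor, angle
(ellipse with matched second central moments, rescaled to the pixel
area, + 1/12 px² per-pixel variance correction); circularity
4πA/P² (clamped to 1); feret_max, feret_min, feret_angle, feret_x,
feret_y; aspect ratio major/minor; roundness 4A/(π·major²); solidity
A/A_hull; convex area; and FDR = F_max/F_min.  The exact membership
of the canonical 34-column set is a reconstruction of the standard
particle-analysis output (the defining table is not public); the
column order is fixed in `FEATURE_COLUMNS` and in the CSV exports.

**Convex hull and Feret diameters.**  The hull is taken over the
pixel-corner polygon (each pixel contributes its four unit-square
corners), so a single pixel has F_min = 1 and positive hull area, and
solidity can never exceed 1.  F_max is the maximum pairwise distance
between hull vertices; F_min is computed exactly by rotating calipers
(minimum over hull edges of the farthest vertex distance to the edge
line).  The test-suite oracle is an independent rotation sweep with
successive refinement around the minimum — the width function of a
polygon has a kink at its minimum, so a single coarse angular grid is
only first-order accurate there.

**Perimeter** is the length of the closed Moore boundary walk through
boundary pixel centres, diagonal steps weighted √2; a single pixel is
treated as a unit square (perimeter 4).  A 10×10 square therefore has
perimeter 36 and circularity 4π·100/36² ≈ 0.97.

## Morphotype criterion

The cascade (ramified → rod → amoeboid → hyper-ramified → activated)
is evaluated in that order, each step consuming the records that
previous steps did not claim.  The two load-bearing cut-offs are
quantitative: the ramified/non-ramified boundary at F_max = 13.201 µm
(the reference minimum amoeboid body length) and the rod elongation
cut-off FDR = 3, with ties (FDR exactly 3) classified as rod.  Steps
3–5 are a deterministic surrogate for distinctions that are partly
qualitative in practice (manual cross-referencing of per-cell binar-
ised crops): solidity ≥ 0.90 for the smooth compact amoeboid body,
and area ≥ 60 µm² with circularity < 0.6 for the large lobular
hyper-ramified body.  These three bounds are configurable and should
not be read as an exact published rule; they were chosen so the
cascade cleanly separates the generator's five shape families.

## Linear SVM classifier

One-vs-rest linear SVC (C = 1.0) over all 34 features, z-scored with
statistics fit on the training folds only (no leakage).  Stratified
k-fold (default 5) cross-validation pools out-of-fold predictions
into the confusion matrix and per-class TPR/FNR, and out-of-fold
decision scores into per-class one-vs-rest ROC curves and AUCs; the
final model is refit on all rows.  One-vs-rest was chosen because it
matches per-class ROC reporting; whether out-of-fold or
resubstitution scores feed a published ROC is often unstated —
out-of-fold is the honest choice and is what is implemented.  TNR
values near zero sometimes reported alongside near-perfect AUCs are
treated as FNR (a true-negative rate cannot be near zero when AUC ≈
1); this package reports FNR.  Model files carry a format version,
the training seed, fold count and a hash of the training matrix;
loading a truncated or incompatible file raises.

## Perivascular analysis

The traced vessel image is binarised by the non-black rule (> 0 in
any channel).  The PA band is `distance ≤ 59.5 px` under the exact
Euclidean distance transform — the half-pixel threshold suggests a
pixel-centre Euclidean band, and Euclidean is the default (chessboard
offered as an option).  Cell membership uses the centroid rounded
half-away-from-zero.  The synthetic generator computes its PA truth
flags by brute-force minimum distance over all vessel pixels, an
independent route that the tests require to agree exactly with the
distance-transform path.

## Retina statistics

Densities are cells per analysed (artefact-excluded) pixel — the
masking rationale implies excluded pixels should not dilute density —
and morphotype counts are percentages of each retina's total, so
retinas of different analysed area are comparable.  PA and nPA
percentages are computed within the respective subsets.  Bland–Altman
agreement reports mean difference and mean ± 1.96 sample SD (ddof 1).
Published limits of agreement from manual-count comparisons depend on
the original images and are treated as report-format references, not
reproduction targets.  Group tests delegate to standard routines
(scipy, statsmodels); the two-way ANOVA's pairwise follow-ups use
Šidák correction by default (configurable), since "multiple
comparisons" alone does not pin down the procedure.

## Synthetic retina generator

The generator emulates Iba-1-like wholemounts: a smooth uneven
background (sum of 2–4 low-frequency sinusoids, amplitude 0.08,
base level 0.12), Gaussian pixel noise (default σ = 0.03; the easy
regime used in end-to-end tests is σ = 0.01), curvilinear vessels
(sine-wandering paths, width 4 px), and five parametric cell-body
families with thin (1 px) process polylines at lower intensity
(0.35–0.5 vs 0.75–0.95 for bodies):

- **ramified** — disc, diameter U(5, 11) µm, 5 long processes;
- **hyper-ramified** — ellipse core with boundary lobes anchored at
  both ends of each axis (pinning the Feret calipers) plus notches
  between lobes, F_max U(15, 25) µm, FDR U(1.5, 2.7), constrained to
  area ≥ 70 µm², circularity ≤ 0.50 and solidity ≤ 0.88;
- **activated** — ellipse with 3–4 broad shallow circular bites on
  the shoulders (solidity ≤ 0.83 while circularity stays ≥ 0.63 and
  the extreme points — both calipers — are untouched), F_max
  U(14, 22) µm, FDR U(1.5, 2.7), 3 short processes;
- **rod** — ellipse, major axis U(18, 28) µm, axis ratio U(3.3, 5.5),
  bipolar processes along the principal axis;
- **amoeboid** — near-circular smooth body, F_max U(15, 24) µm,
  solidity ≥ 0.93, no processes.

The FDR ranges of hyper-ramified and rod leave the symmetric gap
(2.7, 3.3) around 3, so the midpoint between the two measured FDR
distributions recovers the rod cut-off; the suite asserts 3.0 ± 0.15,
the residual being pixel discretisation.  Because the pixel-corner
hull widens measurements asymmetrically (≈ +0.3 px on the long
caliper, ≈ +0.85 px on the short one, measured on digitised
ellipses), the continuous axes are shrunk by those biases before
rasterisation so that *measured* statistics land in the declared
ranges; each body builder additionally rejects rare rasterisations
whose measured FDR/circularity/solidity fall outside its family's
band (hyper-ramified bodies must also survive a 3×3-cross opening as
a single component, since the detection pipeline applies exactly that
cleanup).  Bodies are placed by rejection sampling with no body
overlap and an 8 px border margin; truth rows record the measured
body centroid, generating label, target shape parameters and the
brute-force PA flag.

`make_feature_table` is a feature-space shortcut that samples
34-parameter vectors directly, bypassing imaging: the five
discriminative features (F_max, FDR, solidity, area, circularity)
come from the per-class ranges above, the rest from weakly
informative distributions shaped like pipeline measurements — in
particular the intensity min/skewness/kurtosis mimic the left-skewed,
heavy-tailed histograms of detected particles (which include diluted
boundary pixels), so a model trained on the table transfers to
measured records.

**What passing tests show — and don't.**  The generator encodes the
criterion's separability: class parameter ranges are disjoint exactly
where the cascade's cut-offs separate them, mirroring a
criterion-driven training-set construction.  Synthetic results
therefore demonstrate the internal consistency and numerical
correctness of the pipeline (detection, measurement, classification,
PA geometry), not biological classification accuracy on real retinas,
where class boundaries are not crisp, staining artefacts abound and
processes overlap.  No point-spread function or photon-noise model is
simulated.

## Problem sizes

Default test problem sizes were chosen to exercise every code path at
desk scale: 512×512 synthetic retinas with 50 cells for end-to-end
recovery, 1 200-row training tables (240 per class) for the
classifier, 400 stamps for the cut-off recovery, 32×32 images for the
exhaustive threshold oracles and 128×128 grids for the brute-force PA
oracle.

## Known limitations

- Segmentation parameters are surrogates; real acquisitions will need
  per-dataset tuning of gamma, top-hat λ and the threshold radius.
- The criterion's amoeboid/hyper-ramified/activated bounds are a
  deterministic stand-in for a partly manual decision.
- Process (branch) morphology is not measured — classification uses
  cell-body parameters only.
- Vessel tracing is accepted as input; no automatic vessel
  segmentation is provided.
- The local threshold's per-bin box-filter histogram costs O(bins ·
  pixels) memory (≈ 270 MB at 512×512, float32); very large mosaics
  should be tiled.
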