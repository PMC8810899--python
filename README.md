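# retimorph

Automated microglia characterisation for wholemount retinal
fluorescence images: cell-body counting, 34-parameter morphometry,
five-class morphotype classification (rule-based and linear SVM), and
perivascular-area analysis — with a seeded synthetic-retina generator
so the whole pipeline is testable without any imaging data.

## Who this is for

Retinal neuroinflammation studies routinely stain microglia (Iba-1)
in flat-mounted retinas and ask three questions per sample: how many
microglia are there, what morphological state are they in, and how
many sit next to blood vessels?  Manual counting and shape scoring of
thousands of cells per retina is slow and observer-dependent.
`retimorph` automates that workflow for single-channel wholemount
images with a known physical scale (default 0.636 µm/px).

## The method

**Counting.**  The image is gamma-adjusted, despeckled (3×3 median),
cleared of bright outliers, and flattened with a grayscale
attribute-filter top-hat (`img − area_opening(img, λ)`), which keeps
bright structures smaller than λ px² and removes uneven staining.
Cell bodies are then binarised with a local auto-threshold — IsoData
(iterative intermeans, t ← (µ_below + µ_above)/2) or the Tsai
moment-preserving rule — computed from the histogram of a square
window around every pixel, and detected as 8-connected components.

**Morphometry.**  Each detected body is measured into a canonical
34-parameter record: intensity statistics, centroids, bounding box,
moment-matched ellipse, perimeter and circularity 4πA/P², convex
area and solidity A/A_hull, and the Feret diameters.  F_max is the
greatest distance between two parallel tangents (maximum caliper over
the convex hull of the pixel-corner polygon), F_min the minimum
caliper width by exact rotating calipers, and the Feret diameter
ratio FDR = F_max/F_min measures elongation.

**Morphotypes.**  Five canonical classes are assigned by a
deterministic cascade over the record:

1. *ramified* iff F_max < 13.201 µm;
2. *rod* iff FDR ≥ 3;
3. *amoeboid* iff solidity ≥ 0.90;
4. *hyper-ramified* iff area ≥ 60 µm² and circularity < 0.6;
5. *activated* otherwise.

The criterion labels a pool of measured cells, from which a balanced
training table (240 cells per class, 1200 rows) is compiled and a
linear SVM is trained over all 34 parameters with stratified 5-fold
cross-validation (confusion matrix, per-class TPR/FNR, one-vs-rest
ROC/AUC from out-of-fold decision scores).

**Perivascular analysis.**  A traced vessel image is binarised
(non-black = vessel) and every pixel within 59.5 px of a vessel pixel
(Euclidean distance transform) forms the perivascular area; a cell is
PA iff its centroid pixel falls inside the band.

**Statistics.**  Per-retina summaries (cells per analysed pixel,
morphotype percentages overall and within PA/nPA), Bland–Altman
agreement between counting variants (bias ± 1.96 SD limits), and
group tests (Kruskal–Wallis, Mann–Whitney, two-way ANOVA with
Šidák-corrected comparisons).

## Worked example

Generate a synthetic retina (8 cells per morphotype on a 512×512
canvas), count, train and deploy:

```bash
retimorph synth --out-dir synth --n-per-type 8 --seed 1
retimorph count synth/retina.tif --out-dir count
retimorph train --out-dir train --per-class-n 240 --seed 1
retimorph run synth/retina.tif --vessels synth/vessels.tif \
    --model train/model.joblib --out-dir run
```

which logs

```
INFO wrote synthetic retina with 40 cells to synth
INFO segmenting retina.tif (moments threshold)
INFO counted 40 cells -> count/cells.csv
INFO trained SVM: min TPR 0.992, min AUC 0.9974
INFO retina retina: 40 cells, density 1.53e-04 cells/px
```

All 40 planted cells are recovered (no spurious detections), the
cross-validated classifier separates the five morphotypes with
minimum per-class true-positive rate 99.2 % and minimum one-vs-rest
AUC 0.9974, and `run/summary.csv` reports exactly 20 % per morphotype
— the planted proportions — at a density of 1.53·10⁻⁴ cells per
analysed pixel.  `run/cells_labelled.csv` carries the per-cell
34-parameter records with predicted morphotype and PA flag.

The same operations are available as a library:

```python
from retimorph import make_retina, segment, find_particles, measure
img, truth, vessels = make_retina(n_per_type=8, seed=1)
cells = find_particles(segment(img))
record = measure(cells[0], img)   # 34 named parameters
```

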