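# Methods

## The screening model

The screen treats a subtype-resolved single-cell dataset as two aligned
subtype × gene matrices: mean log2(CPM+1) *intensity* and detection
*fraction* (share of the subtype's cells with raw count > 0). For a target
gene, every gated cell-surface molecule (CSM) receives the Pearson
correlation of its column with the target's column in each matrix, and the
integrated score is the arithmetic mean of the two coefficients. Sorting
ascending puts inverse-expression partners (score → −1) first. The score is
exactly −1 iff the candidate is a decreasing affine transform of the target
in both matrices; this limit is the package's defining identity and is
checked both in the test suite and by `scripts/acceptance.py`.

Conventions that were genuinely open and how they were fixed:

* **CSM gate.** "mean > 3 log2(CPM+1) and fraction > 50% in at least one
  subtype" is read *jointly* — both thresholds in the same subtype — the
  stricter interpretation; `joint=False` switches to the disjoint reading.
  Both comparisons are strict.
* **Zero-variance candidates** (e.g. never detected) have undefined Pearson
  r; they are reported with NaN and excluded from ranking rather than given
  score 0.
* **Ties** in ranking and in cosine matching break lexicographically by gene
  or label, making outputs order-independent and reproducible.
* **ipTM merging** averages however many per-model scores are provided; five
  models is the expected default, not enforced.

## QC and normalization

Filters run in a fixed order: (1) ERCC spike-in outliers — cells whose
spike-in count fraction exceeds median + 3×MAD across cells (the outlier rule
itself is a package choice, logged in the QC report and configurable); (2)
library size < 100,000 counts OR mitochondrial fraction > 5%, both strict, so
a cell at exactly the boundary survives; (3) marker-positive selection over a
user-supplied panel (the marker genes are an input, not a built-in list).
Normalization is log2(1e6·c/L + 1). ERCC spike-ins are excluded from the
library size L and dropped from the normalized output (they are not cellular
transcripts); mitochondrial genes are kept in both. Both choices are
configurable. Raw counts ride along in `layers["counts"]` because detection
("expression fraction") is defined on raw counts, not normalized values.

## Synthetic data: what it emulates, and what it does not

`gen_sc_counts` emulates the structure of a plate-based SMART-seq2 PN atlas:

* 40 subtypes × 30 cells by default (tens of cells per type), ~1000 genes of
  which 40 are CSMs, 3 markers, 10 mitochondrial (`mt:` prefix), 20 ERCC
  (`ERCC-` prefix);
* library sizes log-normal with mean 3×10⁵ and σ=0.25, so the 100,000-count
  QC floor trims a tail rather than the bulk;
* per-cell mitochondrial and ERCC fractions uniform on [0.5%, 3%] and
  [0.5%, 2%], below the QC ceiling;
* counts negative-binomial (dispersion θ=2, var = µ + µ²/θ) around
  subtype-level expected proportions scaled to the cell's library, thinned by
  independent dropout (rate 0.15).

CSM intensity profiles are **on/off bimodal** across subtypes (off ≈ 0–2, on
≈ 5–10 log2 CPM units with 50% on-probability): differential CSMs in real PN
data are near-binary per type, and this is the regime in which the fraction
("breadth") matrix carries signal rather than saturating at 1. Background
gene intensities are drawn on U(6,12) plus per-subtype jitter so that the
implied proportions are approximately self-consistent with the CPM scale at
the default gene count. The planted partner's intensity vector is
`strength · (a − target) + (1 − strength) · random`, hence exactly Pearson
−1 against the target at strength 1 *before sampling*; the ground-truth
object stores the pre-sampling vectors so tests can verify this identity
independent of noise.

Not emulated: read-level chemistry, UMIs, batch effects, doublets, ambient
RNA, gene–gene correlation beyond the planted pair, or intensity-dependent
dropout. Consequently, passing tests demonstrate that the pipeline recovers
planted inverse-expression structure under NB + dropout noise — not that the
generator reproduces the empirical count distribution of any real dataset.

Binding images are hard disks of uniform intrinsic intensity on uniform
background with optional additive Gaussian noise — the simplest model that
exercises Otsu thresholding and the area/circularity gates. Control cells
carry a nucleus inside a larger uniform-ECD body so the dilated nuclear ROI
measures the planted intensity exactly when noiseless. Gradient images are
exact opposing linear ramps; clone tables are binomial draws with
per-glomerulus tallies bounded by the mistargeted total by construction.

## Image quantification conventions

* Histograms for Otsu use 256 bins over the observed range (8-bit heritage);
  foreground is strictly above the threshold. On plateaus of the
  between-class variance (empty histogram gaps) any cut is optimal; the
  first maximizer is taken.
* Connected components are 8-connected. Circularity is 4π·area/perimeter²
  with the **Crofton** multi-directional perimeter estimator: naive pixel-edge
  counting makes rasterized disks fail a 0.9 circularity gate, Crofton keeps
  disks of radius ≥ 10 px above it while a 1-px line scores far below.
* Nuclear ROIs are dilated by round(1.25 µm / pixel size) px (minimum 1 px,
  else a warning and no dilation) to approximate cell-body extent; dilated
  ROIs touching the transfected (FL) mask are dropped.
* The area (7.8–23.4 µm², inclusive) and circularity (> 0.9, strict) gates
  are evaluated on the **pre-dilation nuclear component**; the dilated region
  is the measurement mask. Rationale: the gate window matches nuclear areas
  (diameters ≈ 3.1–5.5 µm), and a nucleus inside the window would always
  leave the window after a 1.25 µm dilation, which would empty the gate.
  `gate_on="dilated"` switches to gating the dilated ROI.
* Gates apply to control ROIs only by default; transfected ROIs are reported
  ungated.

## Spatial profiles

Line profiles sample at unit spacing along the segment with bilinear
interpolation, averaging `width_px` (default 10) evenly spaced perpendicular
offsets per step. Each profile is min-max normalized per lobe per channel
*before* averaging; constant profiles are flagged degenerate and returned as
zeros with a warning rather than dividing by zero. Profiles of different
pixel lengths are linearly resampled to 100 points on [0,1] (the resampling
length is a package choice; any length preserving the profile shape works)
and averaged pointwise with SEM = sd/√n (ddof = 1). Glomerular measures are
per-ROI ratios of means (mean(channel)/mean(reference)), not means of pixel
ratios; ROIs with zero reference mean are flagged invalid.

## Statistics

* **Fisher exact, two-sided**, by the probability method: the p-value sums
  hypergeometric probabilities of all tables with the observed margins whose
  probability does not exceed the observed table's (small relative tolerance
  for floating-point ties). Degenerate margins give p = 1. The test suite
  checks this against exhaustive enumeration on every 2×2 table with margins
  ≤ 12 and verifies the empirical type-I error at α = 0.05 stays ≤ 0.06
  under a null of equal penetrance (the exact test is conservative).
* **BH FDR** is the step-up adjustment; the family is exactly the set of
  p-values submitted in one call (for penetrance, all pairwise genotype
  comparisons in that call). Assembling families across panels is the
  caller's responsibility.
* **Šídák**: p_adj = 1 − (1 − p)^m.
* **Repeated-measures two-way ANOVA** requires a balanced complete
  within-subject design (one observation per subject × factor-A × factor-B
  cell); each effect is tested against its interaction with subjects. With a
  degenerate (all-equal) response both numerator and denominator mean squares
  vanish and the convention F = 0, p = 1 applies. Pairwise A contrasts within
  each B level use paired t tests, Šídák-adjusted over the whole contrast
  family. The decomposition is cross-checked against an independent
  implementation in the tests.
* **Penetrance**: a glomerulus is a "primary" destination only at frequency
  strictly above 0.20. Stars follow *p<0.05, **p<0.01, ***p<0.001.

## Problem sizes and determinism

Tests and the demo run reduced configurations (10–30 subtypes, 15–30 cells
per subtype, 200–300 genes) chosen so that planted effects remain
recoverable; generator defaults stay at the study-scale conditions above.
Every stochastic step takes an explicit seed; a single seed fans out through
`numpy.random.SeedSequence` substreams, and identical configuration + seed
reproduces outputs bit for bit. Replicate-based guarantees (planted-partner
rank 1 in ≥ 18/20 replicates; adjusted p < 0.001 in ≥ 18/20 power
replicates) are evaluated over fixed seed ranges, making them deterministic
checks of a stochastic property.

## Known limitations

* The anti-correlation screen assumes profiles over identical subtype sets;
  no masking or subsetting of subtypes is performed.
* Cluster-to-reference matching uses cosine similarity on mean profiles over
  a caller-chosen gene list (default: shared genes); feature selection and
  clustering themselves are out of scope and arrive as inputs.
* The RM-ANOVA rejects unbalanced designs outright instead of fitting a
  mixed model.
* Glomerulus segmentation is manual input by design; no registration across
  brains is attempted.
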