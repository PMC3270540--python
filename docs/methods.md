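# Methods

## Cooccurrence model

The order-*n* grey-level cooccurrence matrix generalizes classical pair
counting to pixel *n*-tuples. A displacement set holds n−1 integer vectors
(dx_i, dy_i) (x rightwards, y downwards); the anchor pixel is the first
tuple element and occupies the central position of the pattern. Matching is
by absolute value with a sign constraint on the coordinate-difference
product, so an axis-aligned vector admits both ± placements of its neighbour
and a diagonal vector the two placements whose Δx·Δy product has the sign of
dx·dy. Under this rule, order 2 with a single axis-aligned vector reproduces
classical *symmetric* Haralick counting, which is the anchor for all
correctness testing: the sparse engine is checked for exact integer equality
against a brute-force enumerator that re-evaluates the predicate over every
pixel per tuple slot, and the order-2 features are checked against
scikit-image's `graycomatrix`/classical formulas to 1e−9.

Tuples may revisit a pixel (e.g. both placements of a collinear pair resolve
to the same position on a narrow map); the definition does not require
distinct positions, and the oracle counts identically. Tuples with any
neighbour out of bounds or outside the validity mask are skipped whole.

Standard geometries: order 2 — directions 0°/45°/90°/135° at magnitude 1
(the classical adjacency; the magnitude is configurable); order 3 — four
collinear direction pairs (0°,180°), (90°,270°), (45°,225°), (135°,315°) and
eight right-angle pairs (0°,90°), (90°,180°), (180°,270°), (0°,270°),
(45°,135°), (135°,225°), (225°,315°), (45°,315°); order 5 — the groups
(0°,180°,90°,270°) and (45°,225°,135°,315°). Orders 3 and 5 use magnitude 2,
and magnitude scales each nonzero component, so components stay in {0, ±2}
(a Euclidean reading would shrink diagonal components to ±1 and contradict
the stated component set). Storage is a hash map keyed by label tuples:
a dense order-5 array over 256 levels (256⁵ cells) is infeasible, while the
number of observed tuples is bounded by the pixel count, so sparse counting
is exact at full 8-bit depth.

## Extended Haralick statistics

For a normalized tensor p over tuples t = (g₁,…,gₙ), with
D2(t) = 2/(n(n−1))·Σ_{i<j}(g_i−g_j)²:

- energy = Σ p(t)²; entropy = −Σ p(t)·ln p(t) (natural log everywhere);
- contrast = Σ p(t)·D2(t); homogeneity = Σ p(t)/(1+D2(t));
- variance = Σ p(t)·(1/n)Σ_i(g_i−μ)² with μ the p-weighted mean level;
- correlation = Σ p(t)·Π_i(g_i−μ_i) / Π_i σ_i over the n positional
  marginals, reported 0 when any marginal is constant (the n-th
  cross-central moment has no meaningful normalization there);
- max_probability = max p(t).

At n = 2 every formula reduces exactly to the classical definition
(D2 = (g₁−g₂)², positional marginals = row/column marginals). The
generalization via mean pairwise squared differences was chosen because it
is symmetric in the tuple slots, reduces correctly, and keeps homogeneity in
(0, 1]; this reduction is enforced by the oracle test rather than assumed.

## Edge analysis

Gradients are 3×3 Sobel with edge replication; a pixel is an edge when its
gradient magnitude strictly exceeds a threshold (default 0, i.e. any nonzero
gradient). Orientation = round(atan2(G_y, G_x)) in degrees folded into
[0°, 180°) — edges are undirected, so the 180° ambiguity is physical — at a
configurable bin width (default 1°). The EOCM reuses the counting engine
with the edge mask as validity mask and orientations as labels (180 levels).

Edge-orientation variability is the angular deviation of the doubled-angle
distribution: with R the circular resultant of 2·orientation, the feature is
sqrt(2(1−R)) converted to degrees — 0 iff all orientations coincide, ≈81.03°
for a uniform spread. Doubling is the standard treatment for axial data;
without it, orientations 1° and 179° would look maximally different although
they describe nearly the same undirected edge. With fewer than two edge
pixels the feature is recorded as missing.

A caution discovered while testing: a perfect 0/255 checkerboard has *zero*
Sobel response in its interior (the two sampled columns share parity and
cancel), so "everything is an edge" intuitions need textures with a genuine
intensity ramp.

## Classical descriptors

- Mean grey level of the ROI (echogenicity).
- Laws microstructures: the image is correlated with the five symmetric 5×5
  kernels XᵀX for X in {L5, E5, S5, W5, R5}; each absolute response map is
  normalized by the |L5ᵀL5| map, and a pixel is a microstructure hit when
  its normalized energy strictly exceeds mean + k·std of that map
  (default k = 1 — no detection rule is standard, so the z-score rule is a
  documented default). Frequency (count) and density (fraction) per class.
  Note that an isolated 1-pixel impulse excites the wave/ripple kernels on
  more taps than the spot kernel; spot-like textures at the kernel scale
  (2–3 px blobs) are what the spot class detects.
- Two-level Haar wavelet entropies: dwt2 gives LL/LH/HL/HH, each decomposed
  again (20 subbands); Shannon entropy of the normalized squared-coefficient
  distribution per subband (energy rather than raw coefficients, so the
  value is sign- and scale-invariant); an all-zero subband has entropy 0.
- Gradient mean/std and edge density.

Feature averaging over directions happens at the feature level (statistics
of each direction's matrix are averaged), not by pooling matrices. Per-ROI
assembly is schema-stable: degenerate sub-features (e.g. an EOCM direction
with no edge tuples on a constant ROI) become NaN, imputed later by column
means, never dropped columns.

## Feature selection

Columns are discretized by Fayyad–Irani MDL-stopped entropy splitting (the
default inside the toolkit whose CFS/IG implementations this follows);
features with no accepted cut carry zero information. Entropies in this
module are in bits. Symmetrical uncertainty
SU = 2(H(a)+H(b)−H(a,b))/(H(a)+H(b)) (0 when both entropies vanish) feeds
the CFS merit k·r̄_cf/√(k + k(k−1)·r̄_ff); information gain
IG = H(C) − H(C|A) ranks single attributes.

The genetic search uses bitstring chromosomes, population 20, 20
generations, single-point crossover at 0.6, per-bit mutation at 0.033, seed
1 (the reference settings, all configurable). Two design choices were open
and are ours: one elite chromosome per generation (stabilizes the best-ever
contract), and a *windowed* roulette wheel — selection probability
proportional to merit above the generation's worst — because raw-merit
roulette degenerates to near-uniform selection when merits cluster; with
windowing the search matches exhaustive enumeration on ≥90% of seeded
10-feature benchmark tables. The returned subset is additionally floored at
the best singleton, which the search space always contains. The final
relevant set is the union of the CFS subset with the top-k information-gain
features (default k = 10, capped at the feature count; the exact cutoff used
historically is unknown, so it is exposed); the set is never empty — the
top-1 IG feature is retained as a floor.

## Textural model and evaluation

The textural model stores, per selected feature and class: relevance (how
many of the two selectors retained it: 0–2), mean, standard deviation, and a
normalized histogram over the pooled feature range (default 16 bins; a
constant feature collapses to a spike).

Evaluation is stratified k-fold (default 5, i.e. 80%/20% splits) with a
seeded shuffle; class proportions per fold are within ±1 instance. Features
are z-scored on each training fold only (unstated historically but required
for SVM/MLP numerical stability; configurable by evaluating the raw table).
Classifiers: SVM with 3rd-degree polynomial kernel; MLP with one hidden
layer of round((inputs+classes)/2) units, SGD, learning rate 0.2, momentum
0.8, at most 500 epochs with seeded initialization; AdaBoost-M1 with 10
rounds over either base. The M1 combiner is implemented here with weighted
resampling so it accepts base learners without sample-weight support (the
MLP); rounds stop early on a perfect or worse-than-chance learner. Metrics
are computed on the pooled held-out predictions: recognition rate =
trace/total of the pooled confusion matrix, TP/TN rates are the recalls of
the second/first class in sorted label order (macro recall beyond two
classes), and AUC comes from pooled continuous scores (decision function or
positive-class probability; softmaxed one-vs-rest beyond two classes).

## Synthetic textures

The generator emulates the contrasts the method exploits in tissue:
echogenicity (mean level), granularity (correlation length) and regularity.
`periodic` is a sinusoidal grating (amplitude 40 grey levels, random
orientation/phase per seed) plus Gaussian noise; `smooth` is a
Gaussian-filtered noise field centred and rescaled to the requested sigma;
`chaotic` is i.i.d. noise with 2×2 bright/dark spots (±80) at a given rate
per 1000 px. An optional unit-mean log-normal factor (σ = 0.1) imitates
multiplicative speckle; it is off in unit tests and on in the stock
dataset. Images are clipped to [0, 255]; the mean stays within ±5 of the
requested level. Per-image seeds derive from the master seed through a
SeedSequence, so datasets are byte-identical across runs.

The stock two-class dataset (darker periodic "regular" at mean 90 vs
brighter chaotic at mean 150, Δmean 60, speckle on) is intentionally
well-separated; passing the end-to-end tests shows the pipeline is wired
correctly and that its components behave as designed, *not* that comparable
accuracy would be reached on clinical ultrasound, where class overlap,
acquisition variability and speckle statistics are far harder. Properties
that do transfer qualitatively: maximum probability decreasing with matrix
order, and regular textures showing higher maximum probability / lower
entropy than chaotic ones.

## Problem sizes and numerics

The demonstration study uses 100 ROIs per class at 50×50 (the benchmark ROI
size) with full 256-level quantization; the oracle-equivalence tests use
maps up to 12×12 with ≤8 levels, where exhaustive enumeration is exact and
cheap. Normalization tolerance is 1e−12 on probability sums; correlation is
zeroed below 1e−24 marginal variance; the averaging filter rounds half-up on
exact integer sums. Ties in the IG ranking break by column order for
determinism.

## Known limitations

- The fast recursive computation algorithm for higher-order matrices is not
  implemented; direct sparse counting is exact and fast enough at 50×50.
- No DICOM ingestion, despeckling filters, or acquisition modelling.
- The autocorrelation index sometimes reported alongside these features has
  no published formula and is omitted.
- AUC beyond two classes relies on softmaxed decision values for
  margin-only classifiers; probability calibration is out of scope.
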