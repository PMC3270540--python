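# cooctex

Higher-order cooccurrence texture analysis for greyscale images, aimed at
tissue-texture characterization in B-mode ultrasound: grey-level cooccurrence
matrices (GLCM) and edge-orientation cooccurrence matrices (EOCM) of orders
2, 3 and 5 with extended Haralick features, classical texture descriptors,
relevant-feature selection and stratified cross-validated classification.

## Who it is for

Researchers building texture-based tissue classifiers from rectangular
regions of interest (ROIs) of 8-bit greyscale images — e.g. separating a
malignant tumor's chaotic, inhomogeneous texture from the more regular
texture of surrounding parenchyma or benign lesions — and anyone who needs a
tested n-th order cooccurrence engine.

## The model

The order-*n* GLCM counts pixel *n*-tuples with grey levels
(g₁, …, gₙ) whose positions satisfy a displacement relation: the anchor
(x₁, y₁) sits centrally and each partner obeys

|x_{i+1} − x₁| = |dx_i|, |y_{i+1} − y₁| = |dy_i|,
sgn((x_{i+1} − x₁)(y_{i+1} − y₁)) = sgn(dx_i·dy_i),

so axis-aligned vectors count both ± placements and diagonal vectors the two
sign-consistent ones. Standard geometries: order 2 uses the four classical
directions (0°, 45°, 90°, 135°); order 3 uses four collinear direction pairs
plus eight right-angle pairs with components in {0, ±2}; order 5 uses the
groups (0°, 180°, 90°, 270°) and (45°, 225°, 135°, 315°). Counts are
normalized to probabilities p(g₁, …, gₙ) and summarized by extended Haralick
statistics — energy Σp², entropy −Σp·ln p, contrast and local homogeneity
through the mean pairwise squared level difference, correlation through
positional marginals, variance, and the maximum probability max p, which is
high for regular textures and low for chaotic ones and decreases with matrix
order. The EOCM applies the same counting to Sobel edge orientations
(integer degrees folded into [0°, 180°)), restricted to edge pixels.

Around this core the pipeline computes the classical "old" features (mean
grey level, Laws microstructure frequency/density, two-level Haar-wavelet
Shannon entropies, edge/gradient statistics, edge-orientation variability),
selects relevant features as the union of a CFS subset — merit
k·r̄_cf / √(k + k(k−1)·r̄_ff) on symmetrical-uncertainty correlations,
maximized by a seeded genetic search — with the top information-gain
attributes, and evaluates SVM (poly-3), MLP and AdaBoost-M1 combinations
under stratified 5-fold cross-validation.

## Worked example

```python
from cooctex import (RunConfig, TextureRecipe, compute_feature_vector,
                     generate_roi, mean_filter)

regular = generate_roi(TextureRecipe("regular", 120, 8.0, "periodic", 0.0, 5.0, seed=3), 50)
chaotic = generate_roi(TextureRecipe("chaotic", 120, 1.0, "chaotic", 8.0, 40.0, seed=4), 50)
for name, img in (("regular", regular), ("chaotic", chaotic)):
    f = compute_feature_vector(mean_filter(img), RunConfig())
    print(name,
          "mean_grey=%.1f" % f["mean_grey"],
          "glcm2_mp=%.4f" % f["glcm2_avg_max_probability"],
          "glcm3_mp=%.5f" % f["glcm3_avg_max_probability"],
          "glcm5_mp=%.5f" % f["glcm5_0_180_90_270_max_probability"],
          "glcm2_ent=%.2f" % f["glcm2_avg_entropy"],
          "eov=%.1f" % f["edge_orientation_variability"])
```

prints

```
regular mean_grey=120.1 glcm2_mp=0.0038 glcm3_mp=0.00123 glcm5_mp=0.00076 glcm2_ent=6.80 eov=23.1
chaotic mean_grey=119.9 glcm2_mp=0.0025 glcm3_mp=0.00072 glcm5_mp=0.00045 glcm2_ent=7.50 eov=80.4
```

Both textures share the same echogenicity (mean grey ≈ 120), but the regular
grating has the higher maximum probability at every order, the lower
cooccurrence entropy, and a tight edge-orientation distribution (23° angular
deviation vs 80° for the chaotic texture). In both cases the maximum
probability falls as the matrix order rises — higher orders probe rarer,
more specific level combinations.

## Command line

```bash
cooctex synth    --out-dir data --seed 5 --n-per-class 50
cooctex extract  --manifest data/manifest.csv --out features.csv
cooctex select   --features features.csv --out selection.json
cooctex evaluate --features features.csv --selection selection.json \
                 --out report.json --summary-csv summary.csv
cooctex model    --features features.csv --selection selection.json --out model.json
```

All stages are deterministic under fixed seeds; configuration (quantization
levels, direction modes, GA and cross-validation settings) comes from a YAML
file passed via `--config`.

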