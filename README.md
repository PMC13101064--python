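# mpmtex

Classification of label-free multiphoton microscopy (MPM) images of
pancreatic neuroendocrine neoplasms (PNENs) versus normal pancreas using
handcrafted texture features. The package implements the full analysis
pipeline — synthetic tissue-phantom generation, mosaic preprocessing,
GLCM/Haralick feature extraction, statistical screening, and exhaustive
subset-wise Fisher LDA with leave-one-out cross-validation — for
researchers developing automated digital-pathology methods on MPM data.

## The problem and the method

PNEN resection relies on histopathological margin assessment; label-free
MPM (autofluorescence channels NADH, FAD, lipofuscin, porphyrin plus the
second-harmonic-generation (SHG) collagen channel) is a candidate for
automating it. Samples come in two preparations, FFPE and fixed-frozen;
the NADH channel is unusable for fixed-frozen samples (mounting-medium
fluorescence) and is excluded whenever they are analyzed.

Each sample is acquired as a 13×13 grid of 256×256 16-bit tiles with 10%
overlap and five z-slices. Tiles are flat-field corrected, stitched at
known grid positions, and max-projected into a 3016×3016 mosaic per
channel. Per channel image, the gray-level co-occurrence matrix (GLCM)

&nbsp;&nbsp;&nbsp;&nbsp;p(i, j) = Pr[gray levels i, j at pixel distance 1],

accumulated symmetrically and averaged over the four angular directions,
yields the 13 Haralick statistics f1…f13 (energy, contrast, correlation,
variance, entropies, information measures of correlation, …), named like
`SHG 06`. Features are screened by mean absolute Pearson correlation
(retain mean |r| < 0.45), compared between classes with Shapiro-Wilk-gated
Welch t / Mann-Whitney U tests under Benjamini-Hochberg adjustment, and fed
to Fisher's linear discriminant

&nbsp;&nbsp;&nbsp;&nbsp;w = Σ⁻¹(µ₁ − µ₀),&nbsp;&nbsp;threshold at the projected-midpoint,

evaluated by leave-one-out cross-validation over **every** subset of
n = 1…n_max features, 100 runs per n (randomness enters only through
uniform tie-breaking among equally scoring subsets). Outputs are selection
frequencies, accuracy mean ± sd per n, per-sample misclassification
counts, and pooled-score ROC/AUC.

Because the study's patient images are not public, the package ships a
first-class synthetic-data module that emulates the cohort (27/21 FFPE
tumor/normal + 7/7 fixed-frozen), the acquisition geometry, and the two
dominant contrasts: denser/brighter SHG collagen in tumors, and globally
brighter fixed-frozen samples.

## Worked example

```python
from mpmtex import (CohortDesign, GridSpec, PhantomParams, SubsetSearchConfig,
                    build_feature_table, correlation_filter, generate_cohort,
                    repeated_selection)

design = CohortDesign(grid=GridSpec(2, 2, 128, 0.10), n_z=2)  # scaled geometry
params = PhantomParams(tumor_blob_sigma_mult=1.0)             # SHG-only signal
cohort = generate_cohort(design, params, seed=1)              # 62 samples
table = build_feature_table(cohort, ("FAD", "Lipofuscin", "Porphyrin", "SHG"))
reduced = correlation_filter(table, threshold=0.45, max_features=12)
summary = repeated_selection(reduced, SubsetSearchConfig(n_max=3, runs=100, seed=1))
for n, r in summary.by_n.items():
    shg = sum(v for f, v in r.selection_counts.items() if f.startswith("SHG"))
    print(f"n={n}  accuracy {100*r.accuracy_mean:.1f}±{100*r.accuracy_sd:.1f}%  "
          f"AUC {r.auc:.3f}  SHG selections {shg}/{sum(r.selection_counts.values())}")
```

prints

```
n=1  accuracy 95.2±0.0%  AUC 0.972  SHG selections 100/100
n=2  accuracy 98.4±0.0%  AUC 0.998  SHG selections 190/200
n=3  accuracy 100.0±0.0%  AUC 1.000  SHG selections 200/300
```

i.e. on a cohort whose only class signal is SHG fiber density/brightness,
the exhaustive search recovers SHG-channel features (490/600 = 82% of all
selections) and classifies essentially perfectly by n = 3; the zero
standard deviations mean the best subset at each n was unique, so the 100
runs agree exactly.

The same pipeline runs end-to-end from a shell:

```sh
mpmtex all --arm combined --seed 1 --out run1 --nmax 3 --runs 100 --max-features 12
```

writing `features.csv`, `brightness.csv`, `significance.csv`,
`selection_counts.csv`, `accuracy.csv`, `misclassification.csv`,
`roc_<n>.csv`, `auc.csv` and a reproducibility manifest under `run1/`.

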