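# histo3c

Low-dimensional three-channel features for benign/malignant
histopathology image classification.

Classical texture descriptors for H&E-stained breast-tumor micrographs
are usually computed on a grayscale conversion, which throws away the
chroma structure of the stain: hematoxylin renders nuclei blue-purple
while eosin renders cytoplasm and matrix pink, so a substantial part of
the diagnostic signal lives in *hue*, not luminance. `histo3c` extracts
ten classical texture/shape/color descriptors from **each RGB channel
separately** and fuses them by cascade concatenation, then evaluates
them with an RBF-kernel SVM under a strictly patient-disjoint protocol
at both the image level and the patient level.

## Descriptors

| Name | Per-channel dim | What it measures |
|---|---|---|
| GLCM1 | 22 | Haralick statistics of the 256-level co-occurrence matrix, 0° offset |
| GLCM4 | 88 | the same 22 statistics at 0°, 45°, 90°, 135° |
| APVEC | 1 | mean pixel value of the channel, f̄ = (1/MN) Σ f(x, y) |
| HIM | 7 | Hu invariant moments (signed log scale) |
| Wavelet | 5 | detail-subband energies of a 5-level coif5 decomposition |
| Tamura | 6 | coarseness, contrast, directionality, line-likeness, regularity, roughness |
| LBP | 256 | histogram of 3×3-window local binary patterns (P=8, R=1) |
| CLBP | 20 | completed LBP: riu2 histograms of the sign and magnitude components |
| Gabor | 4000 | mean response magnitude of a 5-scale × 8-orientation bank over a 46×70-pixel block grid |
| Hog | 288 | 4×8-cell, 9-bin unsigned gradient-orientation histogram, globally L2-normalized |

Under the three-channel (`rgb`) mode the per-channel vectors are
concatenated in R, G, B order (3× the dimension); `gray`, `R`, `G`, `B`
modes return a single channel's vector.

## Evaluation protocol

Patients — never images — are split 70/30 (stratified by class), so no
patient contributes to both the training and the test set. An SVM with
RBF kernel (penalty *c* = 2, kernel parameter *g* = 1) is trained on
min–max-scaled features (scaling fit on training rows only). Five
trials redraw the split; results are reported as mean ± sample std of

* image-level accuracy  N_correct / N,
* patient-level accuracy  mean over patients of each patient's per-image
  correct fraction,
* sensitivity TP/(TP+FN), precision TP/(TP+FP), F1 = 2TP/(2TP+FP+FN)
  (malignant = positive class).

## Synthetic data

`histo3c.synthetic_histology` generates seeded, patient-grouped
H&E-like images (pink eosin background; benign: sparse, large,
low-contrast elliptical nuclei; malignant: dense, small, high-contrast
blue-purple nuclei), with per-patient stain/density offsets and a
`chroma_effect` knob that moves the class signal from luminance into a
luma-orthogonal hue shift. It writes a `class/subclass/patient/
magnification` tree with BreaKHis-convention filenames
(`SOB_B_TA-14-1000-200-001.png`) plus a CSV manifest, so the whole
pipeline runs without any external dataset.

## Worked example

```python
from histo3c.synthetic_histology import SynthConfig, generate_dataset
from histo3c.fusion_registry import extract_table
from histo3c.evaluation import run_experiment, report_markdown

cfg = SynthConfig(seed=0)  # 6 benign + 14 malignant patients, 10 images each, 200X
dataset = generate_dataset(cfg)
table = extract_table(dataset, "GLCM1", "rgb")   # 66-D fused Haralick features
report = run_experiment(table, n_trials=5, seed=0)
print(report_markdown(report, "GLCM1", "rgb"))
```

prints

```
### GLCM1 (rgb)

| Magnification | image_accuracy | patient_accuracy | sensitivity | precision | f1 |
|---|---|---|---|---|---|
| 200X | 97.33 ± 5.08 | 97.33 ± 5.08 | 100.00 ± 0.00 | 96.53 ± 6.47 | 98.14 ± 3.50 |
```

i.e. on the default synthetic conditions the fused 66-D GLCM descriptor
classifies 97.3 % of held-out-patient images correctly, averaged over
five split redraws; sensitivity 100 % means no malignant test image was
missed in any trial. With the class signal pushed into hue
(`chroma_demo_config()`), the 3-D `rgb` APVEC descriptor stays near
100 % while its grayscale counterpart collapses to the majority-class
rate — the three-channel-vs-gray contrast the package exists to measure.

The same pipeline runs from the shell:

```
histo3c simulate --out data --seed 0
histo3c extract --manifest data/manifest.csv --descriptor GLCM1 --mode rgb --out glcm1.csv
histo3c train-eval --features glcm1.csv --trials 5 --seed 0
```

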