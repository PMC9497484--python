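# skewotsu

Global binary thresholding for grayscale images whose intensity
histograms are **right-skewed** — the regime (common in MRI brain-tumor
slices, ultrasound and SAR imagery) where the classical Otsu method,
which implicitly assumes symmetric class distributions, misplaces the
cut.

The package implements three threshold-selection objectives over the
256-bin gray-level histogram, each maximized by a sequential scan over
all candidate thresholds `t` (smallest maximizer wins):

- **`otsu_gaussian`** — the classical Otsu between-class variance

  σ²(t) = P₀(t)·(μ₀(t) − μ_T)² + P_b(t)·(μ_b(t) − μ_T)²,

  computed in its one-pass rational form
  (μ_T·P₀ − μ₀,cum)² / (P₀(1 − P₀));

- **`otsu_lognormal`** — the same between-class variance computed on
  **log-intensities**: class means μ₀,log, μ_b,log and total mean
  μ_T,log are count-weighted means of λ(i) = log(i + 1), so

  σ²_LN(t) = P₀·(μ₀,log − μ_T,log)² + P_b·(μ_b,log − μ_T,log)².

  If pixel intensities are lognormal within each class, their logs are
  normal, and this objective is exactly the Otsu criterion on the scale
  where the class model holds;

- **`otsu_modified`** — a baseline from the literature that plugs the
  lognormal (log-scale) means into the rational Gaussian-form
  objective while keeping plain class probabilities. (As reconstructed
  here this is algebraically the same quantity as `otsu_lognormal`,
  computed by a different route; see `docs/methods.md`.)

Around the estimators: the five standard segmentation quality scores
(unsupervised image uniformity and region contrast; supervised Jaccard,
F-score and pixel accuracy), a batch comparison pipeline with
per-method averages and increase rates, and a seeded generator of
synthetic two-region images with lognormal mixture intensities and
exact ground-truth masks, so every claim is testable without any
external dataset.

## Worked example

```python
import skewotsu as so

sample = so.generate_image(so.HIGH_SKEW_TEMPLATE)   # 256x256, disk on skewed background
res = so.ThresholdModel(sample.image, method="otsu_lognormal").fit()
print(res.summary())
```

```
Threshold selection results
=============================================
method                    otsu_lognormal
log map                   shift1
threshold t*              34
objective at t*           0.523748
P(object), P(background)  0.6126, 0.3874
class means (mu_o, mu_b)  17.50, 82.90
total mean mu_T           42.84
between/within/total var  1015.3 / 810.3 / 1825.6
degenerate                False
object pixel fraction     0.3874
```

The fitted threshold 34 cuts the long background tail off the bright
disk. Scoring against the exact ground truth:

```python
rep = res.evaluate(truth=sample.truth)
# IU=0.9362 RC=0.6515 Jaccard=0.7207 F=0.8377 acc=0.8884
```

The classical Gaussian objective on the same image picks t\* = 70 —
pulled up into the object by the background's heavy right tail — and
drops to Jaccard 0.5972, accuracy 0.8756.

Batch comparison from the shell:

```sh
skewotsu simulate --n 50 --seed 1 --out data/
skewotsu compare --input data/ --out report/
skewotsu segment data/images/img_0000.png --method lognormal
```

`report/` then holds per-image scores (CSV), per-method averages and
increase rates versus the Gaussian baseline (JSON/CSV).

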