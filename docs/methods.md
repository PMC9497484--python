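# Methods

## Model

A gray image with levels `i = 0..L-1` (L = 256 throughout, carried
explicitly so tiny alphabets can be tested exhaustively) is summarized
by its histogram counts `n_i` and probabilities `P_i = n_i / n`. A
threshold `t` splits the levels into an object class `{0..t}` with mass
`P0(t)` and a background class `{t+1..L-1}` with mass `Pb(t)`; the
produced binary mask marks pixels **above** `t` (`--invert` flips
this). For every `t` the class means, class variances and the
between/within/total variance decomposition are computed from
cumulative moments; the identities `P0 + Pb = 1`,
`P0·mu_o + Pb·mu_b = mu_T` and `var_between + var_within = var_total`
are enforced by tests at every threshold.

The classical Otsu rule maximizes the between-class variance over `t`.
Its implicit model is symmetric (Gaussian-like) class distributions:
the arithmetic class means then characterize class location well. Many
biomedical images instead have right-skewed, lognormal-like intensity
classes. If `X` is lognormal, `log X` is normal, so the natural fix is
to run the same between-class-variance machinery on the log scale. The
log-domain objective used here is

    sigma2_LN(t) = P0(t) (mu_o,log(t) - mu_T,log)^2
                 + Pb(t) (mu_b,log(t) - mu_T,log)^2

where the class log-means are count-weighted means of the log-intensity
map `lambda(i)`. This is exactly the Gaussian Otsu objective applied to
the monotonically relabeled bin values `lambda(i)` — a fact the test
suite uses as the central independent oracle (an explicit slow scan
over relabeled bins must reproduce the production curve and its
argmax).

### Log-intensity map

The log of gray level 0 is undefined, so the default map is
`lambda(i) = log(i + 1)` (`log-map: shift1`): monotone, defined on the
whole range, and a bounded shift of `log i` for `i >= 1`. The
alternative `skip-zero` map uses `log(i)` and excludes bin 0 from every
log-mean sum (bin 0 still counts toward the class probabilities). The
two maps differ only when the image actually contains level 0; both are
exposed because neither convention is canonical.

### The "modified Otsu" baseline

The baseline reconstructed here replaces the arithmetic means inside
the rational Otsu form with log-scale means while keeping plain class
probabilities:

    (mu_T,log w(t) - M_log(t))^2 / (w(t)(1 - w(t))),
    M_log(t) = sum_{i<=t} P_i lambda(i).

Because `M_log = P0 mu_o,log` and the log-means satisfy the same
weighted-mean decomposition as the arithmetic ones, this rational form
is algebraically identical to the two-term log-domain objective above
(under `shift1`; with `skip-zero` and mass at bin 0 the class
probabilities and log weights diverge and the identity no longer
holds). The two methods are therefore distinct computational routes to
the same threshold on default settings, and the suite asserts their
numerical agreement to 1e-9 relative / 1e-12 absolute. They are kept as
separate named methods because they are distinct procedures in the
literature this package compares.

### Numerical choices

- Probabilities and moments in double precision from integer counts;
  the one-pass rational forms are the production path, the explicit
  two-term direct sums the cross-check.
- Degeneracy (one class empty) is decided from **integer** cumulative
  counts, never from floating cumulative probabilities: at the last
  bin `w = 1` only up to rounding, and dividing the squared-difference
  numerator by `w(1-w) ~ 1e-16` would amplify cancellation noise into
  spurious positive objective values. Degenerate thresholds score
  exactly 0, keeping every curve total, finite and non-negative.
- Argmax ties break to the smallest `t` (`np.argmax` semantics),
  matching a sequential upward scan and making reruns deterministic.
  Two independent computational routes can disagree about an argmax
  index when maxima tie within rounding; oracle tests therefore treat
  maxima within 1e-9 relative as tied.
- A constant image yields `t* = 0`, an all-false mask, a flat zero
  curve, a degeneracy flag and a warning.

## Evaluation metrics

Unsupervised (no ground truth):

- **Image uniformity** `IU = 1 - (sigma1^2 + sigma2^2)/Z` with the two
  thresholded regions' intensity variances and
  `Z = (Imax - Imin)^2 / 2` over the image's observed range
  (`--z-range nominal` uses `(L-1)^2/2`). A region variance of values
  confined to the observed range is at most `(Imax-Imin)^2/4 = Z/2`,
  so IU stays in [0, 1]. A constant image (Z = 0) is defined perfectly
  uniform, IU = 1, flagged. IU is invariant under adding a constant to
  all intensities (both numerator and observed-range Z are unchanged).
- **Region contrast** `RC = |mu1 - mu2| / (mu1 + mu2)` from the two
  region means (the Levine–Nazif contrast). It is *not* shift
  invariant. Empty regions or an all-zero image score 0, flagged.

Supervised, from pixelwise confusion counts against the ground truth:
Jaccard `TP/(TP+FP+FN)`, F-score `2PR/(P+R)`, accuracy
`(TP+TN)/total`. Zero denominators score 0 with a flag, so batch
aggregation never propagates NaN; `J = F/(2-F)` whenever TP > 0, hence
`J <= F` always. Per-image family summaries are arithmetic means of
the family's scores (the combination rule is stated because it is a
choice, not a given).

## Synthetic study conditions

The generator draws each region's pixels i.i.d. from its own lognormal
distribution on a 256 × 256 grid (object = centered disk covering 30%
of pixels by default), rounds and clamps to [1, 255] (positive support;
the clamped fraction is recorded in the manifest and stays below 1% for
the bundled templates), and returns the exact region-membership mask as
ground truth. Dataset generation jitters mode locations by ±0.1 (log
scale), sigmas by +[0, 0.05] (one-sided, so template skewness is a
floor) and the disk center by ±10 px, with per-image child seeds from
one master seed; identical seeds give byte-identical images.

Two frozen templates define the study regimes:

- **high-skew** (the 50-image comparative study): object LN(4.4, 0.5)
  on background LN(2.9, 0.6). Both modes strongly right-skewed
  (sigma >= 0.5) and overlapping — the failure regime of the
  symmetric-model objective, where the background's heavy right tail
  drags the Gaussian threshold upward into the object. The object
  location is set so the 255-clamp stays under the 1% budget.
- **well-separated** (threshold-placement control): object LN(5.0,
  0.15) on background LN(3.0, 0.15); essentially disjoint supports.

On well-separated mixtures the pixel-misclassification curve has a
flat minimal valley across the inter-mode gap (often exact count
ties), so "the optimal threshold" is a set; threshold-placement tests
measure the distance from `t*` to the **nearest** minimizer and
require it to be at most 2 gray levels.

What these images do not emulate: spatial noise correlation,
partial-volume boundary voxels, MRI bias fields, Rician noise, or
multiple objects per image. Passing results demonstrate correct
behavior under the stated distributional assumptions, not clinical
segmentation performance.

## Comparison pipeline

Each method's threshold comes solely from its own objective; the
evaluation scores compare methods post hoc (model selection), never
feed back into threshold selection — the alternative reading (picking
`t` by supervised score) would require ground truth at threshold time
and defeat the point of unsupervised thresholding. Per-method averages
are arithmetic means of per-image scores; increase rates are
`100·(avg_method − avg_baseline)/avg_baseline` with the classical
Gaussian Otsu as baseline. `best_method_select` returns the method
with the highest mean over all selected metric scores, ties broken in
canonical order (gaussian, modified, lognormal) — note that on default
settings the modified and lognormal routes tie exactly (see above), so
a three-way selection returns `otsu_modified` by tie-break; head-to-head
comparisons should name the two methods of interest. Parallel execution
(joblib) preserves input order, so reports are identical for any worker
count.

## Problem sizes

The bundled studies use 50 images (comparative) and 20 images
(threshold placement) at 256 × 256, plus 100-histogram oracle sweeps
and an exhaustive scan of every 6-pixel histogram over an 8-level
alphabet; the full suite and the acceptance script each run in well
under a minute on one CPU.

## Known limitations

- Two classes only; no multilevel or locally adaptive thresholding.
- 8-bit single-channel images only; no color, 16-bit or float input.
- The lognormal objective uses fixed log-spaced bin values, not a
  fitted mixture: no EM estimation of mode parameters is performed (or
  needed — the objective is distribution-motivated, not
  likelihood-based).
- RC compares only the two global regions; no adjacency analysis.
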