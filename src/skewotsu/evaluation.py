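"""Segmentation quality metrics.

Two unsupervised scores computed from the image and its threshold —
image uniformity (IU) and region contrast (RC) — and three supervised
scores computed from pixelwise confusion counts against a ground-truth
mask: Jaccard index, F-score and accuracy.  All five lie in [0, 1].

Degenerate situations (constant image, empty region, zero overlap)
return the documented convention value together with a flag, never NaN,
so batch aggregation stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import numpy.typing as npt

from .thresholding import BinaryMask

__all__ = [
    "ConfusionCounts",
    "SupervisedScores",
    "MetricResult",
    "EvalReport",
    "confusion",
    "supervised_scores",
    "image_uniformity",
    "region_contrast",
    "evaluate_segmentation",
    "SUPERVISED_METRICS",
    "UNSUPERVISED_METRICS",
]

SUPERVISED_METRICS = ("jaccard", "fscore", "accuracy")
UNSUPERVISED_METRICS = ("iu", "rc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise 2x2 contingency counts (prediction vs reference)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _pixels(mask: BinaryMask | npt.NDArray) -> npt.NDArray[np.bool_]:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def confusion(mask: BinaryMask | npt.NDArray, truth: BinaryMask | npt.NDArray) -> ConfusionCounts:
    """Confusion counts of a predicted mask against a reference mask."""
    pred = _pixels(mask)
    ref = _pixels(truth)
    if pred.shape != ref.shape:
        raise ValueError(f"dimension mismatch: mask {pred.shape} vs truth {ref.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


class SupervisedScores(NamedTuple):
    jaccard: float
    fscore: float
    accuracy: float
    precision: float
    recall: float
    flags: frozenset[str]

    def __iter3__(self):  # pragma: no cover - documentation helper
        return (self.jaccard, self.fscore, self.accuracy)


def supervised_scores(c: ConfusionCounts) -> SupervisedScores:
    """Jaccard, F-score and accuracy from confusion counts.

    Jaccard = TP/(TP+FP+FN); F = 2PR/(P+R) with precision P = TP/(TP+FP)
    and recall R = TP/(TP+FN); accuracy = (TP+TN)/total.  Zero
    denominators score 0 and are flagged.
    """
    if c.total == 0:
        raise ValueError("empty comparison")
    flags: set[str] = set()

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.add(f"zero-denominator:{name}")
            return 0.0
        return num / den

    jac = _ratio(c.tp, c.tp + c.fp + c.fn, "jaccard")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    rec = _ratio(c.tp, c.tp + c.fn, "recall")
    if prec + rec == 0.0:
        flags.add("zero-denominator:fscore")
        f = 0.0
    else:
        f = 2.0 * prec * rec / (prec + rec)
    acc = (c.tp + c.tn) / c.total
    return SupervisedScores(jac, f, acc, prec, rec, frozenset(flags))


class MetricResult(NamedTuple):
    value: float
    flags: frozenset[str]


def _regions(image: npt.NDArray, t: int):
    arr = np.asarray(image)
    low = arr[arr <= t].astype(float)
    high = arr[arr > t].astype(float)
    return arr, low, high


def image_uniformity(image: npt.NDArray, t: int, z_range: str = "observed", levels: int = 256) -> MetricResult:
    """Image uniformity: IU = 1 - (sigma1^2 + sigma2^2)/Z.

    sigma1^2, sigma2^2 are the intensity variances of the two
    thresholded regions and Z = (Imax - Imin)^2 / 2 normalizes by the
    image's observed dynamic range (``z_range='nominal'`` uses the full
    gray range (L-1)^2/2 instead).  A constant image has Z = 0 and is
    defined to be perfectly uniform (IU = 1, flagged).  Region variances
    of bounded data never exceed Z/2 each, so IU stays in [0, 1].
    """
    arr, low, high = _regions(image, t)
    flags: set[str] = set()
    if z_range == "nominal":
        z = (levels - 1) ** 2 / 2.0
    else:
        z = (float(arr.max()) - float(arr.min())) ** 2 / 2.0
    if z == 0.0:
        return MetricResult(1.0, frozenset({"constant-image"}))
    var1 = float(np.var(low)) if low.size else 0.0
    var2 = float(np.var(high)) if high.size else 0.0
    if low.size == 0 or high.size == 0:
        flags.add("empty-region")
    return MetricResult(1.0 - (var1 + var2) / z, frozenset(flags))


def region_contrast(image: npt.NDArray, t: int) -> MetricResult:
    """Region contrast: RC = |mu1 - mu2| / (mu1 + mu2).

    mu1, mu2 are the mean intensities of the two thresholded regions;
    0 means the regions are indistinguishable, 1 maximal contrast.
    Empty regions or an all-zero image score 0, flagged.
    """
    _, low, high = _regions(image, t)
    if low.size == 0 or high.size == 0:
        return MetricResult(0.0, frozenset({"empty-region"}))
    mu1, mu2 = float(low.mean()), float(high.mean())
    if mu1 + mu2 == 0.0:
        return MetricResult(0.0, frozenset({"zero-means"}))
    return MetricResult(abs(mu1 - mu2) / (mu1 + mu2), frozenset())


@dataclass(frozen=True)
class EvalReport:
    """Five metric values for one (image, method) pair; None = not computed."""

    iu: float | None = None
    rc: float | None = None
    jaccard: float | None = None
    fscore: float | None = None
    accuracy: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in (*UNSUPERVISED_METRICS, *SUPERVISED_METRICS):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def supervised_mean(self) -> float | None:
        """Mean of Jaccard, F-score, accuracy (the per-image supervised summary)."""
        vals = [getattr(self, m) for m in SUPERVISED_METRICS]
        return None if any(v is None for v in vals) else float(np.mean(vals))

    @property
    def unsupervised_mean(self) -> float | None:
        """Mean of IU and RC (the per-image unsupervised summary)."""
        vals = [getattr(self, m) for m in UNSUPERVISED_METRICS]
        return None if any(v is None for v in vals) else float(np.mean(vals))

    def to_row(self) -> dict:
        return {
            "iu": self.iu,
            "rc": self.rc,
            "jaccard": self.jaccard,
            "fscore": self.fscore,
            "accuracy": self.accuracy,
            "flags": ";".join(sorted(self.flags)),
        }


def evaluate_segmentation(
    image: npt.NDArray,
    t: int,
    mask: BinaryMask | npt.NDArray | None = None,
    truth: BinaryMask | npt.NDArray | None = None,
    metrics: tuple[str, ...] = ("unsupervised", "supervised"),
    z_range: str = "observed",
    levels: int = 256,
) -> EvalReport:
    """Full metric report for one segmentation.

    Unsupervised scores need only the image and threshold; supervised
    scores additionally need the predicted mask and the ground truth.
    """
    flags: set[str] = set()
    iu = rc = jac = f = acc = None
    if "unsupervised" in metrics:
        r = image_uniformity(image, t, z_range=z_range, levels=levels)
        iu, fl = r.value, r.flags
        flags |= fl
        r = region_contrast(image, t)
        rc = r.value
        flags |= r.flags
    if "supervised" in metrics:
        if truth is None:
            raise ValueError("supervised metrics requested but no ground truth given")
        pred = _pixels(mask) if mask is not None else np.asarray(image) > t
        s = supervised_scores(confusion(pred, truth))
        jac, f, acc = s.jaccard, s.fscore, s.accuracy
        flags |= s.flags
    return EvalReport(iu=iu, rc=rc, jaccard=jac, fscore=f, accuracy=acc, flags=frozenset(flags))
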