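"""Threshold-selection objectives and the argmax search.

Three objectives are implemented, all functionals of the gray-level
histogram, each scanned over every candidate threshold ``t`` in
``[0, L-1]`` with the smallest maximizer taken as ``t*``:

``otsu_gaussian``
    The classical Otsu between-class variance.  The production path is
    the rational one-pass form

        sigma^2(t) = (mu_T w(t) - m(t))^2 / (w(t) (1 - w(t)))

    with ``w`` and ``m`` the zeroth/first cumulative moments; it equals
    the explicit two-term form
    ``Po (mu_o - mu_T)^2 + Pb (mu_b - mu_T)^2`` wherever both classes
    are non-empty.

``otsu_modified``
    The lognormal-mean baseline: the same rational Otsu form, but with
    the ordinary class means replaced by class means of log-intensity.
    Class probabilities stay the plain histogram masses.

``otsu_lognormal``
    The between-class variance of log-intensities

        sigma^2_LN(t) = Po (mu_o,log - mu_T,log)^2
                        + Pb (mu_b,log - mu_T,log)^2

    computed in its explicit two-term form.  Because intensities are
    assumed lognormal, their logs are the natural (normal) scale on
    which a between-class variance is meaningful for right-skewed
    histograms.

Log-intensity map: gray level 0 has no logarithm, so the default map is
``lambda(i) = log(i + 1)`` (monotone, defined everywhere).  The
alternative ``skip-zero`` map uses ``log(i)`` and excludes bin 0 from
the log-mean sums.

Degenerate thresholds (one class empty) always score 0, so curves are
total, finite and non-negative over the full gray range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import numpy.typing as npt

from .histogram import Histogram, compute_histogram

__all__ = [
    "METHODS",
    "LogMeans",
    "ThresholdCurve",
    "BinaryMask",
    "SegmentationResult",
    "log_bin_values",
    "log_means",
    "otsu_gaussian_curve",
    "otsu_modified_curve",
    "otsu_lognormal_curve",
    "between_class_curve_explicit",
    "threshold_curve",
    "threshold_image",
    "save_mask",
]

METHODS = ("otsu_gaussian", "otsu_modified", "otsu_lognormal")
LogMap = Literal["shift1", "skip-zero"]

_EPS = np.finfo(float).tiny


def log_bin_values(levels: int, log_map: LogMap = "shift1") -> tuple[npt.NDArray, npt.NDArray]:
    """Log-intensity value and inclusion weight for every bin.

    Returns ``(lam, include)``: ``lam[i]`` is the log-intensity assigned
    to gray level i, and ``include[i]`` is 1.0 where the bin takes part
    in log-mean sums (0.0 only for bin 0 under ``skip-zero``).
    """
    i = np.arange(levels, dtype=float)
    if log_map == "shift1":
        return np.log(i + 1.0), np.ones(levels)
    if log_map == "skip-zero":
        lam = np.zeros(levels)
        lam[1:] = np.log(i[1:])
        include = np.ones(levels)
        include[0] = 0.0
        return lam, include
    raise ValueError(f"unknown log map {log_map!r}")


@dataclass(frozen=True)
class LogMeans:
    """Class log-means at threshold ``t`` (object = bins 0..t)."""

    t: int
    mu_object_log: float
    mu_background_log: float
    mu_total_log: float
    degenerate: bool = False


def log_means(h: Histogram, t: int, log_map: LogMap = "shift1") -> LogMeans:
    """Count-weighted means of log-intensity for the two classes and overall.

    ``mu_object_log(t) = sum_{i<=t} h_i lambda(i) / sum_{i<=t} h_i`` and
    analogously for the background and the whole histogram.  Empty
    classes yield 0 with the degenerate flag set.
    """
    if not 0 <= t <= h.levels - 1:
        raise ValueError(f"threshold {t} outside [0, {h.levels - 1}]")
    lam, include = log_bin_values(h.levels, log_map)
    w = h.p * include
    num = w * lam

    def _mean(sl: slice) -> tuple[float, bool]:
        denom = w[sl].sum()
        if denom <= 0.0:
            return 0.0, True
        return float(num[sl].sum() / denom), False

    mu_o, deg_o = _mean(slice(0, t + 1))
    mu_b, deg_b = _mean(slice(t + 1, None))
    mu_t, deg_t = _mean(slice(None))
    return LogMeans(int(t), mu_o, mu_b, mu_t, degenerate=deg_o or deg_b or deg_t)


@dataclass(frozen=True)
class ThresholdCurve:
    """Objective value per candidate threshold, for one method."""

    method: str
    values: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite objective value")
        object.__setattr__(self, "values", values)

    @property
    def t_star(self) -> int:
        """Smallest threshold attaining the maximal objective value."""
        return int(np.argmax(self.values))

    @property
    def degenerate(self) -> bool:
        """True when the objective is identically zero (e.g. constant image)."""
        return bool(np.all(self.values == 0.0))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"t": np.arange(self.values.size), "value": self.values}).to_csv(
            path, index=False
        )


def _nondegenerate(h: Histogram) -> npt.NDArray[np.bool_]:
    """True at t where both classes hold at least one pixel (by exact counts)."""
    cum = np.cumsum(h.counts)
    return (cum > 0) & (cum < h.n)


def _rational_curve(h: Histogram, v: npt.NDArray) -> npt.NDArray:
    """One-pass rational between-class variance for arbitrary bin values ``v``."""
    p = h.p
    w = np.cumsum(p)
    m = np.cumsum(v * p)
    den = w * (1.0 - w)
    vals = np.zeros_like(p)
    ok = _nondegenerate(h) & (den > _EPS)
    vals[ok] = (m[-1] * w[ok] - m[ok]) ** 2 / den[ok]
    return vals


def otsu_gaussian_curve(h: Histogram) -> ThresholdCurve:
    """Classical Otsu between-class variance for every threshold."""
    return ThresholdCurve("otsu_gaussian", _rational_curve(h, np.arange(h.levels, dtype=float)))


def otsu_modified_curve(h: Histogram, log_map: LogMap = "shift1") -> ThresholdCurve:
    """Lognormal-mean baseline: rational Otsu form over log-intensity bin values.

    ``values[t] = (mu_T,log w(t) - M_log(t))^2 / (w(t)(1 - w(t)))`` with
    ``M_log(t) = sum_{i<=t} P_i lambda(i)``; class probabilities remain
    the plain histogram masses.
    """
    lam, include = log_bin_values(h.levels, log_map)
    p = h.p
    w = np.cumsum(p)
    wl = p * include
    m = np.cumsum(wl * lam)
    sw = wl.sum()
    if sw <= 0.0:
        return ThresholdCurve("otsu_modified", np.zeros(h.levels))
    mu_t = m[-1] / sw
    den = w * (1.0 - w)
    vals = np.zeros(h.levels)
    ok = _nondegenerate(h) & (den > _EPS)
    vals[ok] = (mu_t * w[ok] - m[ok]) ** 2 / den[ok]
    return ThresholdCurve("otsu_modified", vals)


def otsu_lognormal_curve(h: Histogram, log_map: LogMap = "shift1") -> ThresholdCurve:
    """Between-class variance of log-intensities (the lognormal objective).

    Explicit two-term form ``Po (mu_o,log - mu_T,log)^2 +
    Pb (mu_b,log - mu_T,log)^2`` with class log-means; degenerate
    thresholds score 0.
    """
    lam, include = log_bin_values(h.levels, log_map)
    p = h.p
    po = np.cumsum(p)
    pb = 1.0 - po
    wl = p * include
    sw = np.cumsum(wl)
    sl = np.cumsum(wl * lam)
    tot_w, tot_l = sw[-1], sl[-1]
    if tot_w <= 0.0:
        return ThresholdCurve("otsu_lognormal", np.zeros(h.levels))
    mu_t = tot_l / tot_w

    mu_o = np.divide(sl, sw, out=np.zeros_like(sl), where=sw > 0)
    bw = tot_w - sw
    mu_b = np.divide(tot_l - sl, bw, out=np.zeros_like(sl), where=bw > 0)

    vals = po * (mu_o - mu_t) ** 2 + pb * (mu_b - mu_t) ** 2
    # one class empty -> no between-class spread by convention
    vals[~_nondegenerate(h) | (sw <= 0.0) | (bw <= 0.0)] = 0.0
    np.clip(vals, 0.0, None, out=vals)
    return ThresholdCurve("otsu_lognormal", vals)


def between_class_curve_explicit(h: Histogram, bin_values: npt.NDArray | None = None) -> npt.NDArray:
    """Explicit two-term between-class variance, one threshold at a time.

    Slow direct-sum evaluation of
    ``Po (mu_o - mu_T)^2 + Pb (mu_b - mu_T)^2`` with arbitrary bin
    values; kept as the cross-check for the one-pass rational form.
    """
    p = h.p
    v = np.arange(h.levels, dtype=float) if bin_values is None else np.asarray(bin_values, float)
    mu_t = float((v * p).sum())
    out = np.zeros(h.levels)
    for t in range(h.levels):
        po = p[: t + 1].sum()
        pb = p[t + 1:].sum()
        if po <= 0.0 or pb <= 0.0:
            continue
        mu_o = (v[: t + 1] * p[: t + 1]).sum() / po
        mu_b = (v[t + 1:] * p[t + 1:]).sum() / pb
        out[t] = po * (mu_o - mu_t) ** 2 + pb * (mu_b - mu_t) ** 2
    return out


def threshold_curve(h: Histogram, method: str, log_map: LogMap = "shift1") -> ThresholdCurve:
    """Dispatch to the objective named by `method`."""
    if method == "otsu_gaussian":
        return otsu_gaussian_curve(h)
    if method == "otsu_modified":
        return otsu_modified_curve(h, log_map)
    if method == "otsu_lognormal":
        return otsu_lognormal_curve(h, log_map)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean segmentation; polarity records the thresholding convention."""

    pixels: npt.NDArray[np.bool_]
    polarity: str = "above"  # True = intensity > t*

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


@dataclass(frozen=True)
class SegmentationResult:
    t_star: int
    mask: BinaryMask
    curve: ThresholdCurve
    degenerate: bool = field(default=False)

    def __iter__(self):
        # allow `t, mask, curve = threshold_image(...)`
        return iter((self.t_star, self.mask, self.curve))


def threshold_image(
    image: npt.NDArray,
    method: str = "otsu_lognormal",
    log_map: LogMap = "shift1",
    invert: bool = False,
    levels: int = 256,
) -> SegmentationResult:
    """Select ``t*`` for `image` and binarize it (object = pixels > ``t*``).

    A constant image has no between-class structure: it yields
    ``t*=0``, an all-false mask, a flat zero curve and the degenerate
    flag (with a warning).
    """
    h = compute_histogram(image, levels=levels)
    curve = threshold_curve(h, method, log_map)
    if curve.degenerate:
        warnings.warn("degenerate image: objective identically zero", stacklevel=2)
        mask = np.zeros(np.asarray(image).shape, dtype=bool)
        return SegmentationResult(0, BinaryMask(mask, "above"), curve, degenerate=True)
    t = curve.t_star
    mask = np.asarray(image) > t
    if invert:
        mask = ~mask
    return SegmentationResult(t, BinaryMask(mask, "below" if invert else "above"), curve)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
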