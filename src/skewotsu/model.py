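"""Model/Results facade over threshold selection.

`ThresholdModel` wraps an image (or a bare histogram) together with the
choice of objective; `fit()` runs the argmax scan and returns a
`ThresholdResults` carrying the selected threshold, the full objective
curve, the binary mask and diagnostics, with `summary()`, `evaluate()`
and plotting hanging off the results object.

    >>> model = ThresholdModel(image, method="otsu_lognormal")
    >>> res = model.fit()
    >>> res.t_star
    73
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

from . import evaluation
from .histogram import Histogram, class_stats, compute_histogram
from .thresholding import (
    METHODS,
    BinaryMask,
    ThresholdCurve,
    threshold_curve,
)

__all__ = ["ThresholdModel", "ThresholdResults"]


class ThresholdModel:
    """Threshold-selection model for one gray image or histogram.

    Parameters
    ----------
    image : 2-D integer array, optional
        8-bit gray image.  Either `image` or `histogram` is required.
    histogram : Histogram, optional
        Precomputed histogram (no mask is produced when fitting from a
        histogram alone).
    method : str
        One of ``otsu_gaussian``, ``otsu_modified``, ``otsu_lognormal``.
    log_map : str
        Log-intensity convention for the lognormal objectives:
        ``shift1`` (log(i+1), default) or ``skip-zero``.
    invert : bool
        Flip the mask polarity (object = pixels <= t*).
    """

    def __init__(
        self,
        image: npt.NDArray | None = None,
        histogram: Histogram | None = None,
        method: str = "otsu_lognormal",
        log_map: str = "shift1",
        invert: bool = False,
        levels: int = 256,
    ) -> None:
        if image is None and histogram is None:
            raise ValueError("provide an image or a histogram")
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        self.image = None if image is None else np.asarray(image)
        self.histogram = (
            histogram if histogram is not None else compute_histogram(self.image, levels=levels)
        )
        self.method = method
        self.log_map = log_map
        self.invert = invert

    @classmethod
    def from_file(cls, path, **kwargs) -> "ThresholdModel":
        from .histogram import read_image

        return cls(image=read_image(path), **kwargs)

    def fit(self) -> "ThresholdResults":
        """Scan the objective over all thresholds and binarize."""
        curve = threshold_curve(self.histogram, self.method, self.log_map)
        degenerate = curve.degenerate
        t = 0 if degenerate else curve.t_star
        mask = None
        if self.image is not None:
            px = np.zeros(self.image.shape, bool) if degenerate else self.image > t
            if self.invert and not degenerate:
                px = ~px
            mask = BinaryMask(px, "below" if self.invert else "above")
        return ThresholdResults(self, t, curve, mask, degenerate)


@dataclass
class ThresholdResults:
    """Fitted threshold with its objective curve, mask and diagnostics."""

    model: ThresholdModel
    t_star: int
    curve: ThresholdCurve
    mask: BinaryMask | None
    degenerate: bool

    @property
    def objective_max(self) -> float:
        return float(self.curve.values[self.t_star])

    @property
    def class_split(self):
        """Gaussian-scale class statistics at the fitted threshold."""
        return class_stats(self.model.histogram, self.t_star)

    def evaluate(
        self,
        truth=None,
        metrics: tuple[str, ...] | None = None,
        z_range: str = "observed",
    ) -> evaluation.EvalReport:
        """Score the fitted segmentation (supervised needs `truth`)."""
        if self.model.image is None:
            raise ValueError("evaluation requires the model to hold an image")
        if metrics is None:
            metrics = ("unsupervised", "supervised") if truth is not None else ("unsupervised",)
        return evaluation.evaluate_segmentation(
            self.model.image,
            self.t_star,
            mask=self.mask,
            truth=truth,
            metrics=metrics,
            z_range=z_range,
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cs = self.class_split
        rows = [
            ("method", self.model.method),
            ("log map", self.model.log_map),
            ("threshold t*", self.t_star),
            ("objective at t*", f"{self.objective_max:.6g}"),
            ("P(object), P(background)", f"{cs.p_object:.4f}, {cs.p_background:.4f}"),
            ("class means (mu_o, mu_b)", f"{cs.mu_object:.2f}, {cs.mu_background:.2f}"),
            ("total mean mu_T", f"{cs.mu_total:.2f}"),
            ("between/within/total var", f"{cs.var_between:.1f} / {cs.var_within:.1f} / {cs.var_total:.1f}"),
            ("degenerate", self.degenerate),
        ]
        if self.mask is not None:
            rows.append(("object pixel fraction", f"{self.mask.pixels.mean():.4f}"))
        width = max(len(k) for k, _ in rows)
        lines = ["Threshold selection results", "=" * 45]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_curve(self, ax=None):
        """Plot the objective curve with the selected threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(self.curve.values.size), self.curve.values, lw=1)
        ax.axvline(self.t_star, color="r", ls="--", label=f"t* = {self.t_star}")
        ax.set_xlabel("threshold t")
        ax.set_ylabel("objective")
        ax.set_title(self.model.method)
        ax.legend()
        return ax
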