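"""Gray-level histograms and per-threshold class statistics.

Every thresholding objective in this package is a functional of the
256-bin intensity histogram.  This module provides the histogram
container, the cumulative-moment machinery (class probabilities, class
means, class variances for every candidate threshold ``t``), and the
image / histogram I/O that the rest of the package builds on.

Conventions
-----------
A threshold ``t`` splits the gray range ``[0, L-1]`` into an *object*
class ``{0, ..., t}`` and a *background* class ``{t+1, ..., L-1}``
(the naming follows the classical Otsu derivation; the binary mask
produced downstream marks pixels *above* ``t``).  When one class holds
no probability mass its mean and variance are defined as 0 and the
statistics are flagged degenerate, so that objective scans stay total
over all ``t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import numpy.typing as npt

__all__ = [
    "Histogram",
    "ClassStats",
    "read_image",
    "compute_histogram",
    "class_stats",
    "cumulative_moments",
]

DEFAULT_LEVELS = 256


def read_image(path: str | Path) -> npt.NDArray[np.uint8]:
    """Read a single-channel 8-bit PNG or TIFF image.

    Multi-channel (RGB/RGBA) and non-8-bit inputs are rejected: silent
    color-to-gray conversion would change the histogram under test.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, "
            f"got shape {arr.shape}; convert to 8-bit gray first"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixels, got dtype {arr.dtype}")
    return arr


def _validate_image(image: npt.NDArray, levels: int) -> npt.NDArray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"expected integer intensities, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(f"intensities outside [0, {levels - 1}]")
    return arr


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram: per-bin counts ``n_i`` and probabilities ``P_i = n_i / n``."""

    counts: npt.NDArray[np.int64]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D array with at least 2 bins")
        if (counts < 0).any():
            raise ValueError("negative bin count")
        if counts.sum() == 0:
            raise ValueError("empty input")
        object.__setattr__(self, "counts", counts)

    @property
    def levels(self) -> int:
        """Number of gray levels L."""
        return int(self.counts.size)

    @property
    def n(self) -> int:
        """Total pixel count."""
        return int(self.counts.sum())

    @property
    def p(self) -> npt.NDArray[np.float64]:
        """Bin probabilities ``P_i``; non-negative, summing to 1."""
        return self.counts / self.counts.sum()

    # -- constructors -------------------------------------------------

    @classmethod
    def from_image(cls, image: npt.NDArray, levels: int = DEFAULT_LEVELS) -> "Histogram":
        arr = _validate_image(image, levels)
        return cls(np.bincount(arr.ravel(), minlength=levels).astype(np.int64))

    @classmethod
    def from_probabilities(cls, p: npt.NDArray, scale: int = 10**9) -> "Histogram":
        """Build an integer-count histogram approximating probabilities `p`."""
        p = np.asarray(p, dtype=float)
        if (p < 0).any():
            raise ValueError("negative probability")
        return cls(np.round(p / p.sum() * scale).astype(np.int64))

    # -- serialization ------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"bin": np.arange(self.levels), "count": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Histogram":
        import pandas as pd

        df = pd.read_csv(path)
        counts = np.zeros(max(DEFAULT_LEVELS, int(df["bin"].max()) + 1), dtype=np.int64)
        counts[df["bin"].to_numpy()] = df["count"].to_numpy()
        return cls(counts)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"counts": self.counts.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Histogram":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["counts"], dtype=np.int64))


def compute_histogram(image: npt.NDArray, levels: int = DEFAULT_LEVELS) -> Histogram:
    """Histogram of an integer gray image (bin i = number of pixels at level i)."""
    return Histogram.from_image(image, levels=levels)


def cumulative_moments(
    h: Histogram, bin_values: npt.NDArray | None = None
) -> tuple[npt.NDArray, npt.NDArray]:
    """Zeroth and first cumulative moments of the histogram.

    Returns ``(w, m)`` where ``w[t] = sum_{i<=t} P_i`` (the class-0
    probability for threshold t) and ``m[t] = sum_{i<=t} v_i P_i`` with
    ``v_i`` the bin value (the identity map ``v_i = i`` unless
    `bin_values` supplies another monotone relabeling, e.g. a log map).
    """
    p = h.p
    v = np.arange(h.levels, dtype=float) if bin_values is None else np.asarray(bin_values, float)
    return np.cumsum(p), np.cumsum(v * p)


@dataclass(frozen=True)
class ClassStats:
    """All per-threshold statistics of the two-class split at threshold ``t``.

    ``var_between + var_within == var_total`` and
    ``p_object * mu_object + p_background * mu_background == mu_total``
    hold exactly (to rounding) whenever both classes are non-empty.
    """

    t: int
    p_object: float
    p_background: float
    mu_object: float
    mu_background: float
    mu_total: float
    var_object: float
    var_background: float
    var_between: float
    var_within: float
    var_total: float
    degenerate: bool = field(default=False)


def class_stats(h: Histogram, t: int) -> ClassStats:
    """Statistics of the object/background split at threshold ``t``.

    Object class is ``{0..t}``, background ``{t+1..L-1}``.  Empty
    classes yield zero mean/variance with ``degenerate=True``.
    """
    if not 0 <= t <= h.levels - 1:
        raise ValueError(f"threshold {t} outside [0, {h.levels - 1}]")
    p = h.p
    i = np.arange(h.levels, dtype=float)
    po = float(p[: t + 1].sum())
    pb = float(p[t + 1:].sum())
    mu_total = float((i * p).sum())
    var_total = float(((i - mu_total) ** 2 * p).sum())

    degenerate = po <= 0.0 or pb <= 0.0
    if po > 0.0:
        mu_o = float((i[: t + 1] * p[: t + 1]).sum() / po)
        var_o = float(((i[: t + 1] - mu_o) ** 2 * p[: t + 1]).sum() / po)
    else:
        mu_o = var_o = 0.0
    if pb > 0.0:
        mu_b = float((i[t + 1:] * p[t + 1:]).sum() / pb)
        var_b = float(((i[t + 1:] - mu_b) ** 2 * p[t + 1:]).sum() / pb)
    else:
        mu_b = var_b = 0.0

    if degenerate:
        var_between = 0.0
    else:
        var_between = po * (mu_o - mu_total) ** 2 + pb * (mu_b - mu_total) ** 2
    var_within = po * var_o + pb * var_b

    return ClassStats(
        t=int(t),
        p_object=po,
        p_background=pb,
        mu_object=mu_o,
        mu_background=mu_b,
        mu_total=mu_total,
        var_object=var_o,
        var_background=var_b,
        var_between=var_between,
        var_within=var_within,
        var_total=var_total,
        degenerate=degenerate,
    )
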