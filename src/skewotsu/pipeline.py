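"""Batch comparison of thresholding methods over an image set.

Runs every selected method on every image, scores each segmentation
with the selected metric families, and aggregates per-method averages
plus relative increase rates against a baseline method (the classical
Gaussian Otsu by default).  Each method's threshold comes solely from
its own objective; the evaluation scores are used post hoc to compare
methods, never to pick thresholds.

Inputs can be in-memory `ImageSample`s (from :mod:`skewotsu.synthetic`)
or a directory of PNG/TIFF images with an optional parallel directory
of ground-truth masks.  Parallel execution (joblib) is a throughput
knob only: per-image outputs are identical for any worker count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .histogram import read_image
from .synthetic import ImageSample
from .thresholding import METHODS, threshold_image

__all__ = ["RunConfig", "ComparisonReport", "run_comparison", "best_method_select"]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = {
    "unsupervised": list(evaluation.UNSUPERVISED_METRICS),
    "supervised": list(evaluation.SUPERVISED_METRICS),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run."""

    input: str | Path | Sequence[ImageSample]
    truth: str | Path | None = None
    methods: tuple[str, ...] = METHODS
    metrics: tuple[str, ...] = ("unsupervised", "supervised")
    log_map: str = "shift1"
    z_range: str = "observed"
    invert: bool = False
    baseline: str = "otsu_gaussian"
    workers: int = 1
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.methods or not self.metrics:
            raise ValueError("select at least one method and one metric family")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.baseline not in self.methods:
            raise ValueError("baseline must be one of the selected methods")


@dataclass(frozen=True)
class ComparisonReport:
    """Per-image scores, per-method averages and increase rates."""

    per_image: pd.DataFrame
    per_method: pd.DataFrame
    increase_rate: pd.DataFrame  # percent, vs baseline
    baseline: str
    metrics: tuple[str, ...]

    @property
    def score_columns(self) -> list[str]:
        cols: list[str] = []
        for fam in self.metrics:
            cols += METRIC_COLUMNS[fam]
        return cols

    def to_json_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "per_method": self.per_method.to_dict(orient="index"),
            "increase_rate_percent": self.increase_rate.to_dict(orient="index"),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_image.to_csv(out / "per_image.csv", index=False)
        self.per_method.to_csv(out / "per_method.csv")
        (out / "aggregate.json").write_text(json.dumps(self.to_json_dict(), indent=1))


def _load_inputs(config: RunConfig) -> list[tuple[str, np.ndarray, np.ndarray | None]]:
    """Resolve the input spec to (name, image, truth-or-None) triples."""
    if not isinstance(config.input, (str, Path)):
        return [
            (f"sample_{k:04d}", s.image, s.truth.pixels)
            for k, s in enumerate(config.input)
        ]
    root = Path(config.input)
    img_dir = root / "images" if (root / "images").is_dir() else root
    truth_dir = None
    if config.truth is not None:
        truth_dir = Path(config.truth)
    elif (root / "masks").is_dir():
        truth_dir = root / "masks"
    triples = []
    for path in sorted(img_dir.glob("*")):
        if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
            continue
        try:
            img = read_image(path)
        except (ValueError, OSError) as exc:
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        truth = None
        if truth_dir is not None:
            tp = truth_dir / path.name
            if tp.exists():
                truth = read_image(tp) > 0
        triples.append((path.name, img, truth))
    return triples


def _score_one(name, img, truth, config: RunConfig) -> list[dict]:
    rows = []
    for method in config.methods:
        res = threshold_image(img, method, log_map=config.log_map, invert=config.invert)
        report = evaluation.evaluate_segmentation(
            img,
            res.t_star,
            mask=res.mask,
            truth=truth if "supervised" in config.metrics else None,
            metrics=config.metrics,
            z_range=config.z_range,
        )
        logger.info("%s %s t*=%d flags=%s", name, method, res.t_star, sorted(report.flags))
        rows.append({"image": name, "method": method, "t_star": res.t_star, **report.to_row()})
    return rows


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Run every selected method on every input image and aggregate.

    Images lacking a ground truth are skipped (with a warning) when
    supervised metrics are requested; if nothing remains an error is
    raised.
    """
    triples = _load_inputs(config)
    if "supervised" in config.metrics:
        kept = []
        for name, img, truth in triples:
            if truth is None:
                logger.warning("skipping %s: supervised metrics need a ground truth", name)
            else:
                kept.append((name, img, truth))
        triples = kept
    if not triples:
        raise ValueError("no usable input images")

    if config.workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=config.workers)(
            delayed(_score_one)(name, img, truth, config) for name, img, truth in triples
        )
    else:
        chunks = [_score_one(name, img, truth, config) for name, img, truth in triples]
    per_image = pd.DataFrame([row for chunk in chunks for row in chunk])

    score_cols: list[str] = []
    for fam in config.metrics:
        score_cols += METRIC_COLUMNS[fam]
    per_method = (
        per_image.groupby("method")[score_cols].mean().reindex(list(config.methods))
    )

    base = per_method.loc[config.baseline]
    increase = 100.0 * (per_method - base) / base
    report = ComparisonReport(
        per_image=per_image,
        per_method=per_method,
        increase_rate=increase,
        baseline=config.baseline,
        metrics=config.metrics,
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report


def best_method_select(report: ComparisonReport) -> str:
    """Method with the highest mean over all selected metric scores.

    Ties break to the earliest method in canonical order
    (otsu_gaussian, otsu_modified, otsu_lognormal).
    """
    if report.per_method.empty:
        raise ValueError("empty report")
    means = report.per_method[report.score_columns].mean(axis=1)
    order = [m for m in METHODS if m in means.index]
    best = max(order, key=lambda m: (means[m], -order.index(m)))
    return best
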