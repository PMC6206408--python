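"""Detection and counting evaluation against point annotations.

Detection is scored by point-in-region containment:

* TP — labeled head points covered by some detected region,
* FN — labeled points covered by no region,
* FP — detected regions containing no labeled point.

The unit asymmetry (TP/FN counted in points, FP in regions) makes
``TP + FN`` equal the total number of labeled heads, while spurious
regions are penalized once each. Precision = TP/(TP+FP), recall =
TP/(TP+FN), F-measure their harmonic mean. Contingencies are pooled
over all images before ratios are taken (micro-averaging).

Counting accuracy is the squared Pearson correlation (R²) between
per-image manual and predicted head totals; the OLS slope and
intercept are reported alongside as diagnostics (R² alone cannot
distinguish a 1:1 relation from a proportional bias).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from sorghead.image_io import LabeledPointSet
from sorghead.region_analysis import CandidateRegion

logger = logging.getLogger(__name__)


def match_detections(
    regions: list[CandidateRegion],
    points: LabeledPointSet,
    image_shape: tuple[int, int],
) -> tuple[int, int, int]:
    """(TP, FP, FN) of one image by point-in-region containment."""
    label = np.zeros(image_shape, dtype=np.int32)
    for reg in regions:
        label[reg.pixels[:, 0], reg.pixels[:, 1]] = reg.region_id + 1
    hit = np.zeros(len(regions), dtype=bool)
    tp = 0
    for r, c in points.points:
        lab = label[r, c]
        if lab > 0:
            tp += 1
            hit[lab - 1] = True
    fn = len(points) - tp
    fp = int((~hit).sum())
    return tp, fp, fn


def precision_recall_f(
    tp: int, fp: int, fn: int
) -> tuple[float, float, float]:
    """Precision, recall and F-measure from a detection contingency.

    Undefined ratios (zero denominators) are returned as NaN with a
    warning; rounding happens only at reporting time.
    """
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        logger.warning("precision undefined: no detections (TP+FP=0)")
        precision = float("nan")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        logger.warning("recall undefined: no labeled points (TP+FN=0)")
        recall = float("nan")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_measure = float("nan")
    else:
        f_measure = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f_measure


def counting_r2(manual, predicted) -> float:
    """Squared Pearson correlation of per-image manual vs predicted totals."""
    manual = np.asarray(manual, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if manual.shape != predicted.shape or manual.size < 3:
        raise ValueError("need >= 3 paired per-image totals")
    if manual.std() == 0 or predicted.std() == 0:
        logger.warning("counting R^2 undefined: zero variance in totals")
        return float("nan")
    r, _ = stats.pearsonr(manual, predicted)
    return float(r * r)


@dataclass
class EvaluationReport:
    """Pooled detection contingency, derived metrics and counting R²."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    r_squared: float
    slope: float
    intercept: float
    n_images: int
    per_image: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_images": self.n_images,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def __str__(self) -> str:  # human-readable table, 2-dp metric rounding
        d = self.to_dict()
        lines = [
            f"images    {self.n_images}",
            f"TP        {self.tp}",
            f"FP        {self.fp}",
            f"FN        {self.fn}",
            f"precision {d['precision']:.2f}",
            f"recall    {d['recall']:.2f}",
            f"F-measure {d['f_measure']:.2f}",
        ]
        if not math.isnan(self.r_squared):
            lines.append(f"counting R^2 {self.r_squared:.2f}")
        return "\n".join(lines)


def evaluate_dataset(per_image: list[dict]) -> EvaluationReport:
    """Micro-averaged evaluation over a dataset.

    ``per_image`` holds one dict per image with keys ``image_id``,
    ``regions`` (list of :class:`CandidateRegion`), ``points``
    (:class:`LabeledPointSet` or None), ``image_shape`` and optionally
    ``predicted_total``. Images without labels are excluded (logged).
    Contingencies are summed over images before computing ratios; R² is
    over per-image (manual, predicted) totals when predictions exist.
    """
    if not per_image:
        raise ValueError("empty dataset")
    rows = []
    for item in per_image:
        points = item.get("points")
        if points is None:
            logger.warning("image %r has no labels; excluded", item.get("image_id"))
            continue
        tp, fp, fn = match_detections(item["regions"], points, item["image_shape"])
        rows.append(
            {
                "image_id": item.get("image_id", ""),
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "manual_total": len(points),
                "predicted_total": item.get("predicted_total", np.nan),
            }
        )
    if not rows:
        raise ValueError("no labeled images to evaluate")
    df = pd.DataFrame(rows)
    tp, fp, fn = int(df["TP"].sum()), int(df["FP"].sum()), int(df["FN"].sum())
    precision, recall, f_measure = precision_recall_f(tp, fp, fn)
    r2 = slope = intercept = float("nan")
    if df["predicted_total"].notna().all() and len(df) >= 3:
        manual = df["manual_total"].to_numpy(dtype=np.float64)
        pred = df["predicted_total"].to_numpy(dtype=np.float64)
        r2 = counting_r2(manual, pred)
        if not math.isnan(r2):
            fit = stats.linregress(manual, pred)
            slope, intercept = float(fit.slope), float(fit.intercept)
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        r_squared=r2,
        slope=slope,
        intercept=intercept,
        n_images=len(df),
        per_image=df,
    )
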