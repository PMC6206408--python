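"""High-level orchestration of the detect-and-count workflow.

Ties the modules together into the experiment protocol used for model
assessment: a segmentation-training image set (annotated scribbles)
trains the decision-tree pixel classifier; a separate labeled test set
is segmented, its candidate regions are labeled with true counts from
the point annotations, the quadratic-SVM counter is trained on five of
six image sets with fivefold cross-validation, and detection and
counting performance are estimated on the held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sorghead import (
    color_features,
    evaluation,
    head_counting,
    region_analysis,
    segmentation,
    synthetic_field,
)
from sorghead.image_io import LabeledPointSet


@dataclass
class ImageRecord:
    """One image with annotations and (progressively filled) results."""

    image_id: str
    image: np.ndarray
    points: LabeledPointSet | None = None
    truth: synthetic_field.GroundTruth | None = None
    class_map: np.ndarray | None = None
    regions: list | None = None
    features: pd.DataFrame | None = None
    true_counts: np.ndarray | None = None
    predicted_counts: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    @property
    def predicted_total(self) -> int:
        return head_counting.count_image(self.predicted_counts)


def train_segmentation(
    records: list[ImageRecord],
    annotations: list[np.ndarray],
    max_per_class: int = 2000,
    max_depth: int = 12,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> segmentation.DTSMModel:
    """Train the pixel classifier from per-image scribble annotations."""
    tables = [
        color_features.collect_training_samples(
            rec.image, ann, image_id=rec.image_id, max_per_class=max_per_class,
            seed=seed + i,
        )
        for i, (rec, ann) in enumerate(zip(records, annotations))
    ]
    table = pd.concat(tables, ignore_index=True)
    return segmentation.train_dtsm(
        table, max_depth=max_depth, min_samples_leaf=min_samples_leaf, seed=seed
    )


def segment_record(
    model: segmentation.DTSMModel, rec: ImageRecord, min_area: int = 20
) -> ImageRecord:
    """Classify pixels, extract candidate regions and their features."""
    rec.class_map = segmentation.classify_pixels(model, rec.image)
    mask = segmentation.head_mask(rec.class_map)
    rec.regions = region_analysis.extract_regions(mask, min_area=min_area)
    rec.features = region_analysis.region_feature_table(rec.regions, rec.image_id)
    if rec.points is not None:
        rec.true_counts = head_counting.label_regions_with_counts(
            rec.regions, rec.points, rec.shape
        )
    return rec


def count_table(records: list[ImageRecord]) -> pd.DataFrame:
    """Stack per-region features + true counts over a list of images."""
    frames = [
        head_counting.build_count_table(rec.features, rec.true_counts)
        for rec in records
        if len(rec.features)
    ]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def predict_records(model: head_counting.CountModel, records: list[ImageRecord]) -> None:
    for rec in records:
        rec.predicted_counts = head_counting.predict_counts(model, rec.features)


def evaluate_records(records: list[ImageRecord]) -> evaluation.EvaluationReport:
    return evaluation.evaluate_dataset(
        [
            {
                "image_id": rec.image_id,
                "regions": rec.regions,
                "points": rec.points,
                "image_shape": rec.shape,
                "predicted_total": rec.predicted_total,
            }
            for rec in records
        ]
    )


def _generate_records(
    n: int, params: synthetic_field.FieldSimParams, seed: int, prefix: str
) -> list[ImageRecord]:
    child = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for i in range(n):
        p = replace(params, seed=int(child[i]))
        img, truth = synthetic_field.generate_field_image(p)
        image_id = f"{prefix}_{i:03d}"
        out.append(
            ImageRecord(
                image_id=image_id,
                image=img,
                points=LabeledPointSet(image_id=image_id, points=truth.centers.points),
                truth=truth,
            )
        )
    return out


def run_synthetic_experiment(
    seed: int = 0,
    n_train_seg: int = 17,
    n_test: int = 52,
    params: synthetic_field.FieldSimParams | None = None,
    min_area: int = 20,
    folds: int = 5,
    clip_fraction: float = 0.5,
) -> dict:
    """End-to-end model assessment on synthetic fields.

    Protocol: ``n_train_seg`` images (with full scribble annotations)
    train the pixel classifier; ``n_test`` independently generated
    labeled images are segmented; the test images are partitioned into
    six sets, five of which train the count SVM with k-fold CV while
    the sixth estimates performance. A plot-clipping degradation of the
    held-out images quantifies the effect of imperfect plot boundaries
    on counting accuracy.

    Returns a dict with the evaluation reports and summary metrics.
    """
    if params is None:
        params = synthetic_field.FieldSimParams()
    ss = np.random.SeedSequence(seed).generate_state(6) % (2**31)

    seg_train = _generate_records(n_train_seg, params, int(ss[0]), "train")
    dtsm = train_segmentation(
        seg_train, [rec.truth.class_map for rec in seg_train], seed=int(ss[1])
    )

    test = _generate_records(n_test, params, int(ss[2]), "test")
    for rec in test:
        segment_record(dtsm, rec, min_area=min_area)

    # held-out pixel accuracy of the segmentation step
    pix_correct = sum(
        int((rec.class_map == rec.truth.class_map).sum()) for rec in test
    )
    pix_total = sum(rec.class_map.size for rec in test)
    pixel_accuracy = pix_correct / pix_total

    split = head_counting.split_six_sets([r.image_id for r in test], seed=int(ss[3]))
    by_id = {r.image_id: r for r in test}
    train_recs = [by_id[i] for i in split.train_ids()]
    hold_recs = [by_id[i] for i in split.holdout_ids()]

    table = count_table(train_recs)
    counter = head_counting.train_count_classifier(table, folds=folds, seed=int(ss[4]))
    predict_records(counter, test)

    report_holdout = evaluate_records(hold_recs)
    report_all = evaluate_records(test)

    # plot-clipping degradation of the held-out set
    clipped_recs = []
    for k, rec in enumerate(hold_recs):
        img_c, truth_c = synthetic_field.degrade_plot_clipping(
            rec.image, rec.truth, clip_fraction, seed=int(ss[5]) + k
        )
        crec = ImageRecord(
            image_id=rec.image_id + "_clipped",
            image=img_c,
            points=LabeledPointSet(
                image_id=rec.image_id + "_clipped", points=truth_c.centers.points
            ),
            truth=truth_c,
        )
        segment_record(dtsm, crec, min_area=min_area)
        clipped_recs.append(crec)
    predict_records(counter, clipped_recs)
    report_clipped = evaluate_records(clipped_recs)

    return {
        "seed": seed,
        "n_train_seg": n_train_seg,
        "n_test": n_test,
        "params": params,
        "split": split,
        "dtsm": dtsm,
        "counter": counter,
        "pixel_accuracy": pixel_accuracy,
        "cv_accuracy": counter.metadata["cv_accuracy"],
        "report_holdout": report_holdout,
        "report_all": report_all,
        "report_clipped": report_clipped,
        "records": test,
        "clipped_records": clipped_recs,
    }
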