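"""Quadratic-SVM head counting over region morphology features.

Candidate head regions may contain zero heads (false detections), one
head, or several merged/overlapping heads. A multi-class support vector
machine with a degree-2 polynomial kernel maps each region's eleven
standardized morphology features to a head count; the per-image total
is the sum of per-region predictions.

Model assessment follows a six-set protocol: images are partitioned
uniformly at random into six sets of near-equal size; five sets train
the classifier (with internal stratified k-fold cross-validation, k=5
by default) and the sixth estimates held-out performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from sorghead.image_io import LabeledPointSet
from sorghead.region_analysis import (
    FEATURE_NAMES,
    PERIMETER_CONVENTION,
    CandidateRegion,
)

_SCHEMA_VERSION = 1


class TrainingError(ValueError):
    """Raised for degenerate counting training tables."""


class FeatureConventionError(ValueError):
    """Raised when a model is applied to features of another convention."""


@dataclass(frozen=True)
class SixSetSplit:
    """A balanced partition of image ids into six sets.

    ``sets`` are disjoint, cover all ids, and differ in size by at most
    one; ``holdout`` indexes the set reserved for performance
    estimation (the remaining five train the model).
    """

    sets: tuple[tuple[str, ...], ...]
    holdout: int = 5

    def train_ids(self) -> list[str]:
        return [i for k, s in enumerate(self.sets) for i in s if k != self.holdout]

    def holdout_ids(self) -> list[str]:
        return list(self.sets[self.holdout])


def split_six_sets(image_ids: list[str], seed: int = 0, n_sets: int = 6) -> SixSetSplit:
    """Uniformly random balanced partition of image ids into six sets.

    Deterministic for a fixed seed; set sizes differ by at most one
    (e.g. 52 images -> four sets of 9 and two of 8).
    """
    ids = [str(i) for i in image_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    if len(ids) < n_sets:
        raise ValueError(f"need >= {n_sets} images, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    sets: list[list[str]] = [[] for _ in range(n_sets)]
    for pos, idx in enumerate(order):
        sets[pos % n_sets].append(ids[idx])
    return SixSetSplit(sets=tuple(tuple(sorted(s)) for s in sets))


def label_regions_with_counts(
    regions: list[CandidateRegion],
    points: LabeledPointSet,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """True head count of each region: labeled points inside its pixel set.

    Regions are disjoint by construction, so each point lands in at most
    one region; points covered by no region contribute to no count.
    Boundary points count as inside (pixel membership is discrete).
    """
    label = np.zeros(image_shape, dtype=np.int32)
    for reg in regions:
        label[reg.pixels[:, 0], reg.pixels[:, 1]] = reg.region_id + 1
    counts = np.zeros(len(regions), dtype=np.int64)
    for r, c in points.points:
        lab = label[r, c]
        if lab > 0:
            counts[lab - 1] += 1
    return counts


def build_count_table(
    feature_table: pd.DataFrame, counts: np.ndarray
) -> pd.DataFrame:
    """Attach true counts to a region feature table (one row per region)."""
    if len(feature_table) != len(counts):
        raise ValueError("feature table and counts length mismatch")
    out = feature_table.copy()
    out["true_count"] = np.asarray(counts, dtype=np.int64)
    return out


@dataclass
class CountModel:
    """Quadratic-kernel SVM count classifier with standardization."""

    pipeline: Pipeline
    classes: tuple[int, ...]
    count_cap: int
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "schema_version": _SCHEMA_VERSION,
                "kind": "count_svm",
                "feature_names": list(FEATURE_NAMES),
                "perimeter_convention": PERIMETER_CONVENTION,
                "pipeline": self.pipeline,
                "classes": list(self.classes),
                "count_cap": self.count_cap,
                "metadata": self.metadata,
            },
            Path(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CountModel":
        blob = joblib.load(Path(path))
        if blob.get("kind") != "count_svm" or blob.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"{path} is not a version-{_SCHEMA_VERSION} count model")
        if blob.get("perimeter_convention") != PERIMETER_CONVENTION:
            raise FeatureConventionError(
                "model was trained under perimeter convention "
                f"{blob.get('perimeter_convention')!r}, this build uses "
                f"{PERIMETER_CONVENTION!r}"
            )
        model = cls(
            pipeline=blob["pipeline"],
            classes=tuple(blob["classes"]),
            count_cap=blob["count_cap"],
            metadata=blob["metadata"],
        )
        return model


def train_count_classifier(
    table: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
    count_cap: int = 5,
    C: float = 1.0,
) -> CountModel:
    """Train the quadratic-SVM count classifier with k-fold cross-validation.

    Counts above ``count_cap`` are pooled into the cap class. Features
    are z-scored with statistics of the training rows only (the scaler
    lives inside the pipeline, so cross-validation refits it per fold —
    no leakage from validation folds). Multi-class reduction is
    one-vs-one; the cross-validated accuracy is stored in metadata.
    """
    if len(table) < folds:
        raise TrainingError(f"need >= {folds} rows for {folds}-fold CV")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = np.minimum(table["true_count"].to_numpy(dtype=np.int64), count_cap)
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("degenerate training set: a single count class")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="poly",
                    degree=2,
                    coef0=1.0,
                    gamma="scale",
                    C=C,
                    decision_function_shape="ovo",
                    random_state=seed,
                ),
            ),
        ]
    )
    # stratified CV cannot use more folds than the rarest class has rows
    cv_folds = min(folds, int(np.unique(y, return_counts=True)[1].min()))
    cv_accuracy = float("nan")
    if cv_folds >= 2:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(pipe, X, y, cv=cv)
        cv_accuracy = float(scores.mean())
    pipe.fit(X, y)
    meta = {
        "seed": seed,
        "folds": folds,
        "effective_folds": cv_folds,
        "cv_accuracy": cv_accuracy,
        "n_rows": int(len(table)),
        "count_cap": count_cap,
        "C": C,
        "perimeter_convention": PERIMETER_CONVENTION,
        "class_counts": {int(c): int((y == c).sum()) for c in classes},
    }
    return CountModel(
        pipeline=pipe,
        classes=tuple(int(c) for c in classes),
        count_cap=count_cap,
        metadata=meta,
    )


def predict_counts(
    model: CountModel,
    features: pd.DataFrame,
    perimeter_convention: str = PERIMETER_CONVENTION,
) -> np.ndarray:
    """Predict a non-negative head count for each region feature row."""
    if perimeter_convention != model.metadata.get(
        "perimeter_convention", PERIMETER_CONVENTION
    ):
        raise FeatureConventionError(
            f"features use perimeter convention {perimeter_convention!r}, "
            f"model expects {model.metadata.get('perimeter_convention')!r}"
        )
    if len(features) == 0:
        return np.zeros(0, dtype=np.int64)
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    return model.pipeline.predict(X).astype(np.int64)


def count_image(counts) -> int:
    """Per-image head total: sum of per-region predicted counts."""
    return int(np.sum(np.asarray(list(counts), dtype=np.int64), initial=0))
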