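"""Decision-tree segmentation model (DTSM) over the nine color features.

A CART-style decision tree assigns each pixel one of the seven scene
classes (soil, shadow, dead leaves, leaves, green/orange/white heads).
The three head classes are then merged into a binary head mask whose
connected components are the candidate head regions of the counting
step. No post-classification smoothing is applied; small spurious
components are handled downstream by the region minimum-area filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from sorghead.color_features import FEATURE_NAMES, pixel_features
from sorghead.image_io import CLASS_PALETTE, HEAD_CLASSES

_SCHEMA_VERSION = 1


class TrainingError(ValueError):
    """Raised for degenerate training tables (e.g. a single class)."""


@dataclass
class DTSMModel:
    """A fitted decision-tree pixel classifier plus training metadata."""

    tree: DecisionTreeClassifier
    classes: tuple[int, ...]
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "schema_version": _SCHEMA_VERSION,
                "kind": "dtsm",
                "feature_names": list(FEATURE_NAMES),
                "tree": self.tree,
                "classes": list(self.classes),
                "metadata": self.metadata,
            },
            Path(path),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DTSMModel":
        blob = joblib.load(Path(path))
        if blob.get("kind") != "dtsm" or blob.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"{path} is not a version-{_SCHEMA_VERSION} DTSM file")
        return cls(
            tree=blob["tree"],
            classes=tuple(blob["classes"]),
            metadata=blob["metadata"],
        )


def train_dtsm(
    table: pd.DataFrame,
    max_depth: int = 12,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> DTSMModel:
    """Fit the decision-tree segmentation model on a labeled feature table.

    ``table`` must carry the nine feature columns and a ``class_code``
    column with at least two distinct classes. Splits use Gini impurity
    on axis-aligned thresholds; the tree is deterministic for a fixed
    seed. Resubstitution accuracy is recorded in the model metadata.
    """
    if table.empty:
        raise TrainingError("empty training table")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = table["class_code"].to_numpy(dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("degenerate training set: fewer than 2 classes")
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    )
    tree.fit(X, y)
    resub = float(tree.score(X, y))
    counts = {int(c): int((y == c).sum()) for c in classes}
    meta = {
        "seed": seed,
        "max_depth": max_depth,
        "min_samples_leaf": min_samples_leaf,
        "samples_per_class": counts,
        "tree_depth": int(tree.get_depth()),
        "resubstitution_accuracy": resub,
    }
    return DTSMModel(tree=tree, classes=tuple(int(c) for c in classes), metadata=meta)


def classify_pixels(model: DTSMModel, img: np.ndarray) -> np.ndarray:
    """Classify every pixel of an image into the seven scene classes.

    Returns an H x W uint8 class map; a pure function of (model, image).
    """
    feats = pixel_features(img)
    h, w = feats.shape[:2]
    flat = feats.reshape(-1, len(FEATURE_NAMES))
    pred = model.tree.predict(flat)
    return pred.reshape(h, w).astype(np.uint8)


def head_mask(class_map: np.ndarray) -> np.ndarray:
    """Boolean union of the three head classes (green, orange, white)."""
    return np.isin(np.asarray(class_map), HEAD_CLASSES)


def render_pseudocolor(class_map: np.ndarray) -> np.ndarray:
    """RGB rendering of a class map with the standard display palette."""
    class_map = np.asarray(class_map)
    out = np.zeros(class_map.shape + (3,), dtype=np.uint8)
    for code, rgb in CLASS_PALETTE.items():
        out[class_map == code] = rgb
    return out
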