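"""Nine-dimensional color features for pixel segmentation.

Every pixel is described by its coordinates in three standard color
spaces: normalized r, g, b in [0, 1]; hexcone H, S, V with hue in
[0, 1) (H = 0 for achromatic pixels); and CIE L*a*b* under the D65
reference white with the standard sRGB transfer function (L* in
[0, 100], a*/b* on the usual opponent scale). The fixed feature order
is ``(r, g, b, H, S, V, L*, a*, b*)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("r", "g", "b", "H", "S", "V", "L_star", "a_star", "b_star")


def _check_unit_range(*channels: float) -> None:
    for v in channels:
        if not (0.0 <= v <= 1.0) or not np.isfinite(v):
            raise ValueError(f"channel value {v!r} outside [0, 1]")


def rgb_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Hexcone HSV of one normalized sRGB pixel; H in [0,1), S,V in [0,1]."""
    _check_unit_range(r, g, b)
    h, s, v = _skcolor.rgb2hsv(np.array([[[r, g, b]]], dtype=np.float64))[0, 0]
    return float(h % 1.0), float(s), float(v)


def _srgb_to_xyz_matrix() -> np.ndarray:
    """sRGB -> XYZ matrix derived from the standard chromaticities.

    Primaries R(0.64, 0.33), G(0.30, 0.60), B(0.15, 0.06) and the D65
    white point (0.3127, 0.3290), per IEC 61966-2-1.
    """
    xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    wx, wy = 0.3127, 0.3290
    prim = np.column_stack(
        [xy[:, 0] / xy[:, 1], np.ones(3), (1 - xy.sum(axis=1)) / xy[:, 1]]
    ).T  # columns: XYZ of each primary at unit luminance
    white = np.array([wx / wy, 1.0, (1 - wx - wy) / wy])
    scale = np.linalg.solve(prim, white)
    return prim * scale


_M_RGB2XYZ = _srgb_to_xyz_matrix()
_WHITE_XYZ = _M_RGB2XYZ @ np.ones(3)


def _lab_from_rgb_array(rgb: np.ndarray) -> np.ndarray:
    """Vectorized sRGB (in [0,1], shape ...x3) -> CIE L*a*b* under D65."""
    lin = np.where(
        rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4
    )
    xyz = lin @ _M_RGB2XYZ.T
    t = xyz / _WHITE_XYZ
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(r: float, g: float, b: float) -> tuple[float, float, float]:
    """CIE L*a*b* (D65, 2° observer) of one normalized sRGB pixel."""
    _check_unit_range(r, g, b)
    L, a, bb = _lab_from_rgb_array(np.array([r, g, b], dtype=np.float64))
    return float(L), float(a), float(bb)


def pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel 9-feature raster of an H x W x 3 uint8 image.

    Returns an H x W x 9 float64 array in the order
    ``(r, g, b, H, S, V, L*, a*, b*)``.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    rgb = img.astype(np.float64) / 255.0
    hsv = _skcolor.rgb2hsv(rgb)
    hsv[..., 0] %= 1.0
    lab = _lab_from_rgb_array(rgb)
    return np.concatenate([rgb, hsv, lab], axis=2)


def feature_table_from_pixels(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """9-feature matrix for an explicit list of pixel coordinates."""
    feats = pixel_features(img)
    return feats[rows, cols]


def collect_training_samples(
    img: np.ndarray,
    annotation: np.ndarray,
    image_id: str = "",
    max_per_class: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample labeled pixels into a training table for the segmentation model.

    For each class code 1–7 present in ``annotation``, up to
    ``max_per_class`` pixels are drawn uniformly without replacement
    (seeded, reproducible). Classes absent from the annotation are
    skipped with a warning; the trainer validates class coverage later.

    Returns a DataFrame with the nine feature columns, ``class_code``,
    and provenance columns ``image_id``, ``row``, ``col``.
    """
    annotation = np.asarray(annotation)
    if annotation.shape != img.shape[:2]:
        raise ValueError(
            f"annotation shape {annotation.shape} does not match image {img.shape[:2]}"
        )
    if max_per_class < 1:
        raise ValueError("max_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    feats = pixel_features(img)
    frames = []
    for code in range(1, 8):
        rr, cc = np.nonzero(annotation == code)
        if rr.size == 0:
            logger.warning("class %d absent from annotation of %r", code, image_id)
            continue
        if rr.size > max_per_class:
            idx = rng.choice(rr.size, size=max_per_class, replace=False)
            idx.sort()
            rr, cc = rr[idx], cc[idx]
        df = pd.DataFrame(feats[rr, cc], columns=list(FEATURE_NAMES))
        df["class_code"] = code
        df["image_id"] = image_id
        df["row"] = rr
        df["col"] = cc
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=list(FEATURE_NAMES) + ["class_code", "image_id", "row", "col"]
        )
    return pd.concat(frames, ignore_index=True)
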