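"""Image and annotation I/O.

Raster convention throughout the package: 0-based ``(row, col)`` indexing
with the origin at the top-left pixel. Images are ``H x W x 3`` uint8
sRGB arrays. Two annotation formats are supported:

* point labels — a CSV with header ``image_id,row,col``, one manually
  clicked head center per line;
* class scribbles — an indexed (palette) PNG whose palette indices code
  the seven scene classes (0 marks unlabeled pixels).

Raw UAV frames suffer lens distortion towards the borders; the pipeline
sidesteps calibration by analysing only a central crop
(:func:`crop_center`, default 1731 x 1154 on a 5472 x 3648 frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: class codes for per-pixel scribble annotations; 0 = unlabeled
CLASS_NAMES = {
    0: "unlabeled",
    1: "soil",
    2: "shadow",
    3: "dead_leaves",
    4: "leaves",
    5: "green_head",
    6: "orange_head",
    7: "white_head",
}

HEAD_CLASSES = (5, 6, 7)

#: default central-crop size (height, width) for full-resolution frames
DEFAULT_CROP = (1731, 1154)


class ImageFormatError(ValueError):
    """Raised for images that are not 3-channel 8/16-bit rasters."""


class AnnotationError(ValueError):
    """Raised for malformed point or scribble annotation files."""


@dataclass(frozen=True)
class LabeledPointSet:
    """Manually clicked head centers for one image.

    Points are integer pixel coordinates ``(row, col)``; they double as
    counting labels (points inside a region define its true count) and
    as detection ground truth.
    """

    image_id: str
    points: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        """Points as an ``(n, 2)`` integer array of (row, col)."""
        if not self.points:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(self.points, dtype=np.int64)


def _validate_rgb(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ImageFormatError(
            f"expected a 3-channel image, got array of shape {pixels.shape}"
        )
    return np.ascontiguousarray(pixels, dtype=np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as an H x W x 3 uint8 sRGB array.

    16-bit inputs are rescaled to 8 bit by an integer right-shift of 8
    (keeps the mapping exact and monotone: ``out == in >> 8``).
    Grayscale and alpha-carrying images are rejected — the pipeline's
    color features require exactly three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode == "P":
            raise ImageFormatError(
                f"{path} is a palette image; use read_class_scribbles for annotations"
            )
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path}: expected 3 channels, got shape {arr.shape} (mode {im.mode})"
        )
    if arr.dtype == np.uint16:
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: unsupported dtype {arr.dtype}")
    return np.ascontiguousarray(arr)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an H x W x 3 uint8 array as PNG/TIFF/JPEG (by extension)."""
    Image.fromarray(_validate_rgb(pixels), mode="RGB").save(Path(path))


def crop_center(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Extract the centered ``out_h x out_w`` window of an image.

    When the margin is odd the extra row goes to the bottom and the
    extra column to the right (floor-division placement), so the window
    top-left is at ``((H - out_h) // 2, (W - out_w) // 2)``. Works for
    both 3-channel images and 2-D label rasters.
    """
    h, w = img.shape[:2]
    if out_h < 1 or out_w < 1:
        raise ValueError("crop size must be positive")
    if out_h > h or out_w > w:
        raise ValueError(f"crop {out_h}x{out_w} exceeds image {h}x{w}")
    top = (h - out_h) // 2
    left = (w - out_w) // 2
    return img[top : top + out_h, left : left + out_w].copy()


def read_point_labels(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> dict[str, LabeledPointSet]:
    """Read a point-annotation CSV into one :class:`LabeledPointSet` per image.

    The CSV must have header ``image_id,row,col``. Duplicate points are
    dropped with a warning; if ``image_shape`` is given, out-of-bounds
    points raise :class:`AnnotationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"image_id": str})
    except pd.errors.ParserError as exc:
        raise AnnotationError(f"{path}: {exc}") from exc
    expected = ["image_id", "row", "col"]
    if list(df.columns[:3]) != expected:
        raise AnnotationError(f"{path}: header must be {','.join(expected)}")
    for col in ("row", "col"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # 1-based, after header
            raise AnnotationError(f"{path}: non-integer {col!r} at line {line}")
        df[col] = df[col].astype(np.int64)
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning(
            "%s: dropped %d duplicate point(s)", path, n_before - len(df)
        )
    if image_shape is not None:
        h, w = image_shape
        oob = (df["row"] < 0) | (df["row"] >= h) | (df["col"] < 0) | (df["col"] >= w)
        if oob.any():
            line = int(df.index[oob][0]) + 2
            raise AnnotationError(
                f"{path}: point outside {h}x{w} image at line {line}"
            )
    out: dict[str, LabeledPointSet] = {}
    for image_id, grp in df.groupby("image_id", sort=True):
        pts = tuple(zip(grp["row"].tolist(), grp["col"].tolist()))
        out[str(image_id)] = LabeledPointSet(image_id=str(image_id), points=pts)
    return out


def write_point_labels(path: str | Path, point_sets: dict[str, LabeledPointSet]) -> None:
    """Write point sets to the ``image_id,row,col`` CSV format."""
    rows = [
        {"image_id": ps.image_id, "row": r, "col": c}
        for ps in point_sets.values()
        for r, c in ps.points
    ]
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(path, index=False)


#: display palette for scribble / class-map PNGs, following the pipeline's
#: pseudo-color scheme: soil gray, shadow black, dead leaves off-white,
#: leaves green, green heads light orange, orange heads dark orange,
#: white heads yellow. Index 0 (unlabeled) is magenta to stand out.
CLASS_PALETTE = {
    0: (255, 0, 255),
    1: (128, 128, 128),
    2: (0, 0, 0),
    3: (240, 234, 214),
    4: (0, 128, 0),
    5: (255, 200, 100),
    6: (210, 105, 30),
    7: (255, 255, 0),
}


def read_class_scribbles(path: str | Path) -> np.ndarray:
    """Read an indexed PNG of per-pixel class scribbles.

    Returns an H x W uint8 raster with values 0–7 (0 = unlabeled).
    Palette indices above 7 are rejected.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "P":
            raise AnnotationError(f"{path}: scribbles must be an indexed (P-mode) PNG")
        labels = np.asarray(im, dtype=np.uint8)
    if labels.max(initial=0) > 7:
        raise AnnotationError(
            f"{path}: palette index {int(labels.max())} outside class range 0-7"
        )
    return labels


def write_class_scribbles(path: str | Path, labels: np.ndarray) -> None:
    """Write a 0–7 class raster as an indexed PNG with the display palette."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise AnnotationError("class raster must be 2-D")
    if labels.min(initial=0) < 0 or labels.max(initial=0) > 7:
        raise AnnotationError("class codes must be in 0-7")
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(CLASS_PALETTE.get(i, (0, 0, 0)))
    im.putpalette(palette)
    im.save(Path(path))
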