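"""Geolocated plot extraction from original UAV frames.

Breeding trials are laid out as a grid of two-row plots. Given the
field layout (plot grid, row spacing, inter-plot gap, bearing) and a
per-image world->pixel homography (produced upstream by photogrammetry
and supplied as input), each plot rectangle is projected into every
image that sees it; the instance whose centroid is closest to the image
center is selected — central pixels suffer the least lens and
perspective distortion — then cropped and rectified to an upright,
long-axis-vertical plot image.

World coordinates are planar (x east-ish, y north-ish, meters);
homographies map homogeneous world ``(x, y, 1)`` to homogeneous pixel
``(row, col, w)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import Polygon
from skimage import transform as _sktransform


@dataclass(frozen=True)
class FieldLayout:
    """Plot-grid geometry of one trial field (lengths in meters)."""

    n_columns: int
    n_rows: int
    plot_length: float = 5.0
    row_spacing: float = 0.76
    inter_plot_gap: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    field_bearing: float = 0.0  # degrees, rotation of the plot grid in world frame

    def __post_init__(self):
        if self.n_columns < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one column and row")
        for name in ("plot_length", "row_spacing", "inter_plot_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldLayout":
        raw = yaml.safe_load(Path(path).read_text())
        raw["origin"] = tuple(raw.get("origin", (0.0, 0.0)))
        return cls(**raw)


def plot_polygons(
    layout: FieldLayout, width_margin: float = 0.76
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """World-coordinate rectangles of every plot in the layout.

    Plot width is ``row_spacing + width_margin`` (the two rows plus half
    a margin each side); length is ``plot_length``. Column pitch is
    twice the row spacing (solid-row configuration), and plots within a
    column repeat every ``plot_length + inter_plot_gap``. Rectangles are
    rotated by ``field_bearing`` about the layout origin. Returns
    ``((column, row), corners)`` pairs where corners is a 4x2 array of
    (x, y) in counter-clockwise order starting at the plot's low corner.
    """
    width = layout.row_spacing + width_margin
    col_pitch = 2.0 * layout.row_spacing
    row_pitch = layout.plot_length + layout.inter_plot_gap
    theta = np.deg2rad(layout.field_bearing)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    ox, oy = layout.origin
    out = []
    for col in range(1, layout.n_columns + 1):
        cx = (col - 1) * col_pitch
        for row in range(1, layout.n_rows + 1):
            cy = (row - 1) * row_pitch
            local = np.array(
                [
                    [cx - width / 2, cy],
                    [cx + width / 2, cy],
                    [cx + width / 2, cy + layout.plot_length],
                    [cx - width / 2, cy + layout.plot_length],
                ]
            )
            world = local @ rot.T + np.array([ox, oy])
            out.append(((col, row), world))
    return out


@dataclass(frozen=True)
class ImageGeoref:
    """World->pixel projective transform of one image."""

    image_id: str
    homography: np.ndarray  # 3x3, maps (x, y, 1) -> (row, col, w)
    image_shape: tuple[int, int]  # (H, W)

    def __post_init__(self):
        H = np.asarray(self.homography, dtype=np.float64)
        if H.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError(f"georef of {self.image_id!r} is singular")
        object.__setattr__(self, "homography", H)


def read_georefs(path: str | Path) -> list[ImageGeoref]:
    """Read a JSON list of per-image georeferences.

    Each entry: ``{"image_id": str, "homography": 3x3 nested list,
    "image_shape": [H, W]}``.
    """
    raw = json.loads(Path(path).read_text())
    return [
        ImageGeoref(
            image_id=e["image_id"],
            homography=np.asarray(e["homography"], dtype=np.float64),
            image_shape=tuple(e["image_shape"]),
        )
        for e in raw
    ]


@dataclass(frozen=True)
class PlotInstance:
    """One plot as seen in one image."""

    plot_id: tuple[int, int]
    image_id: str
    quad: np.ndarray  # 4x2 pixel (row, col) corners
    center_distance: float  # centroid -> image-center Euclidean distance, px
    valid: bool = True


def project_plot(rect: np.ndarray, georef: ImageGeoref, plot_id=(0, 0)) -> PlotInstance:
    """Project a world rectangle through an image homography.

    An instance is marked invalid when a vertex maps near infinity
    (|w| ~ 0) or any corner falls outside the image bounds.
    """
    rect = np.asarray(rect, dtype=np.float64)
    homog = np.column_stack([rect[:, 0], rect[:, 1], np.ones(len(rect))])
    mapped = homog @ georef.homography.T
    w = mapped[:, 2]
    if np.any(np.abs(w) < 1e-9):
        return PlotInstance(plot_id, georef.image_id, rect * np.nan, np.inf, False)
    quad = mapped[:, :2] / w[:, None]
    h, wid = georef.image_shape
    inside = (
        (quad[:, 0] >= 0)
        & (quad[:, 0] <= h - 1)
        & (quad[:, 1] >= 0)
        & (quad[:, 1] <= wid - 1)
    ).all()
    center = np.array([(h - 1) / 2.0, (wid - 1) / 2.0])
    centroid = np.array(Polygon(quad).centroid.coords[0])
    dist = float(np.linalg.norm(centroid - center))
    return PlotInstance(plot_id, georef.image_id, quad, dist, bool(inside))


def select_best_instance(instances: list[PlotInstance]) -> PlotInstance:
    """The valid instance closest to its image center (ties: smallest id)."""
    valid = [i for i in instances if i.valid]
    if not valid:
        raise ValueError("no valid plot instance")
    return min(valid, key=lambda i: (i.center_distance, i.image_id))


def crop_and_rotate(
    img: np.ndarray, quad: np.ndarray, out_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, bool]:
    """Rectify a plot quadrilateral to an upright long-axis-vertical patch.

    The full perspective transform between the quad and an axis-aligned
    output rectangle is estimated and the patch resampled bilinearly.
    Output size defaults to the mean lengths of opposite quad edges
    (preserving scale), oriented long axis vertical. Out-of-bounds
    source pixels are filled black; the second return value flags
    whether any were sampled.

    Raises on degenerate (zero-area) quads.
    """
    quad = np.asarray(quad, dtype=np.float64)
    if quad.shape != (4, 2):
        raise ValueError("quad must be 4x2 (row, col)")
    poly = Polygon(quad)
    if poly.area < 1e-9:
        raise ValueError("degenerate (zero-area) quadrilateral")
    e01 = np.linalg.norm(quad[1] - quad[0])
    e12 = np.linalg.norm(quad[2] - quad[1])
    e23 = np.linalg.norm(quad[3] - quad[2])
    e30 = np.linalg.norm(quad[0] - quad[3])
    len_a = (e01 + e23) / 2.0  # v0->v1 / v2->v3 direction
    len_b = (e12 + e30) / 2.0  # v1->v2 / v3->v0 direction
    if out_shape is None:
        # +1: corner-to-corner length spans n+1 pixel centers
        out_h = int(round(max(len_a, len_b))) + 1
        out_w = int(round(min(len_a, len_b))) + 1
    else:
        out_h, out_w = out_shape
    out_h, out_w = max(out_h, 1), max(out_w, 1)
    if len_b >= len_a:
        # v1->v2 edge is the long axis -> map it to the vertical axis
        dst_rows = np.array([[0, out_w - 1], [0, 0], [out_h - 1, 0], [out_h - 1, out_w - 1]])
    else:
        dst_rows = np.array([[0, 0], [out_h - 1, 0], [out_h - 1, out_w - 1], [0, out_w - 1]])
    # skimage transforms work in (x, y) = (col, row)
    src_xy = dst_rows[:, ::-1].astype(np.float64)
    dst_xy = quad[:, ::-1]
    tform = _sktransform.ProjectiveTransform.from_estimate(src_xy, dst_xy)
    if not tform:
        raise ValueError("could not estimate rectifying transform")
    warped = _sktransform.warp(
        img.astype(np.float64),
        inverse_map=tform,
        output_shape=(out_h, out_w),
        order=1,
        cval=-1.0,
        preserve_range=True,
    )
    clipped = bool((warped < 0).any())
    return np.clip(np.rint(warped), 0, 255).astype(np.uint8), clipped
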