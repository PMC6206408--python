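"""Candidate head regions and their eleven morphological features.

A candidate head region is an 8-connected component of the binary head
mask with at least ``min_area`` pixels. Each region is summarized by the
eleven shape descriptors used by the counting classifier:

==================  =========================================================
area                number of pixels in the region
eccentricity        of the ellipse with the same normalized second central
                    moments (0 = circle)
extent              area / (bounding-box height * width)
perimeter           number of boundary pixels (region pixels with at least
                    one non-region 4-neighbor)
major_axis_length   of the same-moments ellipse, pixels
minor_axis_length   of the same-moments ellipse, pixels
convex_area         pixels inside the filled convex hull of pixel centers
filled_area         pixels after filling interior holes
equiv_diameter      diameter of the circle with the region's area
solidity            area / convex_area
roundness           4*pi*filled_area / perimeter**2, clipped to [0, 1]
==================  =========================================================

The second central moments include the +1/12 per-pixel variance term
(the variance of a unit square), so a single pixel has finite axis
lengths (4*sqrt(1/12) ~ 1.155) rather than a degenerate zero ellipse.
The perimeter convention (boundary-pixel count, not a weighted contour
length) is recorded in model metadata because counting models are not
transferable across perimeter conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

FEATURE_NAMES = (
    "area",
    "eccentricity",
    "extent",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "convex_area",
    "filled_area",
    "equiv_diameter",
    "solidity",
    "roundness",
)

#: tag stored in counting-model metadata; predictions refuse to mix conventions
PERIMETER_CONVENTION = "boundary_pixel_count"

_HULL_EPS = 1e-7


@dataclass(frozen=True)
class CandidateRegion:
    """One 8-connected component of the head mask."""

    region_id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    bbox: tuple[int, int, int, int]  # top, left, height, width
    centroid: tuple[float, float]  # sub-pixel (row, col)

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    def local_mask(self) -> np.ndarray:
        """Boolean mask of the region inside its bounding box."""
        top, left, h, w = self.bbox
        m = np.zeros((h, w), dtype=bool)
        m[self.pixels[:, 0] - top, self.pixels[:, 1] - left] = True
        return m


def extract_regions(mask: np.ndarray, min_area: int = 20) -> list[CandidateRegion]:
    """8-connected components of a head mask with area >= ``min_area``.

    Regions are ordered by the (top, left) corner of their bounding box
    and numbered from 0 in that order; the result is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=2)
    raw = []
    for prop in measure.regionprops(labeled):
        if prop.num_pixels < min_area:
            continue
        top, left, bottom, right = prop.bbox
        raw.append(
            (
                (top, left),
                prop.coords.astype(np.int64),
                (top, left, bottom - top, right - left),
                (float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    raw.sort(key=lambda t: t[0])
    return [
        CandidateRegion(region_id=i, pixels=coords, bbox=bbox, centroid=cen)
        for i, (_, coords, bbox, cen) in enumerate(raw)
    ]


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull (monotone chain) of 2-D points.

    Collinear input returns the two extreme points; a single point
    returns itself. Exact on integer coordinates.
    """
    pts = np.unique(points, axis=0)  # sorted lexicographically
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all points collinear
        return np.array([pts[0], pts[-1]])
    return hull


def _convex_area(pixels: np.ndarray, bbox: tuple[int, int, int, int]) -> int:
    """Pixel count of the filled convex hull of the region's pixel centers.

    A pixel belongs to the hull when its center lies inside or on the
    hull boundary (inclusive within a small tolerance); this boundary
    convention is part of the feature definition.
    """
    hull = _convex_hull(pixels.astype(np.float64))
    top, left, h, w = bbox
    rr, cc = np.meshgrid(
        np.arange(top, top + h, dtype=np.float64),
        np.arange(left, left + w, dtype=np.float64),
        indexing="ij",
    )
    if len(hull) == 1:
        return 1
    if len(hull) == 2:  # collinear: pixels whose centers lie on the segment
        a, b = hull
        d = b - a
        t_num = (rr - a[0]) * d[0] + (cc - a[1]) * d[1]
        seg2 = d[0] ** 2 + d[1] ** 2
        cross = (rr - a[0]) * d[1] - (cc - a[1]) * d[0]
        on = (
            (np.abs(cross) <= _HULL_EPS * np.sqrt(seg2))
            & (t_num >= -_HULL_EPS)
            & (t_num <= seg2 + _HULL_EPS)
        )
        return int(on.sum())
    inside = np.ones_like(rr, dtype=bool)
    for i in range(len(hull)):
        o = hull[i]
        e = hull[(i + 1) % len(hull)] - o
        # ccw hull: interior has cross >= 0 for every directed edge
        cross = e[0] * (cc - o[1]) - e[1] * (rr - o[0])
        inside &= cross >= -_HULL_EPS * max(1.0, np.hypot(e[0], e[1]))
    return int(inside.sum())


def region_features(region: CandidateRegion) -> dict[str, float]:
    """The eleven morphological features of one candidate region."""
    pix = region.pixels
    if pix.shape[0] == 0:
        raise ValueError("empty region")
    area = float(pix.shape[0])
    top, left, h, w = region.bbox
    extent = area / (h * w)

    local = region.local_mask()
    filled = ndimage.binary_fill_holes(local)
    filled_area = float(filled.sum())

    # boundary pixels: region pixels with >=1 non-region 4-neighbor
    padded = np.pad(local, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    perimeter = float((local & ~interior).sum())

    convex_area = float(_convex_area(pix, region.bbox))

    r = pix[:, 0].astype(np.float64)
    c = pix[:, 1].astype(np.float64)
    rc, cc_ = r.mean(), c.mean()
    # +1/12: variance of a unit pixel, keeps 1-px regions non-degenerate
    mu20 = ((r - rc) ** 2).mean() + 1.0 / 12.0
    mu02 = ((c - cc_) ** 2).mean() + 1.0 / 12.0
    mu11 = ((r - rc) * (c - cc_)).mean()
    common = np.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    eccentricity = np.sqrt(max(0.0, 1.0 - lam2 / lam1))

    equiv_diameter = float(np.sqrt(4.0 * area / np.pi))
    solidity = area / convex_area
    roundness = min(1.0, 4.0 * np.pi * filled_area / perimeter**2)

    return {
        "area": area,
        "eccentricity": float(eccentricity),
        "extent": float(extent),
        "perimeter": perimeter,
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "convex_area": convex_area,
        "filled_area": filled_area,
        "equiv_diameter": equiv_diameter,
        "solidity": float(solidity),
        "roundness": float(roundness),
    }


def region_feature_table(
    regions: list[CandidateRegion], image_id: str = ""
) -> pd.DataFrame:
    """Feature table (one row per region) with ids, bbox and centroid."""
    rows = []
    for reg in regions:
        rec = {"image_id": image_id, "region_id": reg.region_id}
        rec.update(
            {
                "bbox_top": reg.bbox[0],
                "bbox_left": reg.bbox[1],
                "bbox_height": reg.bbox[2],
                "bbox_width": reg.bbox[3],
                "centroid_row": reg.centroid[0],
                "centroid_col": reg.centroid[1],
            }
        )
        rec.update(region_features(reg))
        rows.append(rec)
    cols = [
        "image_id",
        "region_id",
        "bbox_top",
        "bbox_left",
        "bbox_height",
        "bbox_width",
        "centroid_row",
        "centroid_col",
        *FEATURE_NAMES,
    ]
    return pd.DataFrame(rows, columns=cols)


def crop_region_thumbnails(
    img: np.ndarray, regions: list[CandidateRegion], zero_background: bool = False
) -> list[np.ndarray]:
    """Bounding-box crops of each region from the source image.

    With ``zero_background`` the pixels outside the region's mask are
    set to black inside each thumbnail.
    """
    out = []
    h_img, w_img = img.shape[:2]
    for reg in regions:
        top, left, h, w = reg.bbox
        bottom = min(top + h, h_img)
        right = min(left + w, w_img)
        patch = img[max(top, 0) : bottom, max(left, 0) : right].copy()
        if zero_background:
            mask = reg.local_mask()[: patch.shape[0], : patch.shape[1]]
            patch[~mask] = 0
        out.append(patch)
    return out
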