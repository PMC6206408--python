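"""Synthetic sorghum-field image generator with full ground truth.

Real head detection contends with changing illumination between
frames, a cluttered background (soil, shadow, dead and green leaves),
head color morphs (white, green, orange, brown), wide size/shape
variation, overlapping heads that merge into one region, and heads
partly occluded by leaves. The generator reproduces each of these
controllably so the whole pipeline can be trained and evaluated
without real imagery:

* the background is an organic patchwork of the four background
  classes (smoothed Gaussian fields, argmax with log-weight offsets);
* heads are filled ellipses (plus occasional smaller overlapping lobes
  for the "expanded" tiller/overlap silhouettes), colored from
  disjoint morph-specific HSV boxes; a configurable fraction is placed
  within one minor-axis of a neighbor so regions genuinely merge;
* a per-image multiplicative gain and color cast emulate the
  sunny/cloudy contrast; Gaussian pixel noise emulates the sensor.

Ground truth (head centers, the rendered class map, per-head ellipse
parameters, per-connected-cluster true counts) is recorded before
noise is added. Everything is deterministic for a fixed seed. Brown
heads are labeled with the orange-head class code (the 7-class scheme
has no separate brown class).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor
from skimage import measure

from sorghead import image_io
from sorghead.image_io import LabeledPointSet

#: HSV sampling boxes per scene class, (lo, hi) for each of H, S, V.
#: Boxes are mutually separated in at least one channel so that a color
#: classifier trained on one image generalizes to another.
#: Hue carries most of the class contrast, so the hue boxes of the
#: chromatic classes are spaced >= 0.05 apart — several times the hue
#: noise of the dullest class at the dark end of the illumination gain
#: range. Classes whose hue overlaps (orange heads vs soil) differ in
#: saturation by >= 0.10; white heads are the only low-saturation
#: class and shadow the only near-black class.
DEFAULT_COLOR_BOXES = {
    "soil": ((0.03, 0.06), (0.45, 0.60), (0.42, 0.58)),
    "shadow": ((0.05, 0.15), (0.35, 0.50), (0.03, 0.09)),
    "dead_leaves": ((0.19, 0.22), (0.40, 0.55), (0.62, 0.78)),
    "leaves": ((0.36, 0.43), (0.55, 0.75), (0.30, 0.50)),
    "green_head": ((0.27, 0.31), (0.55, 0.70), (0.58, 0.72)),
    "orange_head": ((0.00, 0.03), (0.70, 0.85), (0.60, 0.78)),
    "brown_head": ((0.11, 0.14), (0.55, 0.70), (0.30, 0.40)),
    "white_head": ((0.05, 0.15), (0.00, 0.10), (0.88, 1.00)),
}

#: morph name -> class code in the 7-class scheme
MORPH_CLASS = {"white": 7, "green": 5, "orange": 6, "brown": 6}

_BACKGROUND_CLASSES = {"soil": 1, "shadow": 2, "dead_leaves": 3, "leaves": 4}


@dataclass(frozen=True)
class FieldSimParams:
    """Study conditions of a simulated field image.

    Defaults emulate a late-heading breeding-trial frame scaled to a
    desk-sized raster: ~100 heads in a 448 x 336 window (similar head
    density to ~309 heads in 1731 x 1154 at 0.45 cm GSD, with head
    sizes scaled accordingly).
    """

    height: int = 448
    width: int = 336
    gsd_cm: float = 0.45
    heads_mean: float = 100.0
    #: negative-binomial size parameter for the per-image head total
    #: (None -> Poisson). The default reproduces the wide between-image
    #: spread of plot head counts in breeding trials (CV ~ 0.3 from
    #: genotype variation), not just counting noise.
    heads_dispersion: float | None = 10.0
    morph_probs: tuple[tuple[str, float], ...] = (
        ("white", 0.25),
        ("green", 0.25),
        ("orange", 0.30),
        ("brown", 0.20),
    )
    head_major_px: tuple[float, float] = (4.0, 7.5)  # semi-major axis range
    head_aspect: tuple[float, float] = (0.5, 0.85)  # minor/major ratio range
    lobe_probability: float = 0.25  # chance of 1-2 extra overlapping lobes
    overlap_probability: float = 0.15
    occlusion_probability: float = 0.10
    illumination_gain: tuple[float, float] = (0.6, 1.2)
    color_cast: float = 0.06  # max per-channel multiplicative cast
    background_weights: tuple[tuple[str, float], ...] = (
        ("soil", 0.35),
        ("shadow", 0.20),
        ("dead_leaves", 0.15),
        ("leaves", 0.30),
    )
    noise_sd: float = 1.5  # 8-bit counts
    seed: int = 0

    def __post_init__(self):
        probs = dict(self.morph_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("morph probabilities must sum to 1")
        for name, p in list(probs.items()) + list(dict(self.background_weights).items()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        for name in ("heads_mean", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.head_major_px[0] <= 0 or self.head_aspect[0] <= 0:
            raise ValueError("head size distribution parameters must be positive")
        if not 0.0 <= self.occlusion_probability <= 1.0:
            raise ValueError("occlusion probability outside [0, 1]")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap probability outside [0, 1]")


@dataclass(frozen=True)
class HeadParams:
    """Ellipse parameters of one rendered head."""

    center: tuple[int, int]  # (row, col), integer pixel
    semi_major: float
    semi_minor: float
    orientation: float  # radians
    morph: str
    occluded: bool = False


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything the pipeline should recover."""

    centers: LabeledPointSet
    class_map: np.ndarray  # H x W uint8, full 7-class annotation (pre-noise)
    heads: list[HeadParams]
    cluster_counts: list[int]  # true count per connected head-mask component

    def head_mask(self) -> np.ndarray:
        return np.isin(self.class_map, image_io.HEAD_CLASSES)


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: int = 32) -> np.ndarray:
    """Smooth random field via bilinear upsampling of coarse Gaussian noise."""
    coarse = rng.normal(size=(h // scale + 2, w // scale + 2))
    zoomed = ndimage.zoom(coarse, scale, order=1)
    return zoomed[:h, :w]


def _sample_box(rng: np.random.Generator, box, n: int = 1) -> np.ndarray:
    """n HSV samples drawn uniformly over a class color box."""
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    out = rng.uniform(lo, hi, size=(n, 3))
    return out[0] if n == 1 else out


def _ellipse_coords(center, a, b, theta, h, w, extra=0.0):
    """Pixel (rows, cols) inside an ellipse, clipped to the image."""
    r0, c0 = center
    rad = int(np.ceil(max(a, b) + extra)) + 1
    rr = np.arange(max(0, int(r0) - rad), min(h, int(r0) + rad + 1))
    cc = np.arange(max(0, int(c0) - rad), min(w, int(c0) + rad + 1))
    if rr.size == 0 or cc.size == 0:
        return np.empty(0, int), np.empty(0, int)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    dr, dc = R - r0, C - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    inside = (u / (a + extra)) ** 2 + (v / (b + extra)) ** 2 <= 1.0
    return R[inside], C[inside]


def _place_heads(rng: np.random.Generator, params: FieldSimParams, n: int) -> list[HeadParams]:
    morph_names = [m for m, _ in params.morph_probs]
    morph_p = np.array([p for _, p in params.morph_probs])
    placed: list[HeadParams] = []
    h, w = params.height, params.width
    max_retries = 200
    for _ in range(n):
        a = rng.uniform(*params.head_major_px)
        ratio = rng.uniform(*params.head_aspect)
        b = a * ratio
        theta = rng.uniform(0, np.pi)
        morph = morph_names[rng.choice(len(morph_names), p=morph_p)]
        margin = a + 2
        make_overlap = placed and rng.random() < params.overlap_probability
        ok = False
        for _try in range(max_retries):
            if make_overlap:
                anchor = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * np.pi)
                d = anchor.semi_minor + b * rng.uniform(0.4, 0.9)
                r0 = int(round(anchor.center[0] + d * np.cos(ang)))
                c0 = int(round(anchor.center[1] + d * np.sin(ang)))
                if not (margin <= r0 < h - margin and margin <= c0 < w - margin):
                    continue
                ok = True
                break
            r0 = int(rng.uniform(margin, h - margin))
            c0 = int(rng.uniform(margin, w - margin))
            # keep non-overlap heads clear of every placed head
            clear = True
            for other in placed:
                d = np.hypot(r0 - other.center[0], c0 - other.center[1])
                if d < (a + other.semi_major) * 1.1:
                    clear = False
                    break
            if clear:
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n} heads in {h}x{w} within the overlap budget"
            )
        placed.append(
            HeadParams(center=(r0, c0), semi_major=a, semi_minor=b, orientation=theta, morph=morph)
        )
    return placed


def generate_field_image(params: FieldSimParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic field image with its ground truth.

    Deterministic for a fixed ``params.seed``. Raises when the head
    density is too high to place within the overlap budget.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    # -- background class patchwork --------------------------------------
    weights = dict(params.background_weights)
    names = list(weights)
    fields = np.stack(
        [_smooth_field(rng, h, w) + np.log(max(weights[nm], 1e-9)) for nm in names]
    )
    bg_idx = np.argmax(fields, axis=0)
    class_map = np.zeros((h, w), dtype=np.uint8)
    for k, nm in enumerate(names):
        class_map[bg_idx == k] = _BACKGROUND_CLASSES[nm]

    # -- heads ------------------------------------------------------------
    if params.heads_dispersion is None:
        n_heads = int(rng.poisson(params.heads_mean))
    else:
        size = params.heads_dispersion
        p = size / (size + params.heads_mean)
        n_heads = int(rng.negative_binomial(size, p))
    heads = _place_heads(rng, params, n_heads)

    head_color_key = {"white": "white_head", "green": "green_head",
                      "orange": "orange_head", "brown": "brown_head"}
    # per-pixel color in HSV: iid uniform over each class's box, so every
    # image exhibits the class's full color diversity (a classifier
    # trained on a single image generalizes to any other)
    hsv = np.zeros((h, w, 3))
    for nm, code in _BACKGROUND_CLASSES.items():
        sel = class_map == code
        hsv[sel] = _sample_box(rng, DEFAULT_COLOR_BOXES[nm], n=int(sel.sum()))

    head_pixels: list[tuple[np.ndarray, np.ndarray, str]] = []
    for head in heads:
        rr_all, cc_all = _ellipse_coords(
            head.center, head.semi_major, head.semi_minor, head.orientation, h, w
        )
        n_lobes = 0
        if rng.random() < params.lobe_probability:
            n_lobes = int(rng.integers(1, 3))
        for _ in range(n_lobes):
            ang = rng.uniform(0, 2 * np.pi)
            off = head.semi_minor * rng.uniform(0.4, 0.8)
            lr = head.center[0] + off * np.cos(ang)
            lc = head.center[1] + off * np.sin(ang)
            la = head.semi_major * rng.uniform(0.4, 0.6)
            lb = head.semi_minor * rng.uniform(0.4, 0.6)
            lrr, lcc = _ellipse_coords((lr, lc), la, lb, rng.uniform(0, np.pi), h, w)
            rr_all = np.concatenate([rr_all, lrr])
            cc_all = np.concatenate([cc_all, lcc])
        head_pixels.append((rr_all, cc_all, head.morph))

    for (rr, cc, morph), head in zip(head_pixels, heads):
        class_map[rr, cc] = MORPH_CLASS[morph]
        hsv[rr, cc] = _sample_box(
            rng, DEFAULT_COLOR_BOXES[head_color_key[morph]], n=rr.size
        )

    # -- occlusion: leaf blob over the head periphery (never the center) --
    occluded_flags = []
    for (rr, cc, _morph), head in zip(head_pixels, heads):
        occ = rng.random() < params.occlusion_probability
        occluded_flags.append(occ)
        if not occ:
            continue
        ang = rng.uniform(0, 2 * np.pi)
        off = head.semi_major * rng.uniform(0.7, 1.0)
        orr, occ_c = (
            head.center[0] + off * np.cos(ang),
            head.center[1] + off * np.sin(ang),
        )
        la = head.semi_major * rng.uniform(0.4, 0.7)
        lb = head.semi_minor * rng.uniform(0.4, 0.7)
        lrr, lcc = _ellipse_coords((orr, occ_c), la, lb, rng.uniform(0, np.pi), h, w)
        if lrr.size == 0:
            continue
        # never cover the annotated center pixel
        keep = ~((lrr == head.center[0]) & (lcc == head.center[1]))
        lrr, lcc = lrr[keep], lcc[keep]
        class_map[lrr, lcc] = _BACKGROUND_CLASSES["leaves"]
        hsv[lrr, lcc] = _sample_box(rng, DEFAULT_COLOR_BOXES["leaves"], n=lrr.size)

    heads = [replace(hd, occluded=occ) for hd, occ in zip(heads, occluded_flags)]

    # -- truth (pre-noise) -------------------------------------------------
    centers = LabeledPointSet(
        image_id=f"sim_{params.seed:06d}",
        points=tuple(hd.center for hd in heads),
    )
    mask = np.isin(class_map, image_io.HEAD_CLASSES)
    labeled = measure.label(mask, connectivity=2)
    n_comp = int(labeled.max())
    cluster_counts = [0] * n_comp
    for hd in heads:
        lab = labeled[hd.center]
        if lab > 0:
            cluster_counts[lab - 1] += 1
    truth = GroundTruth(
        centers=centers, class_map=class_map, heads=heads, cluster_counts=cluster_counts
    )

    # -- illumination, render to RGB, sensor noise -------------------------
    rgb = _skcolor.hsv2rgb(hsv)
    gain = rng.uniform(*params.illumination_gain)
    cast = 1.0 + rng.uniform(-params.color_cast, params.color_cast, size=3)
    rgb = np.clip(rgb * gain * cast, 0, 1)
    img = rgb * 255.0 + rng.normal(0.0, params.noise_sd, size=rgb.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def generate_dataset(
    n_images: int, params: FieldSimParams, seed: int, out_dir: str | Path
) -> dict:
    """Write an n-image dataset in the formats the I/O module reads.

    Emits ``image_###.png`` frames, ``scribbles_###.png`` full class
    annotations (indexed PNG), one ``points.csv`` for all images, and a
    ``manifest.json``. Per-image seeds are derived from the master seed.
    Returns the manifest dict.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    point_sets: dict[str, LabeledPointSet] = {}
    entries = []
    for i in range(n_images):
        p = replace(params, seed=int(child_seeds[i]))
        img, truth = generate_field_image(p)
        image_id = f"image_{i:03d}"
        img_name = f"{image_id}.png"
        scr_name = f"scribbles_{i:03d}.png"
        image_io.write_image(out_dir / img_name, img)
        image_io.write_class_scribbles(out_dir / scr_name, truth.class_map)
        point_sets[image_id] = LabeledPointSet(
            image_id=image_id, points=truth.centers.points
        )
        entries.append(
            {
                "image_id": image_id,
                "image": img_name,
                "scribbles": scr_name,
                "seed": int(child_seeds[i]),
                "n_heads": len(truth.heads),
            }
        )
    image_io.write_point_labels(out_dir / "points.csv", point_sets)
    manifest = {
        "n_images": n_images,
        "master_seed": seed,
        "points": "points.csv",
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(params).items()
        },
        "images": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def degrade_plot_clipping(
    img: np.ndarray,
    truth: GroundTruth,
    clip_fraction: float,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Cut heads at simulated plot boundaries, as in imperfect plot crops.

    For a ``clip_fraction`` share of heads, a straight boundary line is
    drawn through the head near its centroid and every head pixel on
    the far side is repainted as soil (image and class map). Centers
    are retained (the boundary never removes the center pixel), so the
    manual count is unchanged while detected regions shrink or vanish —
    the mechanism that degrades plot-level counting accuracy.
    """
    if not 0.0 <= clip_fraction <= 1.0:
        raise ValueError("clip_fraction outside [0, 1]")
    img = img.copy()
    class_map = truth.class_map.copy()
    if clip_fraction == 0.0 or not truth.heads:
        return img, GroundTruth(
            centers=truth.centers,
            class_map=class_map,
            heads=list(truth.heads),
            cluster_counts=list(truth.cluster_counts),
        )
    rng = np.random.default_rng(seed)
    h, w = class_map.shape
    n_clip = int(round(clip_fraction * len(truth.heads)))
    idx = rng.choice(len(truth.heads), size=n_clip, replace=False)
    soil_box = DEFAULT_COLOR_BOXES["soil"]
    for i in idx:
        head = truth.heads[i]
        r0, c0 = head.center
        ang = rng.uniform(0, np.pi)  # boundary orientation
        nvec = np.array([np.cos(ang), np.sin(ang)])  # boundary normal
        offset = rng.uniform(0.0, 0.4) * head.semi_minor
        rad = int(np.ceil(head.semi_major * 2)) + 2
        rr = np.arange(max(0, r0 - rad), min(h, r0 + rad + 1))
        cc = np.arange(max(0, c0 - rad), min(w, c0 + rad + 1))
        R, C = np.meshgrid(rr, cc, indexing="ij")
        signed = (R - r0) * nvec[0] + (C - c0) * nvec[1] - offset
        cut = (signed > 0) & np.isin(class_map[R, C], image_io.HEAD_CLASSES)
        # the annotated center always survives (offset >= 0 keeps signed(center) <= 0)
        rows, cols = R[cut], C[cut]
        if rows.size == 0:
            continue
        class_map[rows, cols] = _BACKGROUND_CLASSES["soil"]
        base = _sample_box(rng, soil_box)
        jit = rng.uniform(-1, 1, size=(rows.size, 3)) * 0.02
        hsv_vals = np.clip(base + jit, 0, 1)
        rgb = _skcolor.hsv2rgb(hsv_vals.reshape(1, -1, 3)).reshape(-1, 3) * 255.0
        img[rows, cols] = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    mask = np.isin(class_map, image_io.HEAD_CLASSES)
    labeled = measure.label(mask, connectivity=2)
    n_comp = int(labeled.max())
    cluster_counts = [0] * n_comp
    for hd in truth.heads:
        lab = labeled[hd.center]
        if lab > 0:
            cluster_counts[lab - 1] += 1
    return img, GroundTruth(
        centers=truth.centers,
        class_map=class_map,
        heads=list(truth.heads),
        cluster_counts=cluster_counts,
    )
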