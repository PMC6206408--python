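import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from sorghead import image_io
from sorghead.color_features import collect_training_samples
from sorghead.region_analysis import extract_regions
from sorghead.segmentation import classify_pixels, train_dtsm
from sorghead.synthetic_field import (
    DEFAULT_COLOR_BOXES,
    FieldSimParams,
    degrade_plot_clipping,
    generate_dataset,
    generate_field_image,
)

SMALL = FieldSimParams(height=160, width=160, heads_mean=15.0, heads_dispersion=None)


class TestParams:
    def test_morph_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FieldSimParams(morph_probs=(("white", 0.5), ("green", 0.2)))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            FieldSimParams(noise_sd=-1)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            FieldSimParams(occlusion_probability=1.5)


class TestGenerateFieldImage:
    def test_zero_heads(self):
        img, truth = generate_field_image(replace(SMALL, heads_mean=0.0, seed=1))
        assert len(truth.centers) == 0
        assert not truth.head_mask().any()
        assert img.shape == (160, 160, 3)

    def test_no_overlap_components_equal_heads(self):
        # without overlap placement or lobes, each head is its own component
        p = replace(
            SMALL, heads_mean=25.0, overlap_probability=0.0,
            lobe_probability=0.0, occlusion_probability=0.0, seed=5,
        )
        # force exactly 25 by retrying seeds until the Poisson draw is 25
        for seed in range(100):
            img, truth = generate_field_image(replace(p, seed=seed))
            if len(truth.heads) == 25:
                break
        else:
            pytest.fail("no seed produced 25 heads")
        n_comp = len(truth.cluster_counts)
        assert n_comp == 25
        assert sum(truth.cluster_counts) == 25
        assert len(truth.centers) == 25

    def test_deterministic_bit_identical(self):
        p = replace(SMALL, seed=77)
        img1, t1 = generate_field_image(p)
        img2, t2 = generate_field_image(p)
        assert np.array_equal(img1, img2)
        assert t1.centers.points == t2.centers.points
        assert np.array_equal(t1.class_map, t2.class_map)

    def test_centers_lie_on_head_pixels(self):
        img, truth = generate_field_image(replace(SMALL, seed=9))
        mask = truth.head_mask()
        for r, c in truth.centers.points:
            assert mask[r, c]

    def test_cluster_counts_sum_to_heads(self):
        img, truth = generate_field_image(replace(SMALL, seed=11))
        assert sum(truth.cluster_counts) == len(truth.heads)

    def test_class_map_full_coverage(self):
        img, truth = generate_field_image(replace(SMALL, seed=13))
        assert truth.class_map.min() >= 1 and truth.class_map.max() <= 7

    def test_density_too_high_raises(self):
        p = replace(SMALL, height=60, width=60, heads_mean=400.0)
        with pytest.raises(RuntimeError):
            generate_field_image(replace(p, seed=0))

    def test_head_count_matches_poisson_mean(self):
        # mean over many images within 3 SE of the Poisson mean
        counts = [
            len(generate_field_image(replace(SMALL, seed=s))[1].heads)
            for s in range(60)
        ]
        se = np.sqrt(15.0 / 60)
        assert abs(np.mean(counts) - 15.0) <= 3 * se


class TestColorSeparationProperties:
    def test_single_image_training_generalizes_at_fixed_gain(self):
        # with illumination fixed, the class boxes are separated in every
        # informative feature, and one image's pixels suffice to learn them
        p = replace(
            FieldSimParams(illumination_gain=(1.0, 1.0), color_cast=0.0),
            height=224, width=224, heads_mean=30.0,
        )
        img1, t1 = generate_field_image(replace(p, seed=21))
        img2, t2 = generate_field_image(replace(p, seed=22))
        table = collect_training_samples(img1, t1.class_map, "a", 2000, seed=0)
        model = train_dtsm(table, seed=0)
        acc = (classify_pixels(model, img2) == t2.class_map).mean()
        assert acc >= 0.99

    def test_scribble_self_consistency_fixed_point(self):
        # training on an image's own true class map and classifying that
        # image reproduces the annotation almost everywhere
        p = replace(SMALL, noise_sd=0.0, illumination_gain=(1.0, 1.0), color_cast=0.0)
        img, truth = generate_field_image(replace(p, seed=31))
        table = collect_training_samples(img, truth.class_map, "a", 3000, seed=0)
        model = train_dtsm(table, min_samples_leaf=1, seed=0)
        acc = (classify_pixels(model, img) == truth.class_map).mean()
        assert acc >= 0.999

    def test_color_boxes_pairwise_separated(self):
        # every pair of classes differs by a clear gap in at least one channel
        names = list(DEFAULT_COLOR_BOXES)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if {a, b} == {"orange_head", "brown_head"}:
                    continue  # same class code; need not be separable
                gaps = []
                for (alo, ahi), (blo, bhi) in zip(
                    DEFAULT_COLOR_BOXES[a], DEFAULT_COLOR_BOXES[b]
                ):
                    gaps.append(max(blo - ahi, alo - bhi))
                assert max(gaps) >= 0.04, (a, b, gaps)


class TestGenerateDataset:
    def test_single_image_files_and_manifest(self, tmp_path):
        manifest = generate_dataset(1, SMALL, seed=3, out_dir=tmp_path)
        assert (tmp_path / "image_000.png").exists()
        assert (tmp_path / "scribbles_000.png").exists()
        assert (tmp_path / "points.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        assert manifest["n_images"] == 1

    def test_roundtrip_reproduces_truth(self, tmp_path):
        generate_dataset(2, SMALL, seed=4, out_dir=tmp_path)
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        points = image_io.read_point_labels(tmp_path / "points.csv")
        for entry in manifest["images"]:
            img, truth = generate_field_image(replace(SMALL, seed=entry["seed"]))
            disk_img = image_io.read_image(tmp_path / entry["image"])
            disk_ann = image_io.read_class_scribbles(tmp_path / entry["scribbles"])
            assert np.array_equal(disk_img, img)
            assert np.array_equal(disk_ann, truth.class_map)
            assert sorted(points[entry["image_id"]].points) == sorted(
                truth.centers.points
            )

    def test_invalid_count(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, SMALL, seed=0, out_dir=tmp_path)


class TestDegradePlotClipping:
    def test_zero_fraction_unchanged(self):
        img, truth = generate_field_image(replace(SMALL, seed=41))
        img2, truth2 = degrade_plot_clipping(img, truth, 0.0, seed=0)
        assert np.array_equal(img, img2)
        assert np.array_equal(truth.class_map, truth2.class_map)

    def test_all_points_remain_in_bounds_and_counts_consistent(self):
        img, truth = generate_field_image(replace(SMALL, seed=43))
        img2, truth2 = degrade_plot_clipping(img, truth, 0.7, seed=1)
        h, w = truth2.class_map.shape
        for r, c in truth2.centers.points:
            assert 0 <= r < h and 0 <= c < w
        assert len(truth2.centers) == len(truth.centers)

    def test_head_area_roughly_halved_by_centroid_chord(self):
        # a lone head clipped by a boundary through its centroid loses
        # roughly half its pixels
        p = replace(
            SMALL, heads_mean=1.0, overlap_probability=0.0,
            lobe_probability=0.0, occlusion_probability=0.0,
        )
        for seed in range(50):
            img, truth = generate_field_image(replace(p, seed=seed))
            if len(truth.heads) == 1:
                break
        else:
            pytest.fail("no single-head draw")
        before = int(truth.head_mask().sum())
        img2, truth2 = degrade_plot_clipping(img, truth, 1.0, seed=2)
        after = int(truth2.head_mask().sum())
        assert 0 < after < 0.8 * before

    def test_clipping_shrinks_detected_regions(self):
        img, truth = generate_field_image(replace(SMALL, seed=47))
        img2, truth2 = degrade_plot_clipping(img, truth, 1.0, seed=3)
        before = truth.head_mask().sum()
        after = truth2.head_mask().sum()
        assert after < before

    def test_bad_fraction(self):
        img, truth = generate_field_image(replace(SMALL, seed=1))
        with pytest.raises(ValueError):
            degrade_plot_clipping(img, truth, 1.2)
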