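"""Contracts of the procedural scene generator: seeded determinism, range
containment, mask label semantics, depth-order visibility, domain shift."""

import dataclasses

import numpy as np
import pytest

import strawseg as ss
from strawseg.scene import FruitSpec, LeafSpec, StemSpec

from conftest import DESK_SIZE, single_fruit_spec


def degenerate_ranges():
    return ss.RandomizationRanges(
        stem_count=(2, 2), stem_noise_amp=(0.03, 0.03), leaves_per_stem=(3, 3),
        leaf_scale=(1.0, 1.0), leaf_hue=(120.0, 120.0), leaf_curl=(0.2, 0.2),
        fruit_count=(2, 2), fruit_scale=(1.0, 1.0), flower_prob=0.0,
        camera_t=(0.5, 0.5), camera_angle=(0.0, 0.0), brightness=(1.0, 1.0),
    )


class TestSamplePlant:
    def test_seeded_determinism(self, ranges):
        assert ss.sample_plant(ranges, 7) == ss.sample_plant(ranges, 7)

    def test_degenerate_intervals_pin_every_value(self):
        spec = ss.sample_plant(degenerate_ranges(), 5)
        assert len(spec.stems) == 2
        for stem in spec.stems:
            assert len(stem.leaves) == 3
            for leaf in stem.leaves:
                assert leaf.scale == 1.0 and leaf.hue == 120.0 and leaf.curl == 0.2
            for fruit in stem.fruits:
                assert fruit.scale == 1.0
        assert len(spec.fruit_stages()) == 2

    def test_both_ripeness_classes_always_present(self, ranges):
        for seed in range(30):
            stages = ss.sample_plant(ranges, seed).fruit_stages()
            labels = {ss.classify_fruit(s) for s in stages}
            assert labels == {"ripe", "unripe"}

    def test_range_containment_over_many_draws(self, ranges):
        scales, hues, curls = [], [], []
        for seed in range(250):  # >=1000 leaf draws in total
            for stem in ss.sample_plant(ranges, seed).stems:
                for leaf in stem.leaves:
                    scales.append(leaf.scale)
                    hues.append(leaf.hue)
                    curls.append(leaf.curl)
        assert len(scales) >= 1000
        assert min(scales) >= ranges.leaf_scale[0] and max(scales) <= ranges.leaf_scale[1]
        assert min(hues) >= ranges.leaf_hue[0] and max(hues) <= ranges.leaf_hue[1]
        assert min(curls) >= ranges.leaf_curl[0] and max(curls) <= ranges.leaf_curl[1]

    def test_invalid_interval_rejected(self, ranges):
        bad = dataclasses.replace(ranges, leaf_scale=(1.2, 0.8))
        with pytest.raises(ss.ConfigurationError):
            ss.sample_plant(bad, 0)

    def test_fruit_count_below_two_rejected(self, ranges):
        bad = dataclasses.replace(ranges, fruit_count=(1, 1))
        with pytest.raises(ss.ConfigurationError):
            ss.sample_plant(bad, 0)

    def test_one_sided_stage_interval_exhausts_retries(self, ranges):
        bad = dataclasses.replace(ranges, ripeness_stage=(0.8, 0.9))
        with pytest.raises(ss.GenerationError):
            ss.sample_plant(bad, 0)


class TestFruitClassification:
    @pytest.mark.parametrize("stage,label", [
        (1.0, "ripe"), (0.0, "unripe"), (0.5, "ripe"),  # >= threshold is ripe
        (0.49999, "unripe"), (0.51, "ripe"),
    ])
    def test_threshold_convention(self, stage, label):
        assert ss.classify_fruit(stage) == label

    @pytest.mark.parametrize("stage", [-0.1, 1.1])
    def test_out_of_domain_stage(self, stage):
        with pytest.raises(ValueError):
            ss.classify_fruit(stage)

    def test_color_anchors_and_midpoint(self):
        green = ss.fruit_color(0.0)
        red = ss.fruit_color(1.0)
        mid = ss.fruit_color(0.5)
        assert np.allclose(green, ss.scene.UNRIPE_GREEN)
        assert np.allclose(red, ss.scene.RIPE_RED)
        assert np.allclose(mid, (green + red) / 2)
        for stage in np.linspace(0, 1, 11):
            c = ss.fruit_color(stage, np.random.default_rng(0))
            assert c.min() >= 0 and c.max() <= 255


class TestRenderScene:
    def test_empty_scene_is_all_background(self):
        spec = ss.PlantSpec(stems=(), seed=1)
        sample = ss.render_scene(spec, ss.CameraView(), 1.0, DESK_SIZE)
        assert set(np.unique(sample.mask)) == {ss.BACKGROUND}

    @pytest.mark.parametrize("stage,value", [(0.9, ss.RIPE), (0.1, ss.UNRIPE)])
    def test_single_fruit_mask_values(self, stage, value):
        sample = ss.render_scene(single_fruit_spec(stage), ss.CameraView(), 1.0,
                                 DESK_SIZE)
        assert set(np.unique(sample.mask)) == {ss.BACKGROUND, value}

    def test_leaf_on_top_of_fruit_occludes_label(self):
        """The topmost-primitive rule: fruit pixels hidden by a leaf are
        background in the mask."""
        fruit = FruitSpec(t=0.5, scale=1.2, stage=0.9, depth=2.0, side=0.0)
        # leaf exactly over the fruit center, drawn later (greater depth)
        leaf = LeafSpec(t=0.5, scale=1.5, hue=120.0, curl=0.0, rotation=0.3,
                        depth=2.9)
        stem = StemSpec(points=((0.5, 0.9), (0.5, 0.25)), leaves=(leaf,),
                        fruits=(fruit,), flowers=())
        spec = ss.PlantSpec(stems=(stem,), seed=4)
        occluded = ss.render_scene(spec, ss.CameraView(), 1.0, DESK_SIZE)

        bare = ss.render_scene(single_fruit_spec(0.9, seed=4), ss.CameraView(),
                               1.0, DESK_SIZE)
        fruit_px = bare.mask == ss.RIPE
        # the leaf must actually cover part of the fruit for this to bite
        covered = fruit_px & (occluded.mask == ss.BACKGROUND)
        assert covered.any()
        # and no pixel may carry a fruit label where the leaf is on top
        prims = ss.build_primitives(spec)
        leaf_prim = next(p for p in prims if "leaf" in p.name)
        wx, wy = ss.scene._world_grid(ss.CameraView(), DESK_SIZE)
        assert not (leaf_prim.coverage(wx, wy) & (occluded.mask != 0)).any()

    def test_indivisible_size_rejected(self, ranges):
        with pytest.raises(ss.ConfigurationError):
            ss.render_scene(single_fruit_spec(0.9), ss.CameraView(), 1.0, (60, 60))

    def test_render_determinism(self, ranges):
        spec = ss.sample_plant(ranges, 17)
        view, b = ss.sample_view(ranges, 17)
        s1 = ss.render_scene(spec, view, b, DESK_SIZE)
        s2 = ss.render_scene(spec, view, b, DESK_SIZE)
        assert np.array_equal(s1.image, s2.image)
        assert np.array_equal(s1.mask, s2.mask)

    def test_mask_value_conservation(self, small_batch):
        for sample in small_batch:
            assert set(np.unique(sample.mask)) <= set(ss.scene.MASK_VALUES)

    def test_alignment_oracle(self, ranges):
        """Composing per-class binary re-rasterizations by depth reproduces
        the emitted mask exactly."""
        for seed in (1, 2, 3, 4, 5):
            spec = ss.sample_plant(ranges, seed)
            view, b = ss.sample_view(ranges, seed)
            sample = ss.render_scene(spec, view, b, DESK_SIZE)
            wx, wy = ss.scene._world_grid(view, DESK_SIZE)
            recomposed = np.zeros(DESK_SIZE, dtype=np.uint8)
            for prim in ss.build_primitives(spec):  # already depth-sorted
                recomposed[prim.coverage(wx, wy)] = prim.class_value
            assert np.array_equal(recomposed, sample.mask)


class TestDomainShift:
    def test_identity_params_leave_image_unchanged(self, rendered_sample):
        out = ss.apply_domain_shift(rendered_sample,
                                    ss.DomainShiftParams.identity(), 3)
        assert np.array_equal(out.image, rendered_sample.image)

    def test_mask_is_always_preserved(self, rendered_sample):
        for texture in ("flat", "speckle", "photo_like"):
            params = ss.DomainShiftParams(background_texture=texture)
            out = ss.apply_domain_shift(rendered_sample, params, 9)
            assert np.array_equal(out.mask, rendered_sample.mask)

    def test_seeded_determinism(self, rendered_sample):
        params = ss.DomainShiftParams(gaussian_noise_sd=10.0)
        a = ss.apply_domain_shift(rendered_sample, params, 5)
        b = ss.apply_domain_shift(rendered_sample, params, 5)
        assert np.array_equal(a.image, b.image)

    def test_negative_noise_rejected(self):
        with pytest.raises(ss.ConfigurationError):
            ss.DomainShiftParams(gaussian_noise_sd=-1.0)


class TestGenerateDataset:
    def test_n_zero_empty_manifest(self, ranges, tmp_path):
        manifest = ss.generate_dataset(0, ranges, 1, tmp_path, size=DESK_SIZE)
        assert manifest["samples"] == []
        assert not list((tmp_path / "images").iterdir())

    def test_every_sample_contains_both_fruit_classes(self, small_batch):
        for sample in small_batch:
            values = set(np.unique(sample.mask))
            assert ss.RIPE in values and ss.UNRIPE in values

    def test_rerun_is_byte_identical(self, ranges, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        ss.generate_dataset(3, ranges, 42, a, size=DESK_SIZE)
        ss.generate_dataset(3, ranges, 42, b, size=DESK_SIZE)
        for rel in sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file()):
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_manifest_counts_match_masks(self, ranges, tmp_path):
        manifest = ss.generate_dataset(2, ranges, 8, tmp_path, size=DESK_SIZE)
        from PIL import Image
        for entry in manifest["samples"]:
            mask = np.asarray(Image.open(tmp_path / "masks" / f"{entry['id']}.png"))
            values, counts = np.unique(mask, return_counts=True)
            assert {str(int(v)): int(c) for v, c in zip(values, counts)} == \
                entry["class_pixel_counts"]
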