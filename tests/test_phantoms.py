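"""Phantom generation, augmentation and library building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wedgenet.phantoms import (AugmentationSpec, DatasetManifest, Phantom,
                               _inscribed_mask, augment_image, build_library,
                               generate_phantom, load_library)


class TestGeneratePhantom:
    def test_empty_budget_gives_all_zero(self):
        ph = generate_phantom(128, (0, 0), seed=1)
        assert not ph.pixels.any()

    def test_seed_determinism(self):
        a = generate_phantom(128, (3, 8), seed=7)
        b = generate_phantom(128, (3, 8), seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_range_and_support(self, seed):
        ph = generate_phantom(64, (3, 8), seed=seed)
        assert ph.pixels.min() >= 0.0 and ph.pixels.max() <= 1.0
        assert not ph.pixels[~_inscribed_mask(64, margin=0.0)].any()

    def test_support_strictly_inside_circle_over_seeds(self):
        # exhaustive sweep mirroring the support invariant
        for seed in range(1, 101):
            ph = generate_phantom(128, (3, 8), seed=seed)
            assert ph.pixels.max() <= 1.0 and ph.pixels.min() >= 0.0
            outside = ph.pixels[~_inscribed_mask(128, margin=0.0)]
            assert not outside.any()

    @pytest.mark.parametrize("size,budget", [(16, (3, 8)), (128, (5, 3)),
                                             (128, (-1, 8)), (128, (3, 100))])
    def test_invalid_arguments(self, size, budget):
        with pytest.raises(ValueError):
            generate_phantom(size, budget, seed=0)


class TestAugmentImage:
    def test_all_switches_off_is_identity(self):
        ph = generate_phantom(64, (3, 8), seed=2)
        out = augment_image(ph, AugmentationSpec(), seed=0)
        np.testing.assert_array_equal(out.pixels, ph.pixels)

    def test_forced_horizontal_flip_is_involution(self):
        ph = generate_phantom(64, (3, 8), seed=2)
        spec = AugmentationSpec(random_flip=True, flip_axes=(True, False))
        once = augment_image(ph, spec, seed=0)
        twice = augment_image(once, spec, seed=1)
        np.testing.assert_array_equal(twice.pixels, ph.pixels)

    def test_forced_rotation_moves_disk_center(self):
        # off-center disk at known offset; 90-degree rotation has a closed form
        size = 64
        px = np.zeros((size, size))
        c = (size - 1) / 2
        yy, xx = np.ogrid[:size, :size]
        cy, cx = c - 12, c  # 12 px above center
        px[(yy - cy) ** 2 + (xx - cx) ** 2 < 36] = 1.0
        spec = AugmentationSpec(random_rotation=(90.0, 90.0))
        out = augment_image(Phantom(px), spec, seed=0)
        ys, xs = np.nonzero(out.pixels > 0.5)
        got = np.array([ys.mean(), xs.mean()])
        # CCW rotation about the grid center maps (dy,dx)=(-12,0) -> (0,-12)
        expect = np.array([c, c - 12])
        assert np.abs(got - expect).max() < 1.0

    def test_rotation_conserves_mass_after_pad_resize(self):
        ph = generate_phantom(64, (3, 8), seed=5)
        padded = augment_image(ph, AugmentationSpec(pad_resize=True), seed=0)
        rotated = augment_image(padded, AugmentationSpec(random_rotation=170.0),
                                seed=3)
        assert rotated.pixels.sum() == pytest.approx(padded.pixels.sum(),
                                                     rel=1e-2)

    def test_output_stays_in_range_with_noise(self):
        ph = generate_phantom(64, (3, 8), seed=3)
        spec = AugmentationSpec(random_rotation=45.0, random_flip=True,
                                random_affine=0.1, random_noise=0.05)
        out = augment_image(ph, spec, seed=9)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert out.pixels.shape == ph.pixels.shape

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AugmentationSpec(random_noise=-0.1)
        with pytest.raises(ValueError):
            AugmentationSpec(random_rotation=200.0)


class TestBuildLibrary:
    def test_split_arithmetic_and_roundtrip(self, tmp_path):
        m = build_library({"shapes": 20}, size=32, seed=4, out_path=tmp_path)
        assert len(m.entries) == 20
        splits = [e["split"] for e in m.entries]
        assert splits.count("train") == 18 and splits.count("val") == 2
        m2, phantoms = load_library(tmp_path)
        assert len(phantoms) == 20
        assert all((tmp_path / e["path"]).exists() for e in m.entries)

    def test_same_seed_reproduces_identical_library(self, tmp_path):
        a = build_library({"shapes": 6}, size=32, seed=8, out_path=tmp_path / "a")
        b = build_library({"shapes": 6}, size=32, seed=8, out_path=tmp_path / "b")
        assert a.to_json() == b.to_json()
        for ea, eb in zip(a.entries, b.entries):
            pa = (tmp_path / "a" / ea["path"]).read_bytes()
            pb = (tmp_path / "b" / eb["path"]).read_bytes()
            assert pa == pb

    def test_counts_invariant(self):
        with pytest.raises(ValueError):
            DatasetManifest(entries=[{"path": "x"}], counts={"shapes": 2})

    def test_empty_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_library({}, out_path=tmp_path)
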