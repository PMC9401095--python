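"""Split protocol, augmentation operators, and balancing."""

import numpy as np
import pytest

from ratcapsnet.config import AugmentationConfig, ConfigError
from ratcapsnet.data_protocol import (
    AUGMENTATION_OPS,
    AugmentationRecipe,
    ClassIndex,
    balance_upsample,
    augment_once,
    random_recipe,
    read_split_manifest,
    split_by_smallest_class,
    write_split_manifest,
)


def make_class(name, n):
    return ClassIndex(name, tuple(f"{name}/{i:04d}.png" for i in range(n)))


class TestSplit:
    def test_smallest_class_sets_validation_size(self):
        split = split_by_smallest_class([make_class("A", 1000),
                                         make_class("B", 100)], 0.8, seed=0)
        assert len(split.val["A"]) == 20
        assert len(split.val["B"]) == 20
        assert len(split.train["A"]) == 980
        assert len(split.train["B"]) == 80

    def test_equal_small_classes(self):
        split = split_by_smallest_class([make_class("A", 10),
                                         make_class("B", 10)], 0.8, seed=1)
        assert all(len(v) == 2 for v in split.val.values())
        assert all(len(t) == 8 for t in split.train.values())

    def test_seeded_determinism(self):
        classes = [make_class("A", 50), make_class("B", 30)]
        s1 = split_by_smallest_class(classes, 0.8, seed=42)
        s2 = split_by_smallest_class(classes, 0.8, seed=42)
        assert s1 == s2
        s3 = split_by_smallest_class(classes, 0.8, seed=43)
        assert s1.val != s3.val

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            split_by_smallest_class([make_class("A", 10)], 1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_by_smallest_class([ClassIndex("A", ())], 0.8)

    def test_disjoint_and_equal_over_random_configurations(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n_classes = int(rng.integers(2, 6))
            classes = [make_class(f"C{i}", int(rng.integers(5, 200)))
                       for i in range(n_classes)]
            ratio = float(rng.uniform(0.5, 0.95))
            split = split_by_smallest_class(classes, ratio, seed=trial)
            sizes = {len(v) for v in split.val.values()}
            assert len(sizes) == 1
            m = min(len(c) for c in classes)
            assert sizes.pop() == int(round((1 - ratio) * m))
            for c in classes:
                tr = set(split.train[c.class_name])
                va = set(split.val[c.class_name])
                assert not tr & va
                assert tr | va == set(c.items)


@pytest.fixture
def image(rng):
    return rng.random((32, 32, 3))


class TestAugmentOnce:
    @pytest.mark.parametrize("op", AUGMENTATION_OPS)
    def test_shape_and_range_preserved(self, image, op):
        out = augment_once(image, op, seed=3)
        assert out.shape == image.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_zero_rotation_is_identity(self, image):
        assert np.allclose(augment_once(image, "rotate", {"angle": 0.0}), image)

    def test_horizontal_flip_involution(self, image):
        once = augment_once(image, "flip", {"axis": "horizontal"})
        twice = augment_once(once, "flip", {"axis": "horizontal"})
        assert np.array_equal(twice, image)

    def test_vertical_flip_involution(self, image):
        once = augment_once(image, "flip", {"axis": "vertical"})
        twice = augment_once(once, "flip", {"axis": "vertical"})
        assert np.array_equal(twice, image)

    def test_erase_changes_expected_area(self, image):
        for seed in range(10):
            frac = 0.05 + 0.05 * (seed / 10)
            out = augment_once(image, "erase", {"fraction": frac}, seed=seed)
            changed = np.any(out != image, axis=2).mean()
            # rectangle rounding keeps the area near the requested fraction
            assert 0.5 * frac <= changed <= 2.0 * frac

    def test_deterministic_under_seed(self, image):
        a = augment_once(image, "warp", {"strength": 3.0}, seed=11)
        b = augment_once(image, "warp", {"strength": 3.0}, seed=11)
        assert np.array_equal(a, b)
        c = augment_once(image, "warp", {"strength": 3.0}, seed=12)
        assert not np.array_equal(a, c)

    def test_unknown_op_rejected(self, image):
        with pytest.raises(ValueError, match="unknown"):
            augment_once(image, "solarize")


class TestRecipes:
    def test_recipe_roundtrips_json(self, image):
        cfg = AugmentationConfig(seed=5)
        recipe = random_recipe(cfg, np.random.default_rng(5))
        clone = AugmentationRecipe.from_json(recipe.to_json())
        assert clone == recipe
        assert np.array_equal(clone.apply(image), recipe.apply(image))

    def test_recipe_ops_are_known(self):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(0)
        for _ in range(20):
            recipe = random_recipe(cfg, rng)
            assert 1 <= len(recipe.steps) <= 2
            for op, _, _ in recipe.steps:
                assert op in AUGMENTATION_OPS


class TestBalanceUpsample:
    def test_reaches_target_with_all_originals(self):
        pool = [f"img{i}" for i in range(80)]
        out = balance_upsample(pool, 3000, AugmentationConfig(seed=1))
        assert len(out) == 3000
        used = {ident for ident, _ in out}
        assert used == set(pool)
        n_originals = sum(1 for _, recipe in out if recipe is None)
        assert n_originals == 80

    def test_exact_pool_size_returns_originals_only(self):
        pool = [f"img{i}" for i in range(30)]
        out = balance_upsample(pool, 30, AugmentationConfig(seed=1))
        assert out == [(p, None) for p in pool]

    def test_deterministic_under_seed(self):
        pool = [f"img{i}" for i in range(10)]
        a = balance_upsample(pool, 50, AugmentationConfig(seed=9))
        b = balance_upsample(pool, 50, AugmentationConfig(seed=9))
        assert a == b

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            balance_upsample([], 10, AugmentationConfig())

    def test_target_below_pool_rejected(self):
        with pytest.raises(ValueError, match="below"):
            balance_upsample(["a", "b"], 1, AugmentationConfig())

    def test_uniform_class_distribution_after_balancing(self):
        cfg = AugmentationConfig(seed=2)
        sizes = {"A": 980, "B": 80, "C": 300}
        balanced = {cls: balance_upsample([f"{cls}{i}" for i in range(n)],
                                          1000, cfg)
                    for cls, n in sizes.items()}
        assert {len(v) for v in balanced.values()} == {1000}


class TestManifest:
    def test_roundtrip(self, tmp_path):
        classes = [make_class("A", 10), make_class("B", 8)]
        split = split_by_smallest_class(classes, 0.8, seed=0)
        cfg = AugmentationConfig(seed=0)
        balanced = {cls: balance_upsample(list(split.train[cls]), 20, cfg)
                    for cls in split.train}
        path = tmp_path / "manifest.csv"
        write_split_manifest(path, split, balanced)
        rows = read_split_manifest(path)
        train_rows = [r for r in rows if r[2] == "train"]
        val_rows = [r for r in rows if r[2] == "val"]
        assert len(train_rows) == 40
        assert len(val_rows) == 4
        assert any(r[3] is not None for r in train_rows)


class TestAugmentationConfigValidation:
    def test_erase_fraction_bounds(self):
        with pytest.raises(ConfigError):
            AugmentationConfig(erase_fraction=(0.1, 0.9))

    def test_inverted_range(self):
        with pytest.raises(ConfigError):
            AugmentationConfig(noise_sigma=(0.5, 0.1))

    def test_unknown_flip_axis(self):
        with pytest.raises(ConfigError):
            AugmentationConfig(flip_axes=("diagonal",))
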