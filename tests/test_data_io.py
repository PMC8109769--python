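"""Dataset loading, normalization, and partition arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

import sganfield as sf
from sganfield.data_io import Sample, round_half_up, write_manifest
from sganfield.errors import ConfigurationError


def _write_dir(tmp_path, counts=(2, 1)):
    for name, n in zip(("crop", "weed"), counts):
        d = tmp_path / name
        d.mkdir()
        for i in range(n):
            Image.fromarray(np.full((8, 8, 3), 100 + i, dtype=np.uint8)).save(d / f"{i}.png")
    return tmp_path


class TestLoadImageDir:
    def test_labels_follow_directory_order(self, tmp_path):
        samples = sf.load_image_dir(_write_dir(tmp_path))
        assert [s.label for s in samples] == [0, 0, 1]

    def test_missing_class_dir_raises(self, tmp_path):
        d = tmp_path / "crop"
        d.mkdir()
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(d / "a.png")
        with pytest.raises(ConfigurationError, match="weed"):
            sf.load_image_dir(tmp_path)

    def test_empty_class_dir_raises(self, tmp_path):
        _write_dir(tmp_path)
        for f in (tmp_path / "weed").iterdir():
            f.unlink()
        with pytest.raises(ConfigurationError, match="weed"):
            sf.load_image_dir(tmp_path)

    def test_deterministic_ordering(self, tmp_path):
        root = _write_dir(tmp_path, (3, 3))
        a = sf.load_image_dir(root)
        b = sf.load_image_dir(root)
        assert [s.path for s in a] == [s.path for s in b]

    def test_undecodable_file_skipped(self, tmp_path):
        root = _write_dir(tmp_path)
        (root / "crop" / "broken.png").write_bytes(b"not an image")
        samples = sf.load_image_dir(root)
        assert len(samples) == 3


class TestNormalize:
    def test_endpoints_of_affine_map(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[0, 0] = 255
        out = sf.normalize(img, 16)
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[1, 1, 0] == pytest.approx(-1.0)

    def test_constant_127(self):
        out = sf.normalize(np.full((16, 16, 3), 127, dtype=np.uint8), 16)
        assert np.allclose(out, 127 / 127.5 - 1.0)

    def test_round_trip_without_resize(self, rng):
        img = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        assert np.array_equal(sf.denormalize(sf.normalize(img, 32)), img)

    def test_side_not_divisible_by_16_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.normalize(np.zeros((16, 16, 3), dtype=np.uint8), 17)

    @given(v=st.integers(0, 254))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_pixel_value(self, v):
        a = sf.normalize(np.full((16, 16, 3), v, dtype=np.uint8), 16)
        b = sf.normalize(np.full((16, 16, 3), v + 1, dtype=np.uint8), 16)
        assert np.all(b > a)
        assert a.min() >= -1.0 and b.max() <= 1.0


def _pool(n_per_class, side=4):
    img = np.zeros((side, side, 3), dtype=np.uint8)
    return [Sample(img, c, path=f"{c}/{i}") for c in (0, 1) for i in range(n_per_class)]


class TestSplits:
    def test_70_15_15_exact_on_100_per_class(self):
        ds = sf.split_train_val_test(_pool(100), (0.7, 0.15, 0.15), seed=0)
        for part, n in ((ds.train, 140), (ds.val, 30), (ds.test, 30)):
            labels = [s.label for s in part]
            assert len(part) == n
            assert labels.count(0) == labels.count(1) == n // 2

    def test_same_seed_identical_partition(self):
        a = sf.split_train_val_test(_pool(20), seed=5)
        b = sf.split_train_val_test(_pool(20), seed=5)
        assert [s.path for s in a.train] == [s.path for s in b.train]
        assert [s.path for s in a.test] == [s.path for s in b.test]

    def test_degenerate_all_train(self):
        ds = sf.split_train_val_test(_pool(10), (1.0, 0.0, 0.0), seed=0)
        assert len(ds.train) == 20 and not ds.val and not ds.test

    def test_partition_is_disjoint_and_complete(self):
        ds = sf.split_train_val_test(_pool(17), seed=3)
        paths = [s.path for part in (ds.train, ds.val, ds.test) for s in part]
        assert len(paths) == 34 and len(set(paths)) == 34

    def test_class_below_three_samples_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        pool = [Sample(img, 0, "a"), Sample(img, 0, "b"), Sample(img, 1, "c")]
        with pytest.raises(ConfigurationError):
            sf.split_train_val_test(pool, seed=0)


class TestLabelRate:
    @pytest.mark.parametrize("n,rate,expect_l,expect_u", [
        (1300, 0.20, 260, 1040),
        (1300, 0.40, 520, 780),
        (1300, 0.60, 780, 520),
        (1300, 0.80, 1040, 260),
        (1400, 0.20, 280, 1120),
        (1400, 0.40, 560, 840),
        (1400, 0.60, 840, 560),
        (1400, 0.80, 1120, 280),
    ])
    def test_published_label_rate_rows(self, n, rate, expect_l, expect_u):
        split = sf.apply_label_rate(_pool(n // 2), rate, seed=0)
        assert len(split.labeled) == expect_l
        assert len(split.unlabeled) == expect_u

    def test_rate_one_keeps_all_labels(self):
        split = sf.apply_label_rate(_pool(10), 1.0, seed=0)
        assert len(split.labeled) == 20 and not split.unlabeled

    @pytest.mark.parametrize("rate", [0.0, -0.1, 1.2])
    def test_invalid_rate_rejected(self, rate):
        with pytest.raises(ConfigurationError):
            sf.apply_label_rate(_pool(5), rate, seed=0)

    def test_unlabeled_samples_have_no_label(self):
        split = sf.apply_label_rate(_pool(10), 0.3, seed=1)
        assert all(s.label is None for s in split.unlabeled)
        assert all(s.label is not None for s in split.labeled)

    @given(n_per_class=st.integers(2, 60), rate=st.floats(0.05, 1.0),
           seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_count_invariants_and_stratification(self, n_per_class, rate, seed):
        """|L| = round-half-up(rate*N), |L|+|U| = N, per-class quota within 1."""
        n = 2 * n_per_class
        split = sf.apply_label_rate(_pool(n_per_class), rate, seed=seed)
        assert len(split.labeled) == round_half_up(rate * n)
        assert len(split.labeled) + len(split.unlabeled) == n
        per_class = [sum(1 for s in split.labeled if s.label == c) for c in (0, 1)]
        for cnt in per_class:
            assert abs(cnt - rate * n_per_class) <= 1.0

    def test_seed_deterministic_selection(self):
        a = sf.apply_label_rate(_pool(30), 0.4, seed=9)
        b = sf.apply_label_rate(_pool(30), 0.4, seed=9)
        assert [s.path for s in a.labeled] == [s.path for s in b.labeled]


def test_manifest_round_trip(tmp_path):
    ds = sf.split_train_val_test(_pool(10), seed=0)
    lr = sf.apply_label_rate(ds.train, 0.5, seed=0)
    out = tmp_path / "manifest.csv"
    write_manifest(out, ds, lr)
    df = pd.read_csv(out)
    assert set(df.columns) == {"path", "label", "subset", "labeled"}
    assert len(df) == 20
    train_rows = df[df.subset == "train"]
    assert int(train_rows.labeled.sum()) == len(lr.labeled)
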