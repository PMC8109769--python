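"""Training-loop bookkeeping, determinism, and validation semantics."""

import json

import numpy as np
import pytest

import sganfield as sf
from sganfield.config import GanConfig
from sganfield.data_io import LabelRateSplit, Sample
from sganfield.errors import ConfigurationError
from sganfield.training import make_minibatch, predict_real_class, validate


def _synthetic_split(n_train=24, rate=0.5, side=32, seed=0):
    params = sf.FieldParams(resolution=side, seed=seed)
    samples = sf.normalize_samples(sf.generate_dataset(n_train // 2 + 6, params), side)
    ds = sf.split_train_val_test(samples, (0.7, 0.15, 0.15), seed=seed)
    return sf.apply_label_rate(ds.train, rate, seed=seed), ds.val


class TestTrainLoop:
    def test_histories_match_epoch_count(self, tmp_path):
        split, val = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, epochs=3,
                                     batch_size=8, seed=0)
        state = sf.train(cfg, split, val, log_path=tmp_path / "log.jsonl")
        assert state.epoch == 3
        assert len(state.losses) == 3
        assert len(state.val_accuracy) == 3
        assert all(0.0 <= a <= 100.0 for a in state.val_accuracy)
        lines = [json.loads(l) for l in (tmp_path / "log.jsonl").read_text().splitlines()]
        assert len(lines) == 3 and lines[0]["epoch"] == 1

    def test_loss_decomposition_holds_per_epoch(self):
        split, val = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, epochs=2,
                                     batch_size=8, seed=1)
        state = sf.train(cfg, split, val)
        for b in state.losses:
            assert b.l_d == pytest.approx(b.l_supervised + b.l_unsupervised, rel=1e-6)
            assert b.l_supervised >= 0 and b.l_unsupervised >= 0 and b.l_g >= 0

    def test_fixed_seed_reproduces_epoch_losses(self):
        split, val = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, epochs=2,
                                     batch_size=8, seed=5)
        a = sf.train(cfg, split, val)
        b = sf.train(cfg, split, val)
        assert a.losses[0] == b.losses[0]
        assert a.val_accuracy == b.val_accuracy

    def test_best_checkpoint_written_and_loadable(self, tmp_path):
        from sganfield.training import load_checkpoint

        split, val = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, epochs=2,
                                     batch_size=8, seed=0)
        state = sf.train(cfg, split, val, checkpoint_dir=tmp_path)
        assert state.checkpoint_path is not None
        assert (tmp_path / "best.npz").exists()
        assert state.best_epoch >= 1
        gen = sf.build_generator(cfg)
        disc = sf.build_discriminator(cfg)
        load_checkpoint(tmp_path / "best.npz", gen, disc)
        for layer, saved in zip(gen.param_layers() + disc.param_layers(), state.best_params):
            for name in layer.params:
                assert np.array_equal(layer.params[name], saved[name])

    def test_empty_labeled_pool_rejected(self):
        split, val = _synthetic_split()
        empty = LabelRateSplit(rate=0.01, labeled=[], unlabeled=split.unlabeled)
        cfg = GanConfig.desk_profile(base=2, epochs=1)
        with pytest.raises(ConfigurationError):
            sf.train(cfg, empty, val)


class TestMakeMinibatch:
    def test_three_aligned_subbatches(self):
        split, _ = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        gen = sf.build_generator(cfg)
        x_l, y, x_u, x_g = make_minibatch(split, gen, 6, np.random.default_rng(0))
        assert x_l.shape == x_u.shape == x_g.shape == (6, 3, 32, 32)
        assert y.shape == (6,) and set(np.unique(y)) <= {0, 1}

    def test_small_pool_sampled_with_replacement(self):
        split, _ = _synthetic_split()
        small = LabelRateSplit(rate=0.5, labeled=split.labeled[:2], unlabeled=split.unlabeled)
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        gen = sf.build_generator(cfg)
        x_l, y, _, _ = make_minibatch(small, gen, 8, np.random.default_rng(0))
        assert len(x_l) == 8  # only 2 distinct labeled images available

    def test_fixed_rng_reproduces_batch(self):
        split, _ = _synthetic_split()
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        gen = sf.build_generator(cfg)
        a = make_minibatch(split, gen, 4, np.random.default_rng(9))
        b = make_minibatch(split, gen, 4, np.random.default_rng(9))
        for xa, xb in zip(a, b):
            assert np.array_equal(xa, xb)

    def test_empty_labeled_pool_rejected(self):
        split, _ = _synthetic_split()
        empty = LabelRateSplit(rate=0.5, labeled=[], unlabeled=split.unlabeled)
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        gen = sf.build_generator(cfg)
        with pytest.raises(ConfigurationError):
            make_minibatch(empty, gen, 4, np.random.default_rng(0))


class TestValidate:
    def _val_set(self, disc_side=32, n=8):
        img = np.zeros((disc_side, disc_side, 3), dtype=np.float32)
        return [Sample(img, i % 2) for i in range(n)]

    def test_perfect_predictions_give_100(self, monkeypatch):
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        disc = sf.build_discriminator(cfg)
        val = self._val_set()
        labels = np.array([s.label for s in val])
        monkeypatch.setattr("sganfield.training.predict_real_class",
                            lambda d, x, chunk=64: labels)
        assert validate(disc, val) == 100.0

    def test_random_discriminator_near_chance(self):
        """Untrained random weights on a balanced set land in the 50% binomial band."""
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=123)
        disc = sf.build_discriminator(cfg)
        params = sf.FieldParams(resolution=32, seed=3)
        val = sf.normalize_samples(sf.generate_dataset(250, params), 32)
        acc = validate(disc, val)
        # 99.9% two-sided binomial band around 50% for n=500
        assert 42.0 < acc < 58.0

    def test_prediction_ignores_fake_logit(self):
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        disc = sf.build_discriminator(cfg)
        x = np.random.default_rng(0).uniform(-1, 1, (4, 3, 32, 32)).astype(np.float32)
        preds = predict_real_class(disc, x)
        disc.head.params["b"][-1] += 1000.0  # enormous fake-class logit
        assert np.array_equal(predict_real_class(disc, x), preds)

    def test_empty_val_set_rejected(self):
        cfg = GanConfig.desk_profile(base=2, gen_width=16, disc_width=4, seed=0)
        disc = sf.build_discriminator(cfg)
        with pytest.raises(ConfigurationError):
            validate(disc, [])
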