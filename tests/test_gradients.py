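"""Gradient-step contracts: finite-difference oracles, freezing, descent."""

import numpy as np
import pytest

import sganfield as sf
from sganfield.config import GanConfig
from sganfield.losses import (
    discriminator_grads,
    generator_grads,
    gradient_step_d,
    gradient_step_g,
)
from sganfield.nn import Adam
from sganfield.nn.gradcheck import finite_difference_error


@pytest.fixture(scope="module")
def toy():
    """Tiny float64 generator/discriminator pair with a fixed minibatch.

    Biases are nudged off zero so no ReLU preactivation sits exactly at its
    kink (with zero biases, feature-map positions whose receptive fields are
    fully ReLU-zeroed are non-differentiable points where central
    differences are undefined).
    """
    cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6,
                                 dropout=0.0, seed=7)
    disc = sf.build_discriminator(cfg, dtype=np.float64)
    gen = sf.build_generator(cfg, dtype=np.float64)
    rng = np.random.default_rng(1)
    for model in (gen, disc):
        for layer in model.param_layers():
            layer.params["b"] += rng.uniform(0.01, 0.05, size=layer.params["b"].shape)
    batch = dict(
        x_l=rng.uniform(-1, 1, (3, 3, 32, 32)),
        y=np.array([0, 1, 0]),
        x_u=rng.uniform(-1, 1, (3, 3, 32, 32)),
        x_g=rng.uniform(-1, 1, (3, 3, 32, 32)),
        z=rng.standard_normal((3, 6)),
    )
    return cfg, gen, disc, batch


def test_discriminator_loss_gradient_matches_finite_differences(toy):
    cfg, gen, disc, b = toy
    err = finite_difference_error(
        lambda: discriminator_grads(disc, b["x_l"], b["y"], b["x_u"], b["x_g"], train=False).l_d,
        disc.param_layers())
    assert err < 1e-4


def test_generator_loss_gradient_matches_finite_differences(toy):
    cfg, gen, disc, b = toy
    err = finite_difference_error(
        lambda: generator_grads(gen, disc, b["x_u"], b["z"], train=False),
        gen.param_layers())
    assert err < 1e-4


def _snapshot(model):
    return [{n: p.copy() for n, p in l.params.items()} for l in model.param_layers()]


def _identical(a, b):
    return all(np.array_equal(x[n], y[n]) for x, y in zip(a, b) for n in x)


class TestFreezeContracts:
    def test_d_step_leaves_generator_untouched(self, toy, rng):
        cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6, seed=3)
        gen = sf.build_generator(cfg)
        disc = sf.build_discriminator(cfg)
        opt = Adam(disc.param_layers(), lr=1e-3)
        before_g = _snapshot(gen)
        before_d = _snapshot(disc)
        x = rng.uniform(-1, 1, (4, 3, 32, 32)).astype(np.float32)
        x_g = gen.forward(rng.standard_normal((4, 6)).astype(np.float32))
        gradient_step_d(disc, opt, x, np.array([0, 1, 0, 1]), x, x_g)
        assert _identical(_snapshot(gen), before_g)
        assert not _identical(_snapshot(disc), before_d)

    def test_g_step_leaves_discriminator_bitwise_identical(self, toy, rng):
        cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6, seed=3)
        gen = sf.build_generator(cfg)
        disc = sf.build_discriminator(cfg)
        opt = Adam(gen.param_layers(), lr=1e-3)
        before_d = _snapshot(disc)
        before_g = _snapshot(gen)
        x = rng.uniform(-1, 1, (4, 3, 32, 32)).astype(np.float32)
        gradient_step_g(gen, disc, opt, x, rng.standard_normal((4, 6)).astype(np.float32))
        assert _identical(_snapshot(disc), before_d)
        assert not _identical(_snapshot(gen), before_g)

    def test_zero_learning_rate_changes_nothing(self, toy, rng):
        cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6, seed=3)
        gen = sf.build_generator(cfg)
        disc = sf.build_discriminator(cfg)
        x = rng.uniform(-1, 1, (4, 3, 32, 32)).astype(np.float32)
        before = _snapshot(disc)
        gradient_step_d(disc, Adam(disc.param_layers(), lr=0.0), x,
                        np.array([0, 1, 0, 1]), x, x.copy())
        assert _identical(_snapshot(disc), before)
        before_g = _snapshot(gen)
        gradient_step_g(gen, disc, Adam(gen.param_layers(), lr=0.0), x,
                        rng.standard_normal((4, 6)).astype(np.float32))
        assert _identical(_snapshot(gen), before_g)


class TestDescent:
    def test_repeated_d_steps_decrease_loss_on_fixed_minibatch(self, rng):
        cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6,
                                     dropout=0.0, seed=11)
        disc = sf.build_discriminator(cfg)
        opt = Adam(disc.param_layers(), lr=1e-3)
        x_l = rng.uniform(-1, 1, (6, 3, 32, 32)).astype(np.float32)
        y = np.array([0, 1, 0, 1, 0, 1])
        x_u = rng.uniform(-1, 1, (6, 3, 32, 32)).astype(np.float32)
        x_g = rng.uniform(-1, 1, (6, 3, 32, 32)).astype(np.float32)
        losses = [gradient_step_d(disc, opt, x_l, y, x_u, x_g).l_d for _ in range(20)]
        assert losses[-1] < losses[0]

    def test_repeated_g_steps_decrease_feature_matching_loss(self, rng):
        cfg = GanConfig.desk_profile(base=2, gen_width=8, disc_width=4, latent_dim=6,
                                     dropout=0.0, seed=11)
        gen = sf.build_generator(cfg)
        disc = sf.build_discriminator(cfg)
        opt = Adam(gen.param_layers(), lr=1e-3)
        x = rng.uniform(-1, 1, (6, 3, 32, 32)).astype(np.float32)
        z = rng.standard_normal((6, 6)).astype(np.float32)
        losses = [gradient_step_g(gen, disc, opt, x, z) for _ in range(20)]
        assert losses[-1] < losses[0]
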