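"""The adversarial training loop.

One epoch is one pass over the unlabeled pool in minibatches (the unlabeled
data dominates at low label rates); each iteration draws m labeled, m
unlabeled and m freshly generated images, takes one Adam step on the
discriminator loss with the generator frozen, then one feature-matching
Adam step on the generator with the discriminator frozen (m/2 real + m/2
generated).  Pools smaller than m are sampled with replacement.  Validation
accuracy — argmax over the K real classes only — is recorded every epoch
and the best-validation parameters are kept.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import GanConfig
from .data_io import LabelRateSplit, Sample, images_array, labels_array
from .errors import ConfigurationError, TrainingDiverged
from .losses import LossBreakdown, gradient_step_d, gradient_step_g
from .models import Discriminator, Generator, build_discriminator, build_generator
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class TrainState:
    epoch: int = 0
    losses: list[LossBreakdown] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_val_accuracy: float = -1.0
    best_epoch: int = -1
    checkpoint_path: str | None = None
    generator: Generator | None = None
    discriminator: Discriminator | None = None
    best_params: list[dict[str, np.ndarray]] | None = None


def _to_nchw(samples: Sequence[Sample]) -> np.ndarray:
    return np.transpose(images_array(samples).astype(np.float32), (0, 3, 1, 2))


def _draw(rng: np.random.Generator, n_pool: int, m: int) -> np.ndarray:
    if n_pool >= m:
        return rng.choice(n_pool, size=m, replace=False)
    return rng.choice(n_pool, size=m, replace=True)


def make_minibatch(split: LabelRateSplit, generator: Generator, m: int,
                   rng: np.random.Generator,
                   labeled_nchw: np.ndarray | None = None,
                   labels: np.ndarray | None = None,
                   unlabeled_nchw: np.ndarray | None = None):
    """Draw aligned (labeled, labels, unlabeled, generated) sub-batches of size m."""
    if not split.labeled:
        raise ConfigurationError("the labeled pool is empty; the supervised term is undefined")
    if labeled_nchw is None:
        labeled_nchw = _to_nchw(split.labeled)
        labels = labels_array(split.labeled)
    if unlabeled_nchw is None:
        unlabeled_nchw = _to_nchw(split.unlabeled) if split.unlabeled else labeled_nchw
    il = _draw(rng, len(labeled_nchw), m)
    iu = _draw(rng, len(unlabeled_nchw), m)
    z = rng.standard_normal((m, generator.latent_dim)).astype(np.float32)
    x_g = generator.forward(z, train=False)
    return labeled_nchw[il], labels[il], unlabeled_nchw[iu], x_g


def predict_real_class(discriminator: Discriminator, images_nchw: np.ndarray,
                       chunk: int = 64) -> np.ndarray:
    """Argmax over the K real-class logits (fake logit ignored)."""
    preds = []
    for i in range(0, len(images_nchw), chunk):
        logits, _ = discriminator.forward(images_nchw[i : i + chunk], train=False)
        preds.append(np.argmax(logits[:, : discriminator.n_classes], axis=1))
    return np.concatenate(preds)


def validate(discriminator: Discriminator, val_set: Sequence[Sample]) -> float:
    """Classification accuracy (%) on a labeled set, fake class excluded."""
    if not val_set:
        raise ConfigurationError("validation set is empty")
    preds = predict_real_class(discriminator, _to_nchw(val_set))
    return float((preds == labels_array(val_set)).mean() * 100.0)


def _snapshot(models: Sequence) -> list[dict[str, np.ndarray]]:
    return [
        {name: p.copy() for name, p in layer.params.items()}
        for model in models
        for layer in model.param_layers()
    ]


def restore_params(models: Sequence, snapshot: list[dict[str, np.ndarray]]) -> None:
    layers = [layer for model in models for layer in model.param_layers()]
    for layer, saved in zip(layers, snapshot):
        for name in layer.params:
            layer.params[name][...] = saved[name]


def save_checkpoint(path: str | Path, generator: Generator, discriminator: Discriminator) -> None:
    arrays = {}
    for tag, model in (("g", generator), ("d", discriminator)):
        for i, layer in enumerate(model.param_layers()):
            for name, p in layer.params.items():
                arrays[f"{tag}_{i}_{name}"] = p
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path, generator: Generator, discriminator: Discriminator) -> None:
    data = np.load(path)
    for tag, model in (("g", generator), ("d", discriminator)):
        for i, layer in enumerate(model.param_layers()):
            for name in layer.params:
                layer.params[name][...] = data[f"{tag}_{i}_{name}"]


def train(config: GanConfig, split: LabelRateSplit, val_set: Sequence[Sample],
          log_path: str | Path | None = None,
          checkpoint_dir: str | Path | None = None) -> TrainState:
    """Run the adversarial semi-supervised training loop."""
    if not split.labeled:
        raise ConfigurationError("training requires a non-empty labeled pool")
    if not val_set or any(s.label is None for s in val_set):
        raise ConfigurationError("validation set must be non-empty and fully labeled")

    ss = np.random.SeedSequence(config.seed)
    rng_init_g, rng_init_d, rng_batch = (np.random.default_rng(s) for s in ss.spawn(3))
    generator = build_generator(config, rng_init_g)
    discriminator = build_discriminator(config, rng_init_d)
    opt_d = Adam(discriminator.param_layers(), config.lr_d, config.beta1,
                 config.beta2, weight_decay=config.weight_decay)
    opt_g = Adam(generator.param_layers(), config.lr_g, config.beta1,
                 config.beta2, weight_decay=config.weight_decay)

    labeled_nchw = _to_nchw(split.labeled)
    labels = labels_array(split.labeled)
    unlabeled_nchw = _to_nchw(split.unlabeled) if split.unlabeled else labeled_nchw
    m = config.batch_size
    # epoch = one pass over the whole training pool: the optimization budget
    # is then independent of the labeled rate, and per-epoch work grows
    # slightly with the labeled fraction as published timings show
    n_pool = len(split.labeled) + len(split.unlabeled)
    iters_per_epoch = max(1, int(np.ceil(n_pool / m)))
    half = m // 2

    state = TrainState(generator=generator, discriminator=discriminator)
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, config.epochs + 1):
            ep_losses = []
            for _ in range(iters_per_epoch):
                x_l, y_l, x_u, x_g = make_minibatch(
                    split, generator, m, rng_batch,
                    labeled_nchw=labeled_nchw, labels=labels, unlabeled_nchw=unlabeled_nchw,
                )
                breakdown = gradient_step_d(
                    discriminator, opt_d, x_l, y_l, x_u, x_g,
                    include_labeled_in_unsupervised=config.include_labeled_in_unsupervised,
                    grad_clip=config.grad_clip,
                )
                iu = _draw(rng_batch, len(unlabeled_nchw), half)
                z = rng_batch.standard_normal((half, generator.latent_dim)).astype(np.float32)
                l_g = gradient_step_g(generator, discriminator, opt_g, unlabeled_nchw[iu], z,
                                      grad_clip=config.grad_clip)
                ep_losses.append(LossBreakdown(breakdown.l_supervised, breakdown.l_unsupervised,
                                               breakdown.l_d, l_g))
            mean = lambda key: float(np.mean([getattr(b, key) for b in ep_losses]))
            epoch_loss = LossBreakdown(mean("l_supervised"), mean("l_unsupervised"),
                                       mean("l_d"), mean("l_g"))
            acc = validate(discriminator, val_set)
            state.epoch = epoch
            state.losses.append(epoch_loss)
            state.val_accuracy.append(acc)
            if acc > state.best_val_accuracy:
                state.best_val_accuracy = acc
                state.best_epoch = epoch
                state.best_params = _snapshot([generator, discriminator])
                if checkpoint_dir is not None:
                    ckpt = Path(checkpoint_dir) / "best.npz"
                    save_checkpoint(ckpt, generator, discriminator)
                    state.checkpoint_path = str(ckpt)
            if log_fh:
                log_fh.write(json.dumps({"epoch": epoch, **epoch_loss.as_dict(), "val_acc": acc}) + "\n")
                log_fh.flush()
            logger.debug("epoch %d: L_D=%.4f L_G=%.4f val=%.1f%%", epoch, epoch_loss.l_d,
                         epoch_loss.l_g, acc)
    except TrainingDiverged:
        logger.exception("training diverged at epoch %d; best checkpoint retained", state.epoch + 1)
        raise
    finally:
        if log_fh:
            log_fh.close()
    return state
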