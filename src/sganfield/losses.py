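"""Loss functions and gradient steps for semi-supervised adversarial training.

The discriminator loss decomposes as L_D = L_supervised + L_unsupervised:

* L_supervised  = -E log p(y | x, y < K+1): cross-entropy over the K real
  classes only, i.e. the probabilities are renormalized with the fake class
  excluded, so the supervised term is invariant to the fake-class mass.
* L_unsupervised = -E log(1 - p_fake(x_u)) - E log p_fake(G(z)): unlabeled
  images are pushed away from the fake class, generated images toward it.
  With p_fake playing the role of 1 - D(x), this is the classic real/fake
  GAN loss expressed through the (K+1)-way softmax.

The generator is trained by feature matching: the squared distance between
the mean discriminator feature of a real batch and of a generated batch.

Public loss functions accept probability vectors (clamped before logs);
training uses the numerically stable logit forms with log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ShapeError, TrainingDiverged
from .models import Discriminator, Generator
from .nn import Adam
from .nn.optim import clip_grad_norm

P_EPS = 1e-7


@dataclass(frozen=True)
class LossBreakdown:
    """Per-step (or per-epoch) loss components; l_d = l_supervised + l_unsupervised."""

    l_supervised: float
    l_unsupervised: float
    l_d: float
    l_g: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "l_supervised": self.l_supervised,
            "l_unsupervised": self.l_unsupervised,
            "l_d": self.l_d,
            "l_g": self.l_g,
        }


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_EPS, 1.0 - P_EPS)


def supervised_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean -log p(y | x, y < K+1) from (n, K+1) class probabilities."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels))
    if len(labels) != len(probs):
        raise ShapeError("labels and probabilities must have equal length")
    k = probs.shape[1] - 1
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError(f"supervised labels must be real classes in [0, {k}); the fake class is never a label")
    real = probs[:, :k]
    cond = real / np.maximum(real.sum(axis=1, keepdims=True), P_EPS)
    picked = _clamp(cond[np.arange(len(labels)), labels])
    return float(-np.log(picked).mean())


def unsupervised_loss(probs_unlabeled: np.ndarray, probs_generated: np.ndarray) -> float:
    """-E log(1 - p_fake) over unlabeled - E log p_fake over generated."""
    pu = np.atleast_2d(np.asarray(probs_unlabeled, dtype=np.float64))
    pg = np.atleast_2d(np.asarray(probs_generated, dtype=np.float64))
    if pu.size == 0 or pg.size == 0:
        raise ValueError("unsupervised loss needs non-empty unlabeled and generated batches")
    p_fake_u = _clamp(pu[:, -1])
    p_fake_g = _clamp(pg[:, -1])
    return float(-np.log1p(-p_fake_u).mean() - np.log(p_fake_g).mean())


def discriminator_loss(supervised: float, unsupervised: float) -> LossBreakdown:
    if not (np.isfinite(supervised) and np.isfinite(unsupervised)):
        raise TrainingDiverged(
            f"non-finite discriminator loss: supervised={supervised}, unsupervised={unsupervised}"
        )
    return LossBreakdown(float(supervised), float(unsupervised), float(supervised + unsupervised))


def feature_matching_loss(features_real: np.ndarray, features_fake: np.ndarray) -> float:
    """Squared Euclidean distance between batch-mean feature vectors."""
    fr = np.atleast_2d(np.asarray(features_real, dtype=np.float64))
    ff = np.atleast_2d(np.asarray(features_fake, dtype=np.float64))
    if fr.shape[1] != ff.shape[1]:
        raise ShapeError(f"feature length mismatch: {fr.shape[1]} vs {ff.shape[1]}")
    diff = fr.mean(axis=0) - ff.mean(axis=0)
    return float(diff @ diff)


# ---------------------------------------------------------------------------
# Stable logit-space forms and their analytic gradients
# ---------------------------------------------------------------------------

def supervised_loss_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for the real-class conditional cross-entropy.

    -log p(y|x, y<K+1) = logsumexp(real logits) - logit_y; the fake logit
    receives zero gradient.
    """
    n, kp1 = logits.shape
    k = kp1 - 1
    real = logits[:, :k].astype(np.float64)
    lse = logsumexp(real, axis=1)
    loss = float((lse - real[np.arange(n), labels]).mean())
    grad = np.zeros_like(logits, dtype=np.float64)
    soft = np.exp(real - lse[:, None])
    soft[np.arange(n), labels] -= 1.0
    grad[:, :k] = soft / n
    return loss, grad


def unsupervised_loss_logits(logits_u: np.ndarray, logits_g: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and gradients for both unsupervised terms, in logit space.

    -log(1 - p_fake) = logsumexp(all) - logsumexp(real)
    -log p_fake      = logsumexp(all) - logit_fake
    """
    lu = logits_u.astype(np.float64)
    lg = logits_g.astype(np.float64)
    nu, kp1 = lu.shape
    ng = lg.shape[0]
    k = kp1 - 1

    lse_all_u = logsumexp(lu, axis=1)
    lse_real_u = logsumexp(lu[:, :k], axis=1)
    term_u = float((lse_all_u - lse_real_u).mean())
    grad_u = np.exp(lu - lse_all_u[:, None])
    grad_u[:, :k] -= np.exp(lu[:, :k] - lse_real_u[:, None])
    grad_u /= nu

    lse_all_g = logsumexp(lg, axis=1)
    term_g = float((lse_all_g - lg[:, k]).mean())
    grad_g = np.exp(lg - lse_all_g[:, None])
    grad_g[:, k] -= 1.0
    grad_g /= ng

    return term_u + term_g, grad_u, grad_g


def discriminator_grads(discriminator: Discriminator,
                        x_labeled: np.ndarray, labels: np.ndarray,
                        x_unlabeled: np.ndarray, x_generated: np.ndarray,
                        include_labeled_in_unsupervised: bool = False,
                        train: bool = True) -> LossBreakdown:
    """Forward + backward pass of L_D; leaves gradients on discriminator layers.

    Inputs are NCHW batches.  The generated batch enters as a plain array,
    so the generator is frozen by construction.
    """
    nl, nu = len(x_labeled), len(x_unlabeled)
    x = np.concatenate([x_labeled, x_unlabeled, x_generated], axis=0)
    logits, _ = discriminator.forward(x, train=train)

    l_sup, g_sup = supervised_loss_logits(logits[:nl], np.asarray(labels))
    if include_labeled_in_unsupervised:
        logits_u = logits[: nl + nu]
    else:
        logits_u = logits[nl : nl + nu]
    l_unsup, g_u, g_g = unsupervised_loss_logits(logits_u, logits[nl + nu :])

    dlogits = np.zeros_like(logits, dtype=np.float64)
    dlogits[:nl] += g_sup
    if include_labeled_in_unsupervised:
        dlogits[: nl + nu] += g_u
    else:
        dlogits[nl : nl + nu] += g_u
    dlogits[nl + nu :] += g_g

    breakdown = discriminator_loss(l_sup, l_unsup)
    discriminator.backward(dlogits.astype(logits.dtype), need_input_grad=False)
    return breakdown


def gradient_step_d(discriminator: Discriminator, optimizer: Adam | None,
                    x_labeled: np.ndarray, labels: np.ndarray,
                    x_unlabeled: np.ndarray, x_generated: np.ndarray,
                    include_labeled_in_unsupervised: bool = False,
                    grad_clip: float = 0.0) -> LossBreakdown:
    """One Adam step on L_D with the generator frozen."""
    breakdown = discriminator_grads(
        discriminator, x_labeled, labels, x_unlabeled, x_generated,
        include_labeled_in_unsupervised=include_labeled_in_unsupervised,
    )
    _check_finite_grads(discriminator.param_layers(), "discriminator")
    if grad_clip:
        clip_grad_norm(discriminator.param_layers(), grad_clip)
    if optimizer is not None:
        optimizer.step()
    return breakdown


def generator_grads(generator: Generator, discriminator: Discriminator,
                    x_real: np.ndarray, noise: np.ndarray,
                    train: bool = True) -> float:
    """Forward + backward pass of the feature-matching loss L_G.

    Leaves gradients on the generator layers; the discriminator is frozen
    (its gradients are computed only to route the signal back to G and are
    never applied).
    """
    n_fake = len(noise)
    x_fake = generator.forward(np.asarray(noise), train=train)
    # the real half carries no generator gradient, so it passes through D
    # without keeping caches for backprop
    _, f_real = discriminator.forward(np.asarray(x_real, dtype=x_fake.dtype), train=train)
    f_real = f_real.astype(np.float64)
    logits, feats = discriminator.forward(x_fake, train=train)
    f_fake = feats.astype(np.float64)
    diff = f_real.mean(axis=0) - f_fake.mean(axis=0)
    l_g = float(diff @ diff)

    dfeats = np.full_like(feats, 0.0)
    dfeats[:] = (-2.0 * diff / n_fake).astype(feats.dtype)
    dx = discriminator.backward(np.zeros_like(logits), dfeats)
    generator.backward(dx)
    return l_g


def gradient_step_g(generator: Generator, discriminator: Discriminator,
                    optimizer: Adam | None, x_real: np.ndarray,
                    noise: np.ndarray, grad_clip: float = 0.0) -> float:
    """One Adam step on L_G; discriminator parameters are left untouched."""
    l_g = generator_grads(generator, discriminator, x_real, noise)
    if not np.isfinite(l_g):
        raise TrainingDiverged(f"non-finite generator loss: {l_g}")
    _check_finite_grads(generator.param_layers(), "generator")
    if grad_clip:
        clip_grad_norm(generator.param_layers(), grad_clip)
    if optimizer is not None:
        optimizer.step()
    return l_g


def _check_finite_grads(layers, which: str) -> None:
    for layer in layers:
        for name, g in layer.grads.items():
            if not np.all(np.isfinite(g)):
                raise TrainingDiverged(f"non-finite gradient in {which} parameter '{name}'")
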