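"""Confusion-matrix metrics, the supervised CNN baseline, and the
label-rate comparison harness.

SSCA (semi-supervised classification accuracy) and SCA (supervised
classification accuracy) share one formula — (TP + TN) / (P + N), i.e. the
trace of the confusion matrix over its total — and differ only in which
training regime produced the classifier.  Class 0 (crop) is taken as
"positive"; for two classes the accuracy is symmetric in that choice.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .config import GanConfig
from .data_io import DatasetSplit, Sample, apply_label_rate, labels_array
from .errors import ConfigurationError
from .losses import supervised_loss_logits
from .nn import Adam
from .nn.optim import clip_grad_norm
from .training import TrainState, _draw, _to_nchw, restore_params, train

logger = logging.getLogger(__name__)


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int], k: int = 2) -> np.ndarray:
    """K x K counts; rows = true class, columns = predicted class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ConfigurationError("true and predicted label sequences must have equal length")
    if t.size and (t.max() >= k or p.max() >= k or t.min() < 0 or p.min() < 0):
        raise ConfigurationError(f"labels must lie in [0, {k})")
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def accuracy_from_cm(cm: np.ndarray) -> float:
    """(TP + TN) / (P + N) x 100 — the trace over the total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ConfigurationError("confusion matrix is empty")
    return float(np.trace(cm) / total * 100.0)


# ---------------------------------------------------------------------------
# Supervised baseline: a LeNet5-style small CNN
# ---------------------------------------------------------------------------


class SmallCnn:
    """Compact supervised CNN (seven weight layers counting convs and dense).

    Three stride-2 3x3 conv blocks, global average pooling, and a two-layer
    classification head over the K real classes.  Trained with plain
    softmax cross-entropy on the labeled subset only.
    """

    def __init__(self, n_classes: int, rng: np.random.Generator, width: int = 8):
        w = width
        self.net = nn.Sequential([
            nn.Conv2d(3, w, k=3, stride=2, pad=1, rng=rng), nn.ReLU(),
            nn.Conv2d(w, 2 * w, k=3, stride=2, pad=1, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * w, 4 * w, k=3, stride=2, pad=1, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Dense(4 * w, 4 * w, rng), nn.ReLU(),
            nn.Dense(4 * w, n_classes, rng),
        ])
        self.n_classes = n_classes

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def param_layers(self):
        return self.net.param_layers()

    def predict(self, images_nchw: np.ndarray, chunk: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(images_nchw), chunk):
            out.append(np.argmax(self.forward(images_nchw[i : i + chunk]), axis=1))
        return np.concatenate(out)


def _cross_entropy_step(model: SmallCnn, opt: Adam, x: np.ndarray, y: np.ndarray,
                        grad_clip: float = 0.0) -> float:
    logits = model.forward(x, train=True)
    # reuse the real-class conditional loss with a dummy never-used extra column
    padded = np.concatenate([logits, np.full((len(logits), 1), -1e9, dtype=logits.dtype)], axis=1)
    loss, grad = supervised_loss_logits(padded, y)
    model.net.backward(grad[:, : model.n_classes].astype(np.float32))
    if grad_clip:
        clip_grad_norm(model.param_layers(), grad_clip)
    opt.step()
    return loss


def supervised_baseline(labeled_subset: Sequence[Sample], val_set: Sequence[Sample],
                        test_set: Sequence[Sample], config: GanConfig,
                        return_curve: bool = False):
    """Train the small CNN on labeled data only; return test SCA (%).

    Uses the same optimizer settings, batch size and epoch budget as the
    adversarial run it is compared against, and keeps the best-validation
    parameters.
    """
    if not labeled_subset:
        raise ConfigurationError("supervised baseline needs a non-empty labeled subset")
    ss = np.random.SeedSequence(config.seed + 2_000_003)
    rng_init, rng_batch = (np.random.default_rng(s) for s in ss.spawn(2))
    model = SmallCnn(config.n_real_classes, rng_init)
    opt = Adam(model.param_layers(), config.lr_d, config.beta1, config.beta2,
               weight_decay=config.weight_decay)
    x = _to_nchw(labeled_subset)
    y = labels_array(labeled_subset)
    x_val = _to_nchw(val_set)
    y_val = labels_array(val_set)
    m = min(config.batch_size, len(x))
    iters = max(1, int(np.ceil(len(x) / m)))
    best_acc, best_params, curve = -1.0, None, []
    for _ in range(config.epochs):
        for _ in range(iters):
            idx = _draw(rng_batch, len(x), m)
            _cross_entropy_step(model, opt, x[idx], y[idx], grad_clip=config.grad_clip)
        acc = float((model.predict(x_val) == y_val).mean() * 100.0)
        curve.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_params = [{n: p.copy() for n, p in l.params.items()} for l in model.param_layers()]
    restore_params([model], best_params)
    preds = model.predict(_to_nchw(test_set))
    sca = accuracy_from_cm(confusion(labels_array(test_set), preds, k=config.n_real_classes))
    return (sca, curve) if return_curve else sca


def sgan_test_accuracy(state: TrainState, test_set: Sequence[Sample]) -> float:
    """Test SSCA (%) of the best-validation discriminator checkpoint."""
    if state.best_params is not None:
        restore_params([state.generator, state.discriminator], state.best_params)
    from .training import predict_real_class  # local import to avoid cycle at module load

    preds = predict_real_class(state.discriminator, _to_nchw(test_set))
    return accuracy_from_cm(confusion(labels_array(test_set), preds,
                                      k=state.discriminator.n_classes))


# ---------------------------------------------------------------------------
# Label-rate comparison harness
# ---------------------------------------------------------------------------

ClassifierFn = Callable[[Sequence[Sample], Sequence[Sample], Sequence[Sample], GanConfig], float]


def _run_sgan(labeled, unlabeled, val_set, test_set, config) -> float:
    from .data_io import LabelRateSplit

    split = LabelRateSplit(rate=len(labeled) / max(1, len(labeled) + len(unlabeled)),
                           labeled=list(labeled), unlabeled=list(unlabeled))
    state = train(config, split, val_set)
    return sgan_test_accuracy(state, test_set)


def compare_label_rates(rates: Sequence[float], dataset: DatasetSplit, config: GanConfig,
                        seeds: Sequence[int] = (0, 1, 2),
                        extra_baselines: dict[str, ClassifierFn] | None = None,
                        csv_path: str | Path | None = None) -> pd.DataFrame:
    """Run the adversarial classifier (SSCA) and the supervised baseline (SCA)
    at each labeled rate on identical splits and seeds.

    Returns a tidy table with columns method, rate, seed, split, accuracy_pct.
    ``extra_baselines`` accepts external per-image classifiers with the same
    call signature as :func:`supervised_baseline` for parity runs.
    """
    rows = []
    for rate in rates:
        if not 0.0 < rate <= 1.0:
            raise ConfigurationError(f"labeled rate must be in (0, 1], got {rate}")
        for seed in seeds:
            lr_split = apply_label_rate(dataset.train, rate, seed=seed)
            run_cfg = config.model_copy(update={"seed": int(seed)})
            jobs: list[tuple[str, Callable[[], float]]] = [
                ("sgan", lambda: _run_sgan(lr_split.labeled, lr_split.unlabeled,
                                           dataset.val, dataset.test, run_cfg)),
                ("supervised_cnn", lambda: supervised_baseline(lr_split.labeled, dataset.val,
                                                               dataset.test, run_cfg)),
            ]
            for name, fn in extra_baselines.items() if extra_baselines else []:
                jobs.append((name, lambda fn=fn: fn(lr_split.labeled, dataset.val,
                                                    dataset.test, run_cfg)))
            for method, job in jobs:
                try:
                    acc = job()
                except Exception:
                    logger.exception("run failed: method=%s rate=%s seed=%s", method, rate, seed)
                    acc = np.nan
                rows.append({"method": method, "rate": rate, "seed": seed,
                             "split": "test", "accuracy_pct": acc})
    table = pd.DataFrame(rows, columns=["method", "rate", "seed", "split", "accuracy_pct"])
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


def plot_comparison(table: pd.DataFrame, path: str | Path) -> None:
    """Accuracy-vs-labeled-rate curves, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method, grp in table.groupby("method"):
        mean = grp.groupby("rate")["accuracy_pct"].mean()
        ax.plot(mean.index * 100, mean.values, marker="o", label=method)
    ax.set_xlabel("labeled rate (%)")
    ax.set_ylabel("test accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
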