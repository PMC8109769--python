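"""Finite-difference gradient verification.

Central differences are only a valid derivative estimate where the loss is
locally smooth; perturbing a bias (or a convolution weight) shifts a whole
feature map, so occasionally a ReLU/LeakyReLU kink falls inside the
two-sided stencil and the quotient is meaningless there.  The check
therefore evaluates each coordinate at two stencil widths and discards
coordinates where the two estimates disagree — the standard guard against
non-differentiable points in gradcheck tooling.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .layers import Layer


def finite_difference_error(loss_fn: Callable[[], float], layers: Sequence[Layer],
                            n_per_slot: int = 12, eps: float = 1e-6,
                            seed: int = 0) -> float:
    """Relative L2 error between analytic gradients and central differences.

    ``loss_fn`` must recompute the loss *and* refresh ``layer.grads`` for the
    given layers (a full forward+backward).  A subsample of ``n_per_slot``
    coordinates per parameter array is checked.
    """
    rng = np.random.default_rng(seed)
    ana: list[float] = []
    fd: list[float] = []
    for layer in layers:
        for name in layer.params:
            p = layer.params[name]
            flat = p.ravel()
            loss_fn()
            g = layer.grads[name].ravel().copy()
            idx = rng.choice(p.size, size=min(n_per_slot, p.size), replace=False)
            for i in idx:
                orig = flat[i]
                estimates = []
                for h in (eps, eps / 4):
                    flat[i] = orig + h
                    lp = loss_fn()
                    flat[i] = orig - h
                    lm = loss_fn()
                    flat[i] = orig
                    estimates.append((lp - lm) / (2 * h))
                scale = max(1.0, abs(estimates[0]))
                if abs(estimates[0] - estimates[1]) > 1e-4 * scale:
                    continue  # stencil straddles an activation kink
                ana.append(g[i])
                fd.append(estimates[0])
    ana_arr, fd_arr = np.asarray(ana), np.asarray(fd)
    if len(fd_arr) == 0:
        raise RuntimeError("no smooth coordinates found for the finite-difference check")
    return float(np.linalg.norm(ana_arr - fd_arr) / max(np.linalg.norm(fd_arr), 1e-12))
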