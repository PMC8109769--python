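"""Generator and discriminator architectures.

The generator maps a latent vector through a dense layer to a
``base x base`` grid of ``gen_width`` channels, then four fractionally
strided 5x5 convolutions each double the side while halving the channels,
ending in a 3-channel Tanh image of side ``base * 16`` (base 28 gives
448x448).  Hidden activations are ReLU.

The discriminator is fully convolutional: five stride-2 3x3 blocks
(LeakyReLU + dropout), a global average pool producing the feature vector
used for feature matching, and a linear head to K+1 logits — the K real
classes plus the "fake" class at index K.  Global pooling lets one
architecture serve any image side.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import nn
from .config import GanConfig, UPSAMPLE_STAGES
from .errors import ShapeError

DISC_BLOCKS = 5


class Generator:
    def __init__(self, config: GanConfig, rng: np.random.Generator, dtype=np.float32):
        self.dtype = np.dtype(dtype)
        c0 = config.gen_width
        base = config.base
        layers: list[nn.Layer] = [
            nn.Dense(config.latent_dim, base * base * c0, rng, dtype=dtype),
            nn.ReLU(),
            nn.Reshape((c0, base, base)),
        ]
        channels = [c0, c0 // 2, c0 // 4, c0 // 8, 3]
        for i in range(UPSAMPLE_STAGES):
            layers.append(nn.ConvTranspose2d(channels[i], channels[i + 1], k=config.gen_kernel, rng=rng, dtype=dtype))
            layers.append(nn.Tanh() if i == UPSAMPLE_STAGES - 1 else nn.ReLU())
        self.net = nn.Sequential(layers)
        self.latent_dim = config.latent_dim
        self.output_side = base * 2 ** UPSAMPLE_STAGES

    def forward(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        if z.ndim != 2 or z.shape[1] != self.latent_dim:
            raise ShapeError(f"expected noise of shape (n, {self.latent_dim}), got {z.shape}")
        return self.net.forward(z.astype(self.dtype, copy=False), train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def param_layers(self):
        return self.net.param_layers()

    @property
    def n_params(self) -> int:
        return self.net.n_params


class Discriminator:
    def __init__(self, config: GanConfig, rng: np.random.Generator, dtype=np.float32):
        self.dtype = np.dtype(dtype)
        w = config.disc_width
        channels = [3, w, 2 * w, 4 * w, 8 * w, 8 * w]
        layers: list[nn.Layer] = []
        for i in range(DISC_BLOCKS):
            layers.append(nn.Conv2d(channels[i], channels[i + 1], k=config.disc_kernel, stride=2, pad=1, rng=rng, dtype=dtype))
            layers.append(nn.LeakyReLU(config.leaky_slope))
            layers.append(nn.Dropout(config.dropout, rng))
        layers.append(nn.GlobalAvgPool())
        self.trunk = nn.Sequential(layers)
        self.feature_dim = channels[-1]
        self.n_classes = config.n_real_classes
        self.head = nn.Dense(self.feature_dim, config.n_real_classes + 1, rng, dtype=dtype)
        self.image_side = config.image_side

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """NCHW batch -> (logits (n, K+1), features (n, feature_dim))."""
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != x.shape[3]:
            raise ShapeError(f"expected (n, 3, side, side) input, got {x.shape}")
        if x.shape[2] != self.image_side:
            raise ShapeError(f"discriminator built for side {self.image_side}, got {x.shape[2]}")
        feats = self.trunk.forward(x.astype(self.dtype, copy=False), train=train)
        self._feats = feats
        return self.head.forward(feats), feats

    def backward(self, dlogits: np.ndarray, dfeatures: np.ndarray | None = None,
                 need_input_grad: bool = True) -> np.ndarray | None:
        dfeats = self.head.backward(dlogits)
        if dfeatures is not None:
            dfeats = dfeats + dfeatures
        return self.trunk.backward(dfeats, need_input_grad=need_input_grad)

    def param_layers(self):
        return self.trunk.param_layers() + [self.head]

    @property
    def n_params(self) -> int:
        return self.trunk.n_params + self.head.n_params


def build_generator(config: GanConfig, rng: np.random.Generator | None = None,
                    dtype=np.float32) -> Generator:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return Generator(config, rng, dtype=dtype)


def build_discriminator(config: GanConfig, rng: np.random.Generator | None = None,
                        dtype=np.float32) -> Discriminator:
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    return Discriminator(config, rng, dtype=dtype)


def architecture_summary(model: Generator | Discriminator) -> str:
    """Plain-text layer listing with parameter counts."""
    nets = [("trunk", model.trunk), ("head", model.head)] if isinstance(model, Discriminator) \
        else [("net", model.net)]
    lines = [f"{type(model).__name__}: {model.n_params} parameters"]
    for tag, net in nets:
        layers = net.layers if hasattr(net, "layers") else [net]
        for i, layer in enumerate(layers):
            shapes = ", ".join(f"{n}{list(p.shape)}" for n, p in layer.params.items())
            lines.append(f"  {tag}[{i}] {type(layer).__name__}"
                         + (f": {shapes} ({layer.n_params} params)" if shapes else ""))
    return "\n".join(lines)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate(generator: Generator, noise: np.ndarray) -> np.ndarray:
    """Map latent vectors to images in (-1, 1), returned as (n, side, side, 3)."""
    imgs = generator.forward(np.asarray(noise), train=False)
    return np.transpose(imgs, (0, 2, 3, 1))


def discriminate(discriminator: Discriminator, images: np.ndarray,
                 train: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(n, side, side, 3) images in [-1, 1] -> (class probabilities, features).

    Probabilities are length K+1 per image; index K is the fake class.
    p_real(x) = 1 - p[K].
    """
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if np.abs(images).max() > 1.0 + 1e-6:
        warnings.warn("discriminator input has values outside [-1, 1]; did you forget to normalize?")
    logits, feats = discriminator.forward(np.transpose(images, (0, 3, 1, 2)), train=train)
    return softmax(logits), feats
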