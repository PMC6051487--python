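"""The fully-convolutional plane-detection network family.

The flagship architecture ("sononet") is a VGG16-style feature extractor in
which every fully-connected layer is replaced by a 1x1 "adaptation"
convolution and the final max-pooling stage is dropped, so that the last
layer emits one spatial *class score map* ``F_k`` per class instead of a
scalar.  Four stride-2 poolings give the maps a resolution of 1/16th of the
input: a 224x288 frame yields 14x18 maps.  The per-class maps are aggregated
by their spatial mean into class scores ``a_k`` and passed through a softmax
to produce confidences ``c_k``.  Width-scaled members of the family
(SonoNet-64/-32/-16) share the block plan and differ only in channel count.

A second, shallower family member ("smallnet", six convolutions, no batch
normalisation) is kept for architecture comparisons.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import BatchNorm2d, Conv2d, Layer, MaxPool2d, ReLU

__all__ = [
    "NetworkConfig",
    "ClassScores",
    "Network",
    "build_network",
    "forward",
    "classify_frame",
    "save_network",
    "load_network",
]

#: stride-2 pooling stages in every variant -> total downsampling factor
DOWNSAMPLE = 16

# Block plan of the flagship family: (number of 3x3 convs, width multiplier).
# Pooling follows every block except the last.
_SONONET_BLOCKS = [(2, 1), (2, 2), (3, 4), (3, 8), (3, 8)]

# SmallNet plan: (ksize, width multiplier, pool after?).  Six convolutions,
# four poolings, same /16 output stride as the flagship family.
_SMALLNET_PLAN = [
    (7, 1, True),
    (5, 2, True),
    (3, 3, False),
    (3, 3, True),
    (3, 4, False),
    (3, 4, True),
]


@dataclass
class NetworkConfig:
    """Hyper-parameters defining one member of the network family.

    ``base_width`` is the channel count of the first convolution; the named
    clinical variants use 64, 32 and 16, but any positive width is accepted
    so that reduced desk-scale models can be trained.  ``adapt_batch_norm``
    controls whether the two adaptation convolutions are batch-normalised
    (independent of the feature extractor, so both conventions are
    testable); it defaults to following ``batch_norm``.
    """

    variant: str = "sononet"
    base_width: int = 32
    num_classes: int = 14
    batch_norm: bool | None = None
    adapt_batch_norm: bool | None = None
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("sononet", "smallnet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.base_width < 1:
            raise ValueError("base_width must be a positive integer")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.batch_norm is None:
            self.batch_norm = self.variant == "sononet"
        if self.adapt_batch_norm is None:
            self.adapt_batch_norm = self.batch_norm


@dataclass
class ClassScores:
    """Aggregated class evidence: pre-softmax scores and softmax confidences."""

    a: np.ndarray  # (K,) spatial means of the class score maps
    c: np.ndarray  # (K,) softmax confidences, sum to 1


def _softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    z = a - a.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Network:
    """A built network: an ordered layer stack ending in class score maps.

    ``layers[:adapt_start]`` is the feature extractor, the rest the
    adaptation head.  The mean-pool aggregation and softmax are applied
    functionally on top of the maps.
    """

    def __init__(self, config: NetworkConfig, layers: list[Layer],
                 adapt_start: int) -> None:
        self.config = config
        self.layers = layers
        self.adapt_start = adapt_start

    # -- forward ---------------------------------------------------------

    def forward_maps(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Run a ``(N, C, H, W)`` batch to class score maps ``(N, K, H', W')``."""
        if x.ndim != 4:
            raise ValueError("expected a (N, C, H, W) batch")
        h, w = x.shape[2], x.shape[3]
        if h % DOWNSAMPLE or w % DOWNSAMPLE:
            raise ValueError(
                f"input height and width must be divisible by {DOWNSAMPLE}, "
                f"got {h}x{w}")
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward_from_maps(self, dmaps: np.ndarray, guided: bool = False,
                           guided_adaptation: bool = True) -> np.ndarray:
        """Propagate an error field seeded at the class score maps back to
        the input pixels.

        ``guided`` switches on guided gating at every rectifier;
        ``guided_adaptation=False`` restricts gating to the feature
        extractor's rectifiers.
        """
        g = dmaps
        for i in range(len(self.layers) - 1, -1, -1):
            use_guided = guided and (guided_adaptation or i < self.adapt_start)
            g = self.layers[i].backward(g, guided=use_guided)
        return g

    # -- parameters ------------------------------------------------------

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    @property
    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def build_network(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> Network:
    """Instantiate a network with variance-scaling initial weights."""
    rng = np.random.default_rng(0) if rng is None else rng
    layers: list[Layer] = []
    bw = config.base_width

    def conv_block(in_ch, out_ch, ksize, with_bn, with_relu=True):
        layers.append(Conv2d(in_ch, out_ch, ksize, rng=rng))
        if with_bn:
            layers.append(BatchNorm2d(out_ch))
        if with_relu:
            layers.append(ReLU())

    in_ch = config.in_channels
    if config.variant == "sononet":
        for b, (n_convs, mult) in enumerate(_SONONET_BLOCKS):
            out_ch = bw * mult
            for _ in range(n_convs):
                conv_block(in_ch, out_ch, 3, config.batch_norm)
                in_ch = out_ch
            if b < len(_SONONET_BLOCKS) - 1:
                layers.append(MaxPool2d())
        adapt_in, adapt_mid = bw * 8, bw * 4
    else:  # smallnet
        for ksize, mult, pool in _SMALLNET_PLAN:
            out_ch = bw * mult
            conv_block(in_ch, out_ch, ksize, config.batch_norm)
            in_ch = out_ch
            if pool:
                layers.append(MaxPool2d())
        adapt_in, adapt_mid = bw * 4, bw * 2

    adapt_start = len(layers)
    # Adaptation head: 1x1 conv -> rectifier, then a linear 1x1 conv into the
    # mean pool so the maps carry signed class evidence.
    conv_block(adapt_in, adapt_mid, 1, config.adapt_batch_norm)
    layers.append(Conv2d(adapt_mid, config.num_classes, 1, rng=rng))
    if config.adapt_batch_norm:
        layers.append(BatchNorm2d(config.num_classes))
    return Network(config, layers, adapt_start)


def _as_batch(frame) -> np.ndarray:
    """Accept a Frame, a 2-D array, or a ready (N, C, H, W) batch."""
    pixels = getattr(frame, "pixels", frame)
    x = np.asarray(pixels, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim != 4:
        raise ValueError("expected a 2-D frame or a (N, C, H, W) batch")
    return x


def forward(net: Network, frame) -> tuple[np.ndarray, ClassScores]:
    """Inference-mode forward pass of one frame.

    Returns the class score maps ``(K, H', W')`` together with the mean
    aggregated scores ``a`` and softmax confidences ``c``.
    """
    x = _as_batch(frame)
    maps = net.forward_maps(x, train=False)
    a = maps.mean(axis=(2, 3))
    c = _softmax(a, axis=1)
    return maps[0], ClassScores(a=a[0], c=c[0])


def classify_frame(net: Network, frame) -> tuple[int, float]:
    """Predict the class of one frame: argmax confidence, lowest index on ties."""
    _, scores = forward(net, frame)
    label = int(np.argmax(scores.c))  # argmax takes the first maximum
    return label, float(scores.c[label])


# -- checkpoints ---------------------------------------------------------

def _state_arrays(net: Network) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(net.layers):
        for name, p in layer.params.items():
            arrays[f"layer{i:03d}.{name}"] = p
        if isinstance(layer, BatchNorm2d):
            arrays[f"layer{i:03d}.running_mean"] = layer.running_mean
            arrays[f"layer{i:03d}.running_var"] = layer.running_var
    return arrays


def save_network(net: Network, path) -> None:
    """Write a single-file checkpoint: config JSON + weight arrays (npz)."""
    arrays = _state_arrays(net)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(net.config)))
        zf.writestr("weights.npz", buf.getvalue())


def load_network(path) -> Network:
    """Rebuild a network from :func:`save_network` output."""
    with zipfile.ZipFile(path) as zf:
        config = NetworkConfig(**json.loads(zf.read("config.json")))
        data = np.load(io.BytesIO(zf.read("weights.npz")))
        net = build_network(config)
        for i, layer in enumerate(net.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{i:03d}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = data[f"layer{i:03d}.running_mean"]
                layer.running_var = data[f"layer{i:03d}.running_var"]
            layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}
    return net
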