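"""The 9-layer depthwise-separable-convolution U-Net classifier.

Architecture
------------
Nine DSConv layers in a U shape: four encoder layers, one bottleneck, four
decoder layers.  Each DSConv block is a per-channel 3x3 depthwise
convolution (stride 1, padding 1, no bias), a 1x1 pointwise convolution
mixing channels, batch normalization, and ReLU.  After each encoder block a
2x2 average pool halves the spatial dimensions; the encoder channel
schedule is C0, 2*C0, 4*C0, 8*C0 and the bottleneck expands 8*C0 to 16*C0.
Each decoder level bilinearly upsamples 2x, concatenates the matching
encoder feature map (skip connection), and applies a DSConv that reduces
channels back toward C0 (16*C0+8*C0 -> 8*C0, ..., 2*C0+C0 -> C0).  A global
average pool followed by a fully connected layer maps the final C0-channel
map to ``num_classes`` logits, so the network accepts any input whose sides
are divisible by 2**4.

The per-layer parameter count of a DSConv block is
``Cin * K**2 + Cin * Cout + 2 * Cout`` (depthwise + pointwise + BN scale and
shift), versus ``Cin * Cout * K**2`` for a standard convolution.

Public functional operations (``dsconv_block``, ``downsample_avgpool``,
``upsample_bilinear``, ``concat_skip``, ``classify_head``) state their
contracts on single H x W x C feature maps; internally everything runs
NCHW batched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import numpy as np

from ._nn import (AvgPool2, BatchNorm, BilinearUp2, Dense,
                  DepthwiseConv3x3, GlobalAvgPool, PointwiseConv, ReLU)
from .errors import ConfigError, ShapeError

__all__ = [
    "ModelConfig",
    "DSConvBlock",
    "DSUNetClassifier",
    "dsconv_block",
    "downsample_avgpool",
    "upsample_bilinear",
    "concat_skip",
    "classify_head",
    "count_parameters",
    "dsconv_param_count",
    "standard_conv_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

ENCODER_DEPTH = 4


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    base_channels (C0) is the width of the first encoder layer; the
    bottleneck is always 16x that width, but C0 itself is a free choice,
    configurable with default 16.
    """

    in_channels: int = 3
    base_channels: int = 16
    num_classes: int = 2
    kernel_size: int = 3
    input_size: int = 256

    def __post_init__(self):
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.kernel_size != 3:
            raise ConfigError("only 3x3 depthwise kernels are supported")
        if self.input_size % (2 ** ENCODER_DEPTH) != 0:
            raise ConfigError(
                f"input_size must be divisible by {2 ** ENCODER_DEPTH}")


class DSConvBlock:
    """Depthwise conv -> pointwise conv -> batch norm -> ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        self.depthwise = DepthwiseConv3x3(c_in, rng)
        self.pointwise = PointwiseConv(c_in, c_out, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()

    def params(self):
        return (self.depthwise.params() + self.pointwise.params()
                + self.bn.params())

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ShapeError(
                f"DSConv block expects {self.c_in} channels, got {x.shape[1]}")
        y = self.depthwise.forward(x, training)
        y = self.pointwise.forward(y, training)
        y = self.bn.forward(y, training)
        return self.relu.forward(y, training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu.backward(gy)
        g = self.bn.backward(g)
        g = self.pointwise.backward(g)
        return self.depthwise.backward(g)

    def n_params(self) -> int:
        return dsconv_param_count(self.c_in, self.c_out)


def dsconv_param_count(c_in: int, c_out: int, k: int = 3) -> int:
    """Closed-form trainable-parameter count of one DSConv block."""
    return c_in * k * k + c_in * c_out + 2 * c_out


def standard_conv_param_count(c_in: int, c_out: int, k: int = 3) -> int:
    """Parameter count of a standard KxK convolution (no bias) plus BN."""
    return c_in * c_out * k * k + 2 * c_out


# ---------------------------------------------------------------------------
# functional single-image operations (H x W x C semantics)
# ---------------------------------------------------------------------------

def _to_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ShapeError(f"expected an H x W x C feature map, got shape {x.shape}")
    return np.transpose(x, (2, 0, 1))[None]


def _to_hwc(x: np.ndarray) -> np.ndarray:
    return np.transpose(x[0], (1, 2, 0))


def dsconv_block(x: np.ndarray, block: DSConvBlock, training: bool = False) -> np.ndarray:
    """Apply one DSConv block to an H x W x C feature map."""
    return _to_hwc(block.forward(_to_nchw(x), training))


def downsample_avgpool(x: np.ndarray) -> np.ndarray:
    """2x2 mean pooling of an H x W x C map; H and W must be even."""
    return _to_hwc(AvgPool2().forward(_to_nchw(x)))


def upsample_bilinear(x: np.ndarray) -> np.ndarray:
    """2x bilinear upsampling of an H x W x C map (constants preserved)."""
    return _to_hwc(BilinearUp2().forward(_to_nchw(x)))


def concat_skip(up: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Concatenate two H x W x C maps along channels (`up` first)."""
    up = np.asarray(up)
    enc = np.asarray(enc)
    if up.shape[:2] != enc.shape[:2]:
        raise ShapeError(
            f"spatial mismatch: {up.shape[:2]} vs {enc.shape[:2]}")
    return np.concatenate([up, enc], axis=2)


def classify_head(ydec: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Global average pool then affine map to class scores.

    ``weight`` has shape (C, num_classes), ``bias`` shape (num_classes,).
    """
    ydec = np.asarray(ydec, dtype=np.float64)
    if ydec.ndim != 3 or ydec.shape[2] != weight.shape[0]:
        raise ShapeError("head dimensions inconsistent with feature map")
    pooled = ydec.mean(axis=(0, 1))
    return pooled @ weight + bias


# ---------------------------------------------------------------------------
# the full classifier
# ---------------------------------------------------------------------------

class DSUNetClassifier:
    """Encoder/decoder DSConv classifier with exactly nine DSConv layers."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c0 = config.base_channels
        cin = config.in_channels
        enc_out = [c0 * (2 ** i) for i in range(ENCODER_DEPTH)]        # C0..8C0
        self.encoder = []
        prev = cin
        for c in enc_out:
            self.encoder.append(DSConvBlock(prev, c, rng))
            prev = c
        self.pools = [AvgPool2() for _ in range(ENCODER_DEPTH)]
        self.bottleneck = DSConvBlock(enc_out[-1], enc_out[-1] * 2, rng)   # 8C0 -> 16C0
        self.ups = [BilinearUp2() for _ in range(ENCODER_DEPTH)]
        self.decoder = []
        prev = enc_out[-1] * 2
        for c_skip in reversed(enc_out):                                # 8C0..C0
            self.decoder.append(DSConvBlock(prev + c_skip, c_skip, rng))
            prev = c_skip
        self.gap = GlobalAvgPool()
        self.head = Dense(c0, config.num_classes, rng)
        self._split_channels = None

    # -- structure ---------------------------------------------------------

    def dsconv_blocks(self) -> list[DSConvBlock]:
        return self.encoder + [self.bottleneck] + self.decoder

    def encoder_channels(self) -> list[int]:
        return [b.c_out for b in self.encoder]

    def params(self):
        out = []
        for b in self.dsconv_blocks():
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map an (N, C, H, W) batch to (N, num_classes) logits."""
        if x.ndim != 4:
            raise ShapeError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ShapeError("input spatial size must be divisible by 16")
        skips = []
        for block, pool in zip(self.encoder, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        split_channels = []
        for up, skip, block in zip(self.ups, reversed(skips), self.decoder):
            x = up.forward(x, training)
            split_channels.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x, training)
        pooled = self.gap.forward(x, training)
        self._split_channels = split_channels
        return self.head.forward(pooled, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.gap.backward(g)
        skip_grads = []
        for up, block, nc in zip(reversed(self.ups), reversed(self.decoder),
                                 reversed(self._split_channels)):
            g = block.backward(g)
            skip_grads.append(g[:, nc:])
            g = up.backward(g[:, :nc])
        g = self.bottleneck.backward(g)
        # skip_grads were collected decoder-last first, i.e. in encoder order
        for i in range(ENCODER_DEPTH - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.encoder[i].backward(g)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic class predictions using running BN statistics."""
        return np.argmax(self.forward(x, training=False), axis=1)

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, b in enumerate(self.dsconv_blocks()):
            state[f"block{i}.dw"] = b.depthwise.kernel.value
            state[f"block{i}.pw"] = b.pointwise.kernel.value
            state[f"block{i}.bn_gamma"] = b.bn.gamma.value
            state[f"block{i}.bn_beta"] = b.bn.beta.value
            state[f"block{i}.bn_mean"] = b.bn.running_mean
            state[f"block{i}.bn_var"] = b.bn.running_var
        state["head.weight"] = self.head.weight.value
        state["head.bias"] = self.head.bias.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, b in enumerate(self.dsconv_blocks()):
            b.depthwise.kernel.value[...] = state[f"block{i}.dw"]
            b.pointwise.kernel.value[...] = state[f"block{i}.pw"]
            b.bn.gamma.value[...] = state[f"block{i}.bn_gamma"]
            b.bn.beta.value[...] = state[f"block{i}.bn_beta"]
            b.bn.running_mean[...] = state[f"block{i}.bn_mean"]
            b.bn.running_var[...] = state[f"block{i}.bn_var"]
        self.head.weight.value[...] = state["head.weight"]
        self.head.bias.value[...] = state["head.bias"]

    def architecture_hash(self) -> str:
        sig = json.dumps(sorted((k, list(v.shape)) for k, v in
                                self.state_dict().items()))
        return hashlib.sha256(sig.encode()).hexdigest()[:16]


def count_parameters(model: DSUNetClassifier) -> int:
    """Exact trainable-parameter count (enumerated over arrays)."""
    return sum(p.value.size for p in model.params())


def save_checkpoint(model: DSUNetClassifier, path: str | os.PathLike,
                    seed: int | None = None) -> None:
    """Serialize weights to ``<path>`` (npz) with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {
        "in_channels": model.config.in_channels,
        "base_channels": model.config.base_channels,
        "num_classes": model.config.num_classes,
        "kernel_size": model.config.kernel_size,
        "input_size": model.config.input_size,
        "architecture_hash": model.architecture_hash(),
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | os.PathLike) -> DSUNetClassifier:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(in_channels=sidecar["in_channels"],
                         base_channels=sidecar["base_channels"],
                         num_classes=sidecar["num_classes"],
                         kernel_size=sidecar["kernel_size"],
                         input_size=sidecar["input_size"])
    model = DSUNetClassifier(config)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    if model.architecture_hash() != sidecar["architecture_hash"]:
        raise ConfigError("checkpoint architecture hash mismatch")
    return model
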