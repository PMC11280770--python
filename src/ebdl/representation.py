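"""Shared encoder: sub-views to unit-norm embeddings.

Every sub-view passes through the *same* encoder — a convolutional backbone
producing a D-dimensional feature vector, then a projection head
(Linear D->H, batch norm, ReLU, Linear H->L) — and is L2-normalized onto the
unit hypersphere.  Sharing one encoder guarantees all sub-views land in a
common representation space, which the proxy-based contrastive loss relies
on; gradients flow through the encoder back into the filter parameters.

The default backbone is a small three-block CNN that trains on a CPU in
minutes.  The projection-head widths default to the 512->512->128
configuration used with a ResNet-18 backbone; a pretrained ResNet-18 is
available only when torch/torchvision are installed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm1d, Conv2d, Linear, Module, ReLU
from .subband import SubViewSet

__all__ = ["EncoderSpec", "EmbeddingSet", "TinyCNN", "Encoder",
           "make_default_backbone", "build_encoder", "encode_subviews",
           "l2_normalize"]


def l2_normalize(x: Tensor) -> Tensor:
    """Project row vectors onto the unit hypersphere (differentiable)."""
    sq = (x * x).sum(axis=1, keepdims=True)
    return x / ((sq + 1e-24) ** 0.5)


class TinyCNN(Module):
    """Three conv/ReLU/avg-pool blocks plus global average pooling.

    Input (N, C, H, W) with H, W divisible by 8; output (N, D) where D is
    the final channel count.  Small enough to train on one CPU core.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 1,
                 channels: tuple[int, int, int] = (8, 16, 32)):
        super().__init__()
        c1, c2, c3 = channels
        self.conv1 = Conv2d(in_channels, c1, 3, rng, padding=1)
        self.conv2 = Conv2d(c1, c2, 3, rng, padding=1)
        self.conv3 = Conv2d(c2, c3, 3, rng, padding=1)
        self.feature_dim = c3

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x).relu().avg_pool2d(2)
        x = self.conv2(x).relu().avg_pool2d(2)
        x = self.conv3(x).relu().avg_pool2d(2)
        return x.mean(axis=(2, 3))  # global average pool -> (N, D)


@dataclass
class EncoderSpec:
    """Configuration of the shared encoder.

    ``backbone_kind`` selects the image-to-feature map; ``head_hidden`` and
    ``embed_dim`` size the projection head.  ``replicate_channels`` feeds a
    1-channel spectrogram to a 3-channel backbone by replication.
    """

    backbone_kind: str = "tiny_cnn"
    feature_dim: int = 512
    head_hidden: int = 512
    embed_dim: int = 128
    replicate_channels: bool = False
    tiny_channels: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self):
        if min(self.feature_dim, self.head_hidden, self.embed_dim) <= 0:
            raise ValueError("feature_dim, head_hidden and embed_dim must be positive")


def make_default_backbone(kind: str, rng: np.random.Generator | None = None,
                          spec: EncoderSpec | None = None) -> Module:
    """Build a backbone by name: ``tiny_cnn`` (default, CPU-friendly) or
    ``resnet18_pretrained`` (requires torch + torchvision)."""
    if kind == "tiny_cnn":
        rng = rng if rng is not None else np.random.default_rng(0)
        channels = spec.tiny_channels if spec is not None else (8, 16, 32)
        in_ch = 3 if (spec is not None and spec.replicate_channels) else 1
        return TinyCNN(rng, in_channels=in_ch, channels=channels)
    if kind == "resnet18_pretrained":
        raise ImportError(
            "the resnet18_pretrained backbone needs torch and torchvision "
            "with downloaded weights; install them and wrap the model as an "
            "ebdl.nn.Module, or use backbone_kind='tiny_cnn'")
    raise ValueError(f"unknown backbone kind {kind!r}")


class Encoder(Module):
    """Backbone + projection head + L2 normalization."""

    def __init__(self, backbone: Module, feature_dim: int, head_hidden: int,
                 embed_dim: int, rng: np.random.Generator,
                 replicate_channels: bool = False):
        super().__init__()
        self.backbone = backbone
        self.fc1 = Linear(feature_dim, head_hidden, rng)
        self.bn = BatchNorm1d(head_hidden)
        self.fc2 = Linear(head_hidden, embed_dim, rng)
        self.relu = ReLU()
        self.replicate_channels = replicate_channels
        self.embed_dim = embed_dim

    def forward(self, views: Tensor) -> Tensor:
        """(N, 1, T, F) sub-views -> (N, L) unit-norm embeddings."""
        if self.replicate_channels:
            views = views * np.ones((1, 3, 1, 1))
        feats = self.backbone(views)
        z = self.fc2(self.relu(self.bn(self.fc1(feats))))
        z = l2_normalize(z)
        if not np.all(np.isfinite(z.data)):
            bad = int(np.sum(~np.isfinite(z.data)))
            raise FloatingPointError(
                f"encoder produced {bad} non-finite embedding entries "
                f"(input range [{views.data.min():.3g}, {views.data.max():.3g}])")
        return z


def build_encoder(spec: EncoderSpec, rng: np.random.Generator) -> Encoder:
    backbone = make_default_backbone(spec.backbone_kind, rng, spec)
    feature_dim = getattr(backbone, "feature_dim", spec.feature_dim)
    return Encoder(backbone, feature_dim, spec.head_hidden, spec.embed_dim, rng,
                   replicate_channels=spec.replicate_channels)


@dataclass
class EmbeddingSet:
    """M unit-norm L-dimensional vectors, one per sub-view."""

    z: np.ndarray  # (M, L)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2:
            raise ValueError("z must be an M x L matrix")
        norms = np.linalg.norm(self.z, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("embeddings must be unit-norm (within 1e-6)")

    @property
    def n_views(self) -> int:
        return self.z.shape[0]


def encode_subviews(views: SubViewSet, encoder: Encoder) -> EmbeddingSet:
    """Encode the M sub-views of one sample (deterministic evaluation mode)."""
    was_training = encoder.training
    encoder.eval()
    try:
        m, t, f = views.views.shape
        z = encoder(Tensor(views.views.reshape(m, 1, t, f)))
    finally:
        encoder.train(was_training)
    return EmbeddingSet(z=z.data)
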