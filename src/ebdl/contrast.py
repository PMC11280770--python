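"""Proxy-based sub-view contrastive learning.

Each of the M sub-views keeps one trainable proxy vector per class on the
unit hypersphere (an M x C bank).  For the embedding z_i of sub-view i of a
sample with class c, the proxies partition into four groups:

* p-tilde — same view, same class (the positive);
* A(i)    — same view, other classes (repelled);
* B(i)    — other views, same class (their similarity is clamped by a ReLU,
            so they are only repelled while positively correlated — this
            pushes different sub-views to encode *different* features);
* others  — different view and class, excluded from the loss entirely.

The per-view loss term is

    -log[ e^{p~.z_i} / ( e^{p~.z_i} + sum_{p in A} e^{p.z_i}
                                     + sum_{p in B} e^{ReLU(p.z_i)} ) ]

and the sample loss is the mean over views; all similarities are dot
products of unit vectors (cosine similarity), with no temperature.

At test time each z_i is compared only to the proxies of its own sub-view;
the class of the globally most similar proxy across all views wins (the
discriminative evidence may live in a single sub-view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor
from .nn import Module
from .representation import EmbeddingSet

__all__ = ["ProxyBank", "ProxyPartition", "SCLossValue",
           "init_proxies", "partition_proxies", "scloss", "scloss_batch",
           "predict"]


class ProxyBank(Module):
    """M x C trainable class proxies of dimension L.

    Stored unconstrained and normalized at use time, so any optimizer step
    keeps the unit-norm contract wherever similarities are computed.
    """

    def __init__(self, p: np.ndarray):
        super().__init__()
        p = np.asarray(p, dtype=np.float64)
        if p.ndim != 3:
            raise ValueError("proxy bank must be an M x C x L array")
        self.p = Parameter(p)

    @property
    def n_views(self) -> int:
        return self.p.shape[0]

    @property
    def n_classes(self) -> int:
        return self.p.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.p.shape[2]

    def normalized_tensor(self) -> Tensor:
        sq = (self.p * self.p).sum(axis=2, keepdims=True)
        return self.p / ((sq + 1e-24) ** 0.5)

    def normalized(self) -> np.ndarray:
        return self.p.data / (np.linalg.norm(self.p.data, axis=2, keepdims=True) + 1e-24)


def init_proxies(m: int, c: int, l: int, seed: int = 1024) -> ProxyBank:
    """Isotropic Gaussian draws normalized to the unit sphere, reproducible."""
    if min(m, c, l) < 1:
        raise ValueError("M, C and L must all be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((m, c, l))
    p /= np.linalg.norm(p, axis=2, keepdims=True)
    return ProxyBank(p)


@dataclass
class ProxyPartition:
    """Index view of the four proxy groups for one (view, class) pair."""

    same_view_same_class: tuple[int, int]
    same_view_other_classes: list[tuple[int, int]]
    other_views_same_class: list[tuple[int, int]]
    excluded: list[tuple[int, int]]


def partition_proxies(bank: ProxyBank, view_index: int, class_label: int) -> ProxyPartition:
    m, c = bank.n_views, bank.n_classes
    if not (0 <= view_index < m and 0 <= class_label < c):
        raise IndexError("view_index or class_label out of range")
    return ProxyPartition(
        same_view_same_class=(view_index, class_label),
        same_view_other_classes=[(view_index, k) for k in range(c) if k != class_label],
        other_views_same_class=[(j, class_label) for j in range(m) if j != view_index],
        excluded=[(j, k) for j in range(m) for k in range(c)
                  if j != view_index and k != class_label],
    )


@dataclass
class SCLossValue:
    """Loss of one sample: overall value and the M per-view terms."""

    value: float
    per_view_terms: np.ndarray

    def __post_init__(self):
        self.per_view_terms = np.asarray(self.per_view_terms, dtype=np.float64)


def scloss_batch(z: Tensor, bank: ProxyBank, labels: np.ndarray
                 ) -> tuple[Tensor, Tensor]:
    """Differentiable batch loss.

    z: (B, M, L) unit-norm embeddings; labels: (B,) ints.
    Returns (scalar mean loss, (B, M) per-view terms), both on the tape.
    """
    b, m, l = z.shape
    if (m, l) != (bank.n_views, bank.embed_dim):
        raise ValueError(
            f"embedding set ({m} views, dim {l}) does not match proxy bank "
            f"({bank.n_views} views, dim {bank.embed_dim})")
    labels = np.asarray(labels, dtype=np.intp)
    if labels.shape != (b,) or labels.min() < 0 or labels.max() >= bank.n_classes:
        raise ValueError("labels must be a (B,) int array within [0, C)")
    pn = bank.normalized_tensor()                      # (M, C, L)

    # same-view similarities S[b,i,c] = z[b,i] . pn[i,c]
    zt = z.transpose(1, 0, 2)                          # (M, B, L)
    s = zt.matmul(pn.transpose(0, 2, 1))               # (M, B, C)
    s = s.transpose(1, 0, 2)                           # (B, M, C)

    bi = np.arange(b)[:, None]
    vi = np.arange(m)[None, :]
    pos = s[bi, vi, labels[:, None]]                   # (B, M) p~ . z_i

    # cross-view similarities X[b,i,j] = z[b,i] . pn[j, y_b]
    p_y = pn[:, labels, :]                             # (M, B, L)
    x = z.matmul(p_y.transpose(1, 2, 0))               # (B, M, M)

    exp_s_sum = s.exp().sum(axis=2)                    # (B, M): positive + A terms
    a_sum = exp_s_sum - pos.exp()
    relu_x = x.relu()
    b_sum = relu_x.exp().sum(axis=2) - relu_x[bi, vi, vi].exp()

    denom = pos.exp() + a_sum + b_sum
    per_view = denom.log() - pos                       # (B, M)
    return per_view.mean(), per_view


def scloss(z: EmbeddingSet, bank: ProxyBank, class_label: int) -> SCLossValue:
    """Sub-view contrastive loss of a single sample (numerical interface)."""
    loss, per_view = scloss_batch(Tensor(z.z[None, :, :]), bank,
                                  np.array([class_label]))
    return SCLossValue(value=float(loss.data), per_view_terms=per_view.data[0])


def predict(z: EmbeddingSet, bank: ProxyBank) -> int:
    """Nearest-proxy classification across sub-views.

    Each embedding is compared to its own view's proxies only; the class of
    the single most similar proxy over all views is returned, ties broken
    toward the lowest class index.
    """
    if z.n_views != bank.n_views or z.z.shape[1] != bank.embed_dim:
        raise ValueError("embedding set does not match proxy bank")
    sims = np.einsum("il,icl->ic", z.z, bank.normalized())   # (M, C)
    best_per_class = sims.max(axis=0)                        # (C,)
    return int(np.argmax(best_per_class))                    # first max -> lowest class


def predict_batch(z: np.ndarray, bank: ProxyBank) -> np.ndarray:
    """Vectorized ``predict`` for a (B, M, L) block of embeddings."""
    sims = np.einsum("bil,icl->bic", z, bank.normalized())
    return sims.max(axis=1).argmax(axis=1)
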