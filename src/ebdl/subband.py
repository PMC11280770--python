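"""Adaptive sub-band filtering with trainable generalized-Gaussian profiles.

Each filter scales a time-frequency matrix per frequency bin by

    g(f; mu, sigma, beta) = exp( - (|f - mu| / sigma)^beta )

on the normalized frequency axis [-1, 1].  ``mu`` sets the center frequency,
``sigma`` the bandwidth, and the fixed even shape exponent ``beta`` (default
8) the steepness of the band edges — a near-flat top with rapidly decaying
sides.  ``mu`` and ``sigma`` are trained by gradient descent together with
the encoder, so the model discovers where the class-discriminative sub-bands
lie; they are deliberately left unconstrained (learned values can leave
[-1, 1] and sigma can go negative, which the even exponent renders harmless).

Applying M filters to one TFR yields M "sub-views", each the input rescaled
toward zero outside that filter's band.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .autodiff import Parameter, Tensor
from .nn import Module
from .tfr_pipeline import TFRSample

__all__ = ["SubBandFilter", "FilterBank", "SubViewSet",
           "gaussian_scale", "init_filter_bank", "apply_filters",
           "uniform_interior_centers"]


def gaussian_scale(fb, mu, sigma, beta: int = 8):
    """Generalized-Gaussian scaling factor at normalized frequency ``fb``.

    Vectorized over ``fb``.  Values lie in (0, 1] with the peak value 1
    attained exactly at ``fb == mu``; the sign of ``sigma`` is irrelevant
    for even ``beta``.
    """
    if sigma == 0:
        raise ValueError("sigma must be nonzero")
    if beta <= 0 or beta % 2:
        raise ValueError("beta must be a positive even integer")
    fb = np.asarray(fb, dtype=np.float64)
    return np.exp(-(np.abs(fb - mu) / np.abs(sigma)) ** beta)


@dataclass
class SubBandFilter:
    """One trainable band profile: location ``mu``, scale ``sigma``, fixed shape."""

    mu: float
    sigma: float
    beta: int = 8

    def response(self, freq_axis: np.ndarray) -> np.ndarray:
        return gaussian_scale(freq_axis, self.mu, self.sigma, self.beta)


@dataclass
class SubViewSet:
    """M filtered copies of one TFR, each with the source's T x F shape."""

    views: np.ndarray  # (M, T, F)

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=np.float64)
        if self.views.ndim != 3:
            raise ValueError("views must be an M x T x F array")

    def __len__(self) -> int:
        return self.views.shape[0]


def uniform_interior_centers(m: int) -> np.ndarray:
    """Centers -1 + 2i/(M+1), i=1..M: uniform along the axis, endpoints excluded."""
    return -1.0 + 2.0 * np.arange(1, m + 1) / (m + 1)


class FilterBank(Module):
    """M generalized-Gaussian filters over one normalized frequency axis.

    ``mu`` and ``sigma`` are autodiff parameters so the bank can sit at the
    front of a trained model; the numpy-facing helpers (``responses``,
    ``as_filters``) read their current values.
    """

    def __init__(self, mu: np.ndarray, sigma: np.ndarray, freq_axis: np.ndarray,
                 beta: int = 8):
        super().__init__()
        mu = np.atleast_1d(np.asarray(mu, dtype=np.float64))
        sigma = np.atleast_1d(np.asarray(sigma, dtype=np.float64))
        if mu.shape != sigma.shape or mu.ndim != 1 or mu.size < 1:
            raise ValueError("mu and sigma must be equal-length 1-D arrays, M >= 1")
        if beta <= 0 or beta % 2:
            raise ValueError("beta must be a positive even integer")
        self.mu = Parameter(mu)
        self.sigma = Parameter(sigma)
        self.freq_axis = np.asarray(freq_axis, dtype=np.float64)
        self.beta = beta

    @property
    def n_filters(self) -> int:
        return self.mu.data.size

    def responses_tensor(self) -> Tensor:
        """(M, F) filter curves as a differentiable tensor.

        For even beta, |f-mu|^beta == ((f-mu)^2)^(beta/2), which keeps the
        graph smooth and lets a negative sigma pass through squaring.
        """
        f = Tensor(self.freq_axis)  # (F,)
        mu = self.mu.reshape(-1, 1)
        sigma = self.sigma.reshape(-1, 1)
        d = (f - mu)  # (M, F) by broadcasting
        q = (d * d) / (sigma * sigma)
        return (-(q ** (self.beta // 2))).exp()

    def responses(self) -> np.ndarray:
        """(M, F) filter curves evaluated on the bank's frequency axis."""
        return np.stack([flt.response(self.freq_axis) for flt in self.as_filters()])

    def as_filters(self) -> list[SubBandFilter]:
        return [SubBandFilter(float(m), float(s), self.beta)
                for m, s in zip(self.mu.data, self.sigma.data)]

    def filter_batch(self, x: Tensor) -> Tensor:
        """Apply all filters to a batch: (B, T, F) -> (B, M, T, F)."""
        g = self.responses_tensor()  # (M, F)
        xb = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        return xb * g.reshape(1, self.n_filters, 1, g.shape[1])

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "beta": self.beta,
            "freq_axis": self.freq_axis.tolist(),
            "filters": [{"mu": float(m), "sigma": float(s)}
                        for m, s in zip(self.mu.data, self.sigma.data)],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FilterBank":
        obj = json.loads(text)
        return cls(mu=np.array([f["mu"] for f in obj["filters"]]),
                   sigma=np.array([f["sigma"] for f in obj["filters"]]),
                   freq_axis=np.array(obj["freq_axis"]), beta=int(obj["beta"]))

    def plot(self, ax=None):
        """Line plot of the M filter curves (matplotlib, lazy import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        for i, curve in enumerate(self.responses()):
            ax.plot(self.freq_axis, curve, label=f"filter {i + 1}")
        ax.set_xlabel("normalized frequency")
        ax.set_ylabel("scaling factor")
        ax.legend()
        return ax


def init_filter_bank(m: int, freq_axis: np.ndarray, beta: int = 8) -> FilterBank:
    """Initial bank: centers uniformly spaced in the interior of [-1, 1],
    all scales set to 1."""
    if m < 1:
        raise ValueError("need at least one filter")
    return FilterBank(mu=uniform_interior_centers(m), sigma=np.ones(m),
                      freq_axis=np.asarray(freq_axis, dtype=np.float64), beta=beta)


def apply_filters(x: TFRSample, bank: FilterBank) -> SubViewSet:
    """Scale one TFR by every filter in the bank, yielding M sub-views."""
    if x.freq_axis.shape != bank.freq_axis.shape or not np.allclose(
            x.freq_axis, bank.freq_axis):
        raise ValueError("sample and filter bank are on different frequency axes")
    return SubViewSet(views=x.values[None, :, :] * bank.responses()[:, None, :])
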