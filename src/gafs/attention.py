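"""Channel-attention recalibration for C x H x W feature maps.

Per-channel gating weights in (0, 1) are computed from two globally pooled
descriptors (average and max) pushed through a shared bottleneck MLP and a
sigmoid:

    A_c(F) = sigmoid( V1 . act(V0 . F_avg) + V1 . act(V0 . F_max) )

with V0 mapping C-vectors to a hidden layer of ceil(C / r) units (r the
reduction ratio) and V1 mapping back to C. The two branches share weights
and are combined by element-wise summation. The gated map is the input map
with each channel multiplied by its attention weight. No training loop is
provided here; weights are supplied or seeded-Gaussian initialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .errors import GafsError


def _check_map(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 3 or min(F.shape) < 1:
        raise GafsError("feature map must be a 3-D (C, H, W) array")
    if not np.all(np.isfinite(F)):
        raise GafsError("feature map must be finite")
    return F


def global_avg_pool(F: np.ndarray) -> np.ndarray:
    """Per-channel mean over the H x W spatial positions."""
    return _check_map(F).mean(axis=(1, 2))


def global_max_pool(F: np.ndarray) -> np.ndarray:
    """Per-channel maximum over the H x W spatial positions."""
    return _check_map(F).max(axis=(1, 2))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class AttentionParams:
    """Weights of the shared bottleneck MLP.

    ``v0`` has shape (hidden, C) and ``v1`` shape (C, hidden) with
    hidden = ceil(C / r). Hidden activation is ReLU by default; biases are
    off by default (the recalibration uses only the two weight matrices).
    """

    v0: np.ndarray
    v1: np.ndarray
    activation: Callable[[np.ndarray], np.ndarray] = relu
    b0: Optional[np.ndarray] = None
    b1: Optional[np.ndarray] = None

    def __post_init__(self):
        self.v0 = np.asarray(self.v0, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        if self.v0.ndim != 2 or self.v1.ndim != 2:
            raise GafsError("v0 and v1 must be matrices")
        hidden, c = self.v0.shape
        if self.v1.shape != (c, hidden):
            raise GafsError(
                f"v1 shape {self.v1.shape} incompatible with v0 shape {self.v0.shape}"
            )
        if hidden < 1:
            raise GafsError("hidden size must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.v0.shape[1]

    @classmethod
    def random_init(cls, n_channels: int, r: int = 8, seed: int = 0) -> "AttentionParams":
        """Seeded Gaussian init with fan-in scaling; hidden = ceil(C / r)."""
        if r < 1:
            raise GafsError("reduction ratio must be >= 1")
        hidden = max(math.ceil(n_channels / r), 1)
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal((hidden, n_channels)) / math.sqrt(n_channels)
        v1 = rng.standard_normal((n_channels, hidden)) / math.sqrt(hidden)
        return cls(v0=v0, v1=v1)

    def mlp(self, v: np.ndarray) -> np.ndarray:
        h = self.v0 @ v
        if self.b0 is not None:
            h = h + self.b0
        h = self.activation(h)
        out = self.v1 @ h
        if self.b1 is not None:
            out = out + self.b1
        return out


def channel_attention(F: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Attention weights: sigmoid(MLP(F_avg) + MLP(F_max)), element-wise in
    (0, 1), one weight per channel."""
    F = _check_map(F)
    if F.shape[0] != params.n_channels:
        raise GafsError(
            f"map has {F.shape[0]} channels but params expect {params.n_channels}"
        )
    pre = params.mlp(global_avg_pool(F)) + params.mlp(global_max_pool(F))
    # the sigmoid saturates to exactly 0/1 in float64 for |pre| > ~37;
    # nudge back inside so gating weights stay strictly in (0, 1)
    return np.clip(
        expit(pre), np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0)
    )


def apply_channel_attention(F: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Multiply channel c of the map by weights[c] (broadcast over H x W)."""
    F = _check_map(F)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (F.shape[0],):
        raise GafsError(
            f"need one weight per channel ({F.shape[0]}), got shape {weights.shape}"
        )
    return F * weights[:, None, None]
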