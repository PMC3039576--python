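"""Gaussian channel kernels and their weighted fusion.

Each channel e contributes K_e(x, y) = exp(-gamma * ||x - y||^2); the fused
kernel is the convex combination sum_e w_e K_e with non-negative weights
summing to one, which keeps the result a valid (PSD) kernel. A single gamma
is shared across all five channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel

from gotlm.features import CHANNELS

logger = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-12


@dataclass
class KernelMatrix:
    """A (rows x cols) kernel block with the protein ids labelling each axis."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    channel: str = "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match id lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )


@dataclass(frozen=True)
class KernelWeights:
    """Non-negative weights over the five channels, summing to one."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing channels: {sorted(missing)}")
        vals = np.array([self.weights[c] for c in CHANNELS], dtype=float)
        if (vals < -_WEIGHT_TOL).any():
            raise ValueError(f"negative kernel weight in {dict(self.weights)}")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"kernel weights must sum to 1, got {vals.sum()!r}")
        object.__setattr__(self, "weights", {c: float(self.weights[c]) for c in CHANNELS})

    def __getitem__(self, channel: str) -> float:
        return self.weights[channel]

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[c] for c in CHANNELS])

    @staticmethod
    def uniform(channels: Sequence[str] = CHANNELS) -> "KernelWeights":
        w = 1.0 / len(channels)
        return KernelWeights({c: (w if c in channels else 0.0) for c in CHANNELS})

    @staticmethod
    def from_products(products: Mapping[str, float]) -> "KernelWeights":
        """Normalize per-channel SE*MCC products into weights.

        Negative products clamp to zero (a worse-than-random channel
        contributes nothing); if every product is zero the weights fall back
        to uniform over the channels present, with a warning.
        """
        clamped = {c: max(0.0, float(v)) for c, v in products.items()}
        total = sum(clamped.values())
        if total <= 0.0:
            logger.warning(
                "all channel SE*MCC products are <= 0; falling back to uniform weights"
            )
            return KernelWeights.uniform(tuple(products))
        return KernelWeights(
            {c: (clamped.get(c, 0.0) / total) for c in CHANNELS}
        )


def gaussian_kernel(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """K(x, y) = exp(-gamma * ||x - y||^2), as a dense (n_x, n_y) matrix.

    A zero-dimensional feature space (empty GO vocabulary) gives the all-ones
    kernel — every distance is zero — which is flagged degenerate in the log
    rather than raised, so partially annotated datasets still train.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError(f"incompatible feature shapes {X.shape} and {Y.shape}")
    if X.shape[1] == 0:
        logger.warning(
            "degenerate channel: empty feature space yields the all-ones kernel"
        )
        return np.ones((X.shape[0], Y.shape[0]))
    K = rbf_kernel(X, Y, gamma=gamma)
    if Y is X:
        K = (K + K.T) / 2.0  # exact symmetry for the square train kernel
        np.fill_diagonal(K, 1.0)
    return K


def channel_kernels(
    channels_x: Mapping[str, "np.ndarray | object"],
    channels_y: Mapping[str, "np.ndarray | object"] | None,
    gamma: float,
) -> dict[str, np.ndarray]:
    """Per-channel Gaussian kernels between two channel sets (or one vs itself).

    Accepts plain matrices or :class:`~gotlm.features.FeatureChannel` objects.
    """

    def mat(obj):
        return obj.matrix if hasattr(obj, "matrix") else np.asarray(obj, dtype=float)

    out = {}
    for name, chan in channels_x.items():
        X = mat(chan)
        Y = X if channels_y is None else mat(channels_y[name])
        out[name] = gaussian_kernel(X, Y, gamma)
    return out


def fuse_kernels(
    kernels: Mapping[str, np.ndarray], weights: KernelWeights
) -> np.ndarray:
    """Element-wise weighted sum of channel kernels.

    Channels with exactly zero weight may be omitted from ``kernels``
    (ablation); a missing channel with positive weight is an error, as is any
    shape mismatch between the provided kernel blocks.
    """
    shape = None
    fused = None
    for c in CHANNELS:
        w = weights[c]
        if c not in kernels:
            if w != 0.0:
                raise ValueError(f"channel {c!r} has weight {w} but no kernel")
            continue
        K = np.asarray(kernels[c], dtype=float)
        if shape is None:
            shape = K.shape
            fused = np.zeros(shape)
        elif K.shape != shape:
            raise ValueError(
                f"channel {c!r} kernel shape {K.shape} != expected {shape}"
            )
        fused += w * K
    if fused is None:
        raise ValueError("no kernels provided")
    return fused


def write_kernel(kernel: KernelMatrix, path) -> None:
    """Dump a kernel block as whitespace-delimited text with an id header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(kernel.col_ids) + "\n")
        for rid, row in zip(kernel.row_ids, kernel.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
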