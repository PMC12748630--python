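"""Train-set range normalization.

Parameters (per-channel minima and maxima) are fitted on the training cycles
of a fold only, then applied identically to training and held-out data:
value -> (value - min) / (max - min).  Training data map into [0, 1];
held-out values may fall outside that interval and are never clipped.
A "global" mode using one range across all channels is available, but the
default is per-channel because accelerometer and gyroscope magnitudes differ
by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError


@dataclass
class NormalizationParams:
    minimum: np.ndarray  # shape (6,)
    maximum: np.ndarray  # shape (6,)
    mode: str = "per_channel"

    @property
    def degenerate(self) -> np.ndarray:
        """Channels whose train range collapsed to a point (max == min)."""
        return self.maximum == self.minimum

    @property
    def denominator(self) -> np.ndarray:
        """Range per channel, with unit substitution on degenerate channels."""
        span = self.maximum - self.minimum
        return np.where(span == 0, 1.0, span)


def fit_range(train_X: np.ndarray, mode: str = "per_channel") -> NormalizationParams:
    """Fit per-channel (default) or global min/max over all training samples.

    ``train_X`` has shape (n_samples, n_channels, n_time).
    """
    train_X = np.asarray(train_X)
    if train_X.ndim != 3 or train_X.shape[0] < 1:
        raise ContractError("fit_range needs a non-empty (n, channels, time) array")
    if mode == "per_channel":
        minimum = train_X.min(axis=(0, 2))
        maximum = train_X.max(axis=(0, 2))
    elif mode == "global":
        minimum = np.full(train_X.shape[1], train_X.min())
        maximum = np.full(train_X.shape[1], train_X.max())
    else:
        raise ContractError(f"unknown normalization mode {mode!r}")
    return NormalizationParams(minimum=minimum, maximum=maximum, mode=mode)


def apply_range(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Affine per-channel rescale; out-of-range held-out values stay unclipped."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.ndim != 3 or X.shape[1] != params.minimum.shape[0]:
        raise ContractError("apply_range expects (n, channels, time) matching the fit")
    out = (X - params.minimum[None, :, None]) / params.denominator[None, :, None]
    return out[0] if single else out
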