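"""Rate coding: continuous features → binary spike trains.

Features are min–max normalised per channel into [0, 1] and treated as
per-step spiking probabilities of an inhomogeneous Poisson (Bernoulli per
discrete step) process: each channel×step cell draws an independent uniform
number and spikes when the draw does not exceed the rate.

Also provides the kinematic augmentation used on motion-capture input:
appending discrete-difference velocity (and optionally acceleration)
channels to a position matrix.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["normalize_minmax", "kinematic_augment", "poisson_encode"]


def normalize_minmax(
    data: np.ndarray,
    stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Scale each channel (row) of ``data`` into [0, 1].

    Parameters
    ----------
    data : (channels, time) array, finite.
    stats : optional (min, max) per-channel arrays computed on training
        data; when given they are applied unchanged and out-of-range test
        values are clipped into [0, 1].

    Returns
    -------
    (rates, stats): the rate matrix and the (min, max) used, so the same
    scaling can be replayed on held-out data.

    Channels with zero range map to 0 everywhere.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    if stats is None:
        lo = data.min(axis=1, keepdims=True)
        hi = data.max(axis=1, keepdims=True)
    else:
        lo = np.asarray(stats[0], dtype=np.float64).reshape(-1, 1)
        hi = np.asarray(stats[1], dtype=np.float64).reshape(-1, 1)
        if lo.shape[0] != data.shape[0]:
            raise ValueError("stats do not match channel count")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(span > 0, (data - lo) / np.where(span > 0, span, 1.0), 0.0)
    rates = np.clip(rates, 0.0, 1.0)
    return rates, (lo.ravel(), hi.ravel())


def kinematic_augment(positions: np.ndarray, order: int = 1) -> np.ndarray:
    """Append velocity (order 1) and acceleration (order 2) channels.

    Differences are taken along time; the first frame(s) are padded by edge
    replication so the time length is preserved.  A (C, T) input becomes
    (2C, T) at order 1 and (3C, T) at order 2.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if positions.ndim != 2 or positions.shape[1] < 3:
        raise ValueError("positions must be a (channels, >=3 frames) matrix")
    vel = np.diff(positions, axis=1, prepend=positions[:, :1])
    vel[:, 0] = vel[:, 1]  # edge replication: no zero spike at the boundary
    blocks = [positions, vel]
    if order == 2:
        acc = np.diff(vel, axis=1, prepend=vel[:, :1])
        acc[:, 0] = acc[:, 1]
        blocks.append(acc)
    return np.vstack(blocks)


def poisson_encode(rates: np.ndarray, seed: int) -> np.ndarray:
    """Draw a binary spike train from a [0, 1] rate matrix.

    spike[c, t] = 1 iff u[c, t] <= rates[c, t] with independent uniform
    draws; reproducible for a fixed seed.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.size and (rates.min() < 0 or rates.max() > 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(rates.shape)
    # boundary-inclusive comparison; a zero rate never spikes even though
    # the uniform draw can itself be exactly 0.0
    return ((u <= rates) & (rates > 0)).astype(np.int8)
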