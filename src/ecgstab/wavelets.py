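"""Periodic orthonormal discrete wavelet machinery.

Implements the two-channel analysis/synthesis steps on periodized signals.
With an orthonormal lowpass filter (unit norm, double-shift orthogonal)
the transform matrix is orthogonal, so reconstruction is exact and energy
is conserved to machine precision — properties the feature modules assert.

Analysis is correlation with stride 2; synthesis is the adjoint
(zero-stuffed circular convolution). Signals must have even length at
every level; callers pad to a multiple of ``2**levels`` first.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmf_highpass",
    "analysis_step",
    "synthesis_step",
    "wavedec",
    "waverec",
    "pad_to_multiple",
]


def qmf_highpass(h: np.ndarray) -> np.ndarray:
    """Quadrature-mirror highpass partner g[n] = (-1)^n h[L-1-n]."""
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def _circular_correlate(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """y[k] = sum_m h[m] x[(k+m) mod N], length N."""
    L = len(h)
    if L == 1:
        return x * h[0]
    reps = -(-(L - 1) // len(x))  # filter may be longer than the signal
    ext = np.concatenate([x] + [x] * reps)[: len(x) + L - 1]
    return np.correlate(ext, h, mode="valid")


def _circular_convolve(u: np.ndarray, h: np.ndarray) -> np.ndarray:
    """y[n] = sum_m h[m] u[(n-m) mod N], length N."""
    n = len(u)
    full = np.convolve(u, h)
    out = np.zeros(n)
    for start in range(0, len(full), n):
        seg = full[start:start + n]
        out[: len(seg)] += seg
    return out


def analysis_step(x: np.ndarray, h: np.ndarray, g: np.ndarray):
    """One level of periodic analysis; returns (approx, detail), each N/2."""
    if len(x) % 2:
        raise ValueError("analysis_step requires even-length input")
    return _circular_correlate(x, h)[::2], _circular_correlate(x, g)[::2]


def synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`analysis_step`; exact inverse for orthonormal h."""
    n = 2 * len(a)
    ua = np.zeros(n)
    ua[::2] = a
    ud = np.zeros(n)
    ud[::2] = d
    return _circular_convolve(ua, h) + _circular_convolve(ud, g)


def wavedec(x: np.ndarray, h: np.ndarray, levels: int):
    """Multi-level periodic DWT.

    Returns ``(approx, details)`` with ``details[0]`` the finest level.
    ``len(x)`` must be divisible by ``2**levels``.
    """
    if len(x) % (1 << levels):
        raise ValueError(f"length {len(x)} not divisible by 2^{levels}")
    g = qmf_highpass(h)
    details = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        a, d = analysis_step(a, h, g)
        details.append(d)
    return a, details


def waverec(approx: np.ndarray, details, h: np.ndarray) -> np.ndarray:
    """Inverse of :func:`wavedec` (details finest-first)."""
    g = qmf_highpass(h)
    a = np.asarray(approx, dtype=float)
    for d in reversed(details):
        a = synthesis_step(a, d, h, g)
    return a


def pad_to_multiple(x: np.ndarray, multiple: int):
    """Symmetric (reflect) pad to the next multiple; returns (padded, slice).

    The slice recovers the original extent from the padded array. Padding is
    split between both ends so edge effects are shared.
    """
    n = len(x)
    target = -(-n // multiple) * multiple
    extra = target - n
    left = extra // 2
    right = extra - left
    if extra == 0:
        return np.asarray(x, dtype=float), slice(0, n)
    padded = np.pad(np.asarray(x, dtype=float), (left, right), mode="symmetric")
    return padded, slice(left, left + n)
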