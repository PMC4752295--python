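"""Moment and spectral summary helpers shared by the feature families.

Kurtosis is the plain fourth standardized moment (non-excess: the normal
distribution scores 3); skewness the third. Both use biased (population)
moment estimators. Degenerate inputs yield NaN rather than raising.
"""

from __future__ import annotations

import numpy as np


def skewness(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0.0:
        return float("nan")
    return float(np.mean((x - m) ** 3) / m2 ** 1.5)


def kurtosis(x: np.ndarray) -> float:
    """Fourth standardized moment (normal -> 3)."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0.0:
        return float("nan")
    return float(np.mean((x - m) ** 4) / m2 ** 2)


def basic_stats(x: np.ndarray, prefix: str) -> dict[str, float]:
    """mean / sd / skew / kurt / energy / mean-abs-first-difference."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    mad = float(np.mean(np.abs(np.diff(x)))) if len(x) > 1 else 0.0
    return {
        f"{prefix}_mean": float(np.mean(x)),
        f"{prefix}_std": sd,
        f"{prefix}_skew": skewness(x),
        f"{prefix}_kurt": kurtosis(x),
        f"{prefix}_energy": float(np.sum(x ** 2)),
        f"{prefix}_mad": mad,
    }


def spectral_summary(freqs: np.ndarray, power: np.ndarray, prefix: str,
                     edge_fraction: float = 0.95) -> dict[str, float]:
    """Dominant frequency and amplitude, median and edge frequency of a PSD.

    Median/edge are the frequencies below which 50% / ``edge_fraction`` of
    the total power lies (first bin reaching the cumulative threshold).
    """
    power = np.asarray(power, dtype=float)
    total = power.sum()
    if total <= 0 or not np.isfinite(total):
        return {f"{prefix}_dom_freq": float("nan"), f"{prefix}_dom_amp": float("nan"),
                f"{prefix}_median_freq": float("nan"), f"{prefix}_edge_freq": float("nan")}
    k = int(np.argmax(power))
    cum = np.cumsum(power) / total
    return {
        f"{prefix}_dom_freq": float(freqs[k]),
        f"{prefix}_dom_amp": float(power[k]),
        f"{prefix}_median_freq": float(freqs[np.searchsorted(cum, 0.5)]),
        f"{prefix}_edge_freq": float(freqs[np.searchsorted(cum, edge_fraction)]),
    }
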