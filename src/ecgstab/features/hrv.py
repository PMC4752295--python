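"""Traditional heart-rate-variability features (the 10-feature baseline).

Time-domain statistics of the R-R series, a periodogram PSD on the
spline-resampled tachogram, LF/HF band powers, and distribution moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

from ..datatypes import RrSeries
from ._stats import kurtosis, skewness

RESAMPLE_RATE = 4.0      # Hz, tachogram resampling rate
LF_BAND = (0.004, 0.15)  # Hz, as printed (conventional lower edge is 0.04)
HF_BAND = (0.15, 0.40)   # Hz
NN50_THRESHOLD_MS = 50.0

#: The named "typical HRV" comparison group.
TYPICAL_HRV_FEATURES = [
    "sdnn", "sdsd", "rmssd", "pnn50",
    "lf_power", "hf_power", "hf_lf_ratio",
    "rr_mean", "rr_skew", "rr_kurt",
]


@dataclass
class PsdEstimate:
    frequencies: np.ndarray   # Hz, uniform from 0 to resample_rate/2
    power: np.ndarray         # ms^2/Hz
    resample_rate: float


def time_domain_features(z: RrSeries, literal_sdsd: bool = True) -> dict[str, float]:
    """SDNN, SDSD, RMSSD and pNN50 of an R-R interval series.

    ``literal_sdsd=True`` reproduces the printed formula: the SD of the
    *absolute* successive differences about their mean, normalized by the
    number of differences. ``False`` substitutes the conventional signed
    differences (same normalization).
    """
    v = np.asarray(z.z, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 R-R intervals")
    u = np.diff(v)
    sdsd_arg = np.abs(u) if literal_sdsd else u
    nn50 = int(np.sum(np.abs(u) > NN50_THRESHOLD_MS))
    return {
        "sdnn": float(np.std(v, ddof=1)),
        "sdsd": float(np.std(sdsd_arg, ddof=0)),
        "rmssd": float(np.sqrt(np.mean(u ** 2))),
        "pnn50": 100.0 * nn50 / len(u),
    }


def psd_rr(z: RrSeries, resample_rate: float = RESAMPLE_RATE) -> PsdEstimate:
    """FFT periodogram of the cubic-spline-resampled, mean-removed tachogram."""
    v = np.asarray(z.z, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 R-R intervals for a PSD")
    t = np.cumsum(v) / 1000.0
    duration = t[-1] - t[0]
    if len(v) < 30 or duration < 60.0:
        warnings.warn("short window (<30 intervals or <60 s); low-frequency "
                      "PSD estimates are low-confidence")
    grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
    resampled = CubicSpline(t, v)(grid)
    resampled = resampled - resampled.mean()
    freqs, power = periodogram(resampled, fs=resample_rate, window="boxcar",
                               detrend=False)
    return PsdEstimate(frequencies=freqs, power=power, resample_rate=resample_rate)


def band_powers(psd: PsdEstimate, lf_band=LF_BAND, hf_band=HF_BAND) -> dict[str, float]:
    """Integrated LF / HF band powers and the HF/LF ratio."""
    f, p = psd.frequencies, psd.power
    df = f[1] - f[0]
    lf = float(np.sum(p[(f >= lf_band[0]) & (f < lf_band[1])]) * df)
    hf = float(np.sum(p[(f >= hf_band[0]) & (f <= hf_band[1])]) * df)
    return {"lf_power": lf, "hf_power": hf,
            "hf_lf_ratio": hf / lf if lf > 0 else float("nan")}


def moment_features(z: RrSeries) -> dict[str, float]:
    """Mean (ms), skewness and non-excess kurtosis of the interval series."""
    v = np.asarray(z.z, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 R-R intervals")
    return {"rr_mean": float(np.mean(v)), "rr_skew": skewness(v), "rr_kurt": kurtosis(v)}


def typical_hrv_features(z: RrSeries, literal_sdsd: bool = True) -> dict[str, float]:
    """The full 10-feature traditional HRV group."""
    out = time_domain_features(z, literal_sdsd=literal_sdsd)
    out.update(band_powers(psd_rr(z)))
    out.update(moment_features(z))
    return {name: out[name] for name in TYPICAL_HRV_FEATURES}
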