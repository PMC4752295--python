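"""Peak-based morphology features.

Interval-ratio features over all ordered pairs of the 15 canonical
intervals, amplitude difference/ratio/interaction features, non-typical
HRV spectral summaries, and ECG-derived respiration (EDR) features.

All quantities are per-beat ratios/differences averaged over the window,
so every feature is dimensionless and independent of heart rate, time
origin and positive affine amplitude scaling of the raw ECG.
"""

from __future__ import annotations

import warnings
from itertools import combinations, permutations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

from ..datatypes import FiducialSet, RrSeries, WAVES
from ._stats import spectral_summary
from . import hrv as _hrv

EDR_RATE = 4.0  # Hz

#: Intra-beat intervals (time from first wave to second, same beat).
INTRA_INTERVALS = tuple(a + b for a, b in combinations(WAVES, 2))
#: Beat-to-beat same-wave intervals.
B2B_INTERVALS = tuple(w + w for w in WAVES)
ALL_INTERVALS = INTRA_INTERVALS + B2B_INTERVALS

#: Amplitude base quantities: intra-beat differences and beat-to-beat
#: same-wave differences, mirroring the interval layout.
AMP_BASES = ALL_INTERVALS


def _interval_arrays(fid: FiducialSet) -> dict[str, np.ndarray]:
    """Per-beat interval values, all aligned on beats 2..n.

    Beat-to-beat intervals only exist from the second beat on; intra-beat
    intervals are restricted to the same beats so that every per-beat
    ratio pairs values from one beat.
    """
    t = fid.times
    out = {}
    for name in INTRA_INTERVALS:
        a, b = name[0], name[1]
        out[name] = (t[b] - t[a])[1:]
    for name in B2B_INTERVALS:
        w = name[0]
        out[name] = np.diff(t[w])
    return out


def _amp_arrays(fid: FiducialSet) -> dict[str, np.ndarray]:
    """Per-beat amplitude differences, aligned on beats 2..n."""
    a = fid.amps
    out = {}
    for name in INTRA_INTERVALS:
        x, y = name[0], name[1]
        out[name] = (a[y] - a[x])[1:]
    for name in B2B_INTERVALS:
        w = name[0]
        out[name] = np.diff(a[w])
    return out


def _mean_ratio(num: np.ndarray, den: np.ndarray, name: str,
                on_empty: str = "raise") -> float:
    """Mean of per-beat ratios; beats with a zero denominator are skipped."""
    ok = den != 0.0
    if not ok.all():
        warnings.warn(f"{name}: {np.sum(~ok)} beat(s) skipped (zero denominator)")
    if not ok.any():
        if on_empty == "raise":
            raise ValueError(f"{name}: all beats skipped")
        return float("nan")
    return float(np.mean(num[ok] / den[ok]))


def interval_ratio_features(fid: FiducialSet) -> dict[str, float]:
    """t_{A/B} = mean over beats of A(i)/B(i) for every ordered pair A != B."""
    if fid.n_beats < 2:
        raise ValueError("need at least 2 beats")
    arrays = _interval_arrays(fid)
    return {f"t_{a}/{b}": _mean_ratio(arrays[a], arrays[b], f"t_{a}/{b}")
            for a, b in permutations(ALL_INTERVALS, 2)}


def amplitude_features(fid: FiducialSet) -> dict[str, float]:
    """Amplitude differences plus their pairwise ratios and interactions.

    Base features are window means of per-beat amplitude differences;
    ratios are means of per-beat ratios (ordered pairs) and interactions
    means of per-beat products (unordered pairs — the product commutes).
    """
    if fid.n_beats < 2:
        raise ValueError("need at least 2 beats")
    arrays = _amp_arrays(fid)
    out = {f"a_{name}": float(np.mean(arr)) for name, arr in arrays.items()}
    for a, b in permutations(AMP_BASES, 2):
        out[f"a_{a}/{b}"] = _mean_ratio(arrays[a], arrays[b], f"a_{a}/{b}",
                                        on_empty="nan")
    for a, b in combinations(AMP_BASES, 2):
        out[f"a_{a}*{b}"] = float(np.mean(arrays[a] * arrays[b]))
    return out


def hrv_spectral_extra(rr: RrSeries) -> dict[str, float]:
    """Dominant/median/edge frequency summaries of the HRV PSD."""
    if rr.n < 10:
        raise ValueError("need at least 10 R-R intervals")
    if rr.n < 30:
        warnings.warn("fewer than 30 R-R intervals; HRV spectral summaries "
                      "are low-confidence")
    psd = _hrv.psd_rr(rr)
    if psd.power.sum() <= 0:
        raise ValueError("all-zero HRV PSD")
    return spectral_summary(psd.frequencies, psd.power, "hrv")


def derive_respiration(fid: FiducialSet, rate: float = EDR_RATE) -> np.ndarray:
    """ECG-derived respiration: detrended, resampled R-amplitude series."""
    if fid.n_beats < 10:
        raise ValueError("need at least 10 beats for EDR")
    t, a = fid.times["r"], fid.amps["r"]
    trend = np.polynomial.Polynomial.fit(t, a, 1)
    grid = np.arange(t[0], t[-1], 1.0 / rate)
    return CubicSpline(t, a - trend(t))(grid)


def respiratory_features(edr: np.ndarray, rate: float = EDR_RATE) -> dict[str, float]:
    """Spread and spectral summaries of the EDR signal and its derivative."""
    edr = np.asarray(edr, dtype=float)
    if len(edr) < 10.0 * rate:
        raise ValueError("EDR shorter than 10 s")
    if len(edr) < 30.0 * rate:
        warnings.warn("EDR shorter than 30 s; respiratory spectral features "
                      "are low-confidence")
    out = {}
    for prefix, sig in (("resp", edr), ("resp_d1", np.diff(edr) * rate)):
        out[f"{prefix}_spread"] = float(np.std(sig, ddof=1))
        freqs, power = periodogram(sig - sig.mean(), fs=rate, window="boxcar",
                                   detrend=False)
        out.update(spectral_summary(freqs, power, prefix))
    return out


def morphology_features(fid: FiducialSet, rr: RrSeries) -> dict[str, float]:
    """The full peak-based family for one window."""
    out = interval_ratio_features(fid)
    out.update(amplitude_features(fid))
    out.update(hrv_spectral_extra(rr))
    out.update(respiratory_features(derive_respiration(fid)))
    return out
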