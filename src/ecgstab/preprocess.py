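"""Tumbling beat-count windowing, baseline removal, smoothing."""

from __future__ import annotations

import warnings

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .datatypes import BeatWindow, EcgRecord

DEFAULT_BEATS_PER_WINDOW = 120
DEFAULT_BASELINE_DEGREE = 6
DEFAULT_SG_FRAME = 15       # samples (30 ms at 500 Hz)
DEFAULT_SG_ORDER = 2


def segment_windows(record: EcgRecord, r_times: np.ndarray,
                    beats_per_window: int = DEFAULT_BEATS_PER_WINDOW) -> list[BeatWindow]:
    """Split a record into consecutive windows of exactly N complete beats.

    Window sample boundaries sit halfway between the last beat of one
    window and the first beat of the next, so each window contains its
    beats in full. The trailing partial window is discarded; each window
    is tagged with the stage containing its midpoint sample.
    """
    r_times = np.asarray(r_times, dtype=float)
    if beats_per_window < 2:
        raise ValueError("beats_per_window must be >= 2")
    n_beats = len(r_times)
    n_windows = n_beats // beats_per_window
    if n_windows == 0:
        raise ValueError(f"record has {n_beats} beats, fewer than one window "
                         f"of {beats_per_window}")
    fs = record.fs
    n_samples = len(record.samples)
    windows = []
    for k in range(n_windows):
        beats = r_times[k * beats_per_window:(k + 1) * beats_per_window]
        if k == 0:
            start = 0
        else:
            prev_last = r_times[k * beats_per_window - 1]
            start = int(round((prev_last + beats[0]) / 2 * fs))
        if k == n_windows - 1 and (k + 1) * beats_per_window == n_beats:
            stop = n_samples
        else:
            nxt = r_times[(k + 1) * beats_per_window]
            stop = int(round((beats[-1] + nxt) / 2 * fs))
        mid = (start + stop) // 2
        windows.append(BeatWindow(
            samples=record.samples[start:stop].copy(),
            fs=fs,
            r_times=beats - start / fs,
            subject_id=record.subject_id,
            window_index=k,
            stage=record.stage_of_sample(mid),
        ))
    return windows


def remove_baseline_poly(window: BeatWindow, degree: int = DEFAULT_BASELINE_DEGREE) -> BeatWindow:
    """Subtract the least-squares degree-``degree`` polynomial fit.

    The fit uses a scaled abscissa so the Vandermonde system stays well
    conditioned; on numerical failure the degree is lowered with a warning.
    """
    x = window.samples
    if len(x) <= degree + 1:
        raise ValueError("window too short for the requested polynomial degree")
    deg = degree
    while deg >= 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", np.exceptions.RankWarning)
                fit = Polynomial.fit(np.arange(len(x)), x, deg)
            break
        except (np.exceptions.RankWarning, np.linalg.LinAlgError):
            warnings.warn(f"baseline fit ill-conditioned at degree {deg}; retrying lower")
            deg -= 1
    residual = x - fit(np.arange(len(x)))
    return BeatWindow(samples=residual, fs=window.fs, r_times=window.r_times,
                      subject_id=window.subject_id, window_index=window.window_index,
                      stage=window.stage, severity=window.severity, label=window.label)


def smooth_savitzky_golay(samples: np.ndarray, frame_len: int = DEFAULT_SG_FRAME,
                          poly_order: int = DEFAULT_SG_ORDER) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial filter).

    Edges are handled by fitting the boundary polynomial to the truncated
    frame, so the output has the same length as the input and polynomials
    up to ``poly_order`` pass through unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    if frame_len % 2 == 0:
        raise ValueError("frame_len must be odd")
    if frame_len <= poly_order:
        raise ValueError("frame_len must exceed poly_order")
    return savgol_filter(samples, frame_len, poly_order, mode="interp")
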