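"""Record-to-feature-table extraction: the per-window processing chain.

For each record: low-frequency filtering and R detection on the full
waveform define the beats; tumbling beat-count windows are then baseline
corrected, smoothed, re-filtered, delineated, augmented, normalized and
passed to the four feature families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BeatWindow, EcgRecord, RrSeries
from . import peaks, preprocess
from .features import dtcwt as dtcwt_mod
from .features import hrv as hrv_mod
from .features import morphology as morph_mod
from .features import tautstring as ts_mod


@dataclass
class ExtractConfig:
    beats_per_window: int = preprocess.DEFAULT_BEATS_PER_WINDOW
    baseline_degree: int = preprocess.DEFAULT_BASELINE_DEGREE
    sg_frame: int = preprocess.DEFAULT_SG_FRAME
    sg_order: int = preprocess.DEFAULT_SG_ORDER
    eps_grid: tuple = ts_mod.DEFAULT_EPS_GRID
    use_truth_beats: bool = False   # bypass the detector with simulator truth


def detect_beats(record: EcgRecord, config: ExtractConfig | None = None) -> np.ndarray:
    """Full-record R times (provisional pass defining window boundaries)."""
    config = config or ExtractConfig()
    if config.use_truth_beats:
        if record.truth is None:
            raise ValueError("record carries no truth annotations")
        return record.truth.r_times
    filtered = peaks.filter_lowfreq_wavelet(record.samples, record.fs)
    return peaks.detect_r_peaks(filtered, record.fs)


def extract_window_features(window: BeatWindow, config: ExtractConfig | None = None) -> dict:
    """Run the processing chain on one segmented window; returns a feature row."""
    config = config or ExtractConfig()
    win = preprocess.remove_baseline_poly(window, config.baseline_degree)
    smoothed = preprocess.smooth_savitzky_golay(win.samples, config.sg_frame, config.sg_order)
    filtered = peaks.filter_lowfreq_wavelet(smoothed, win.fs)
    fid = peaks.delineate_pqst(filtered, win.fs, win.r_times)
    fid = peaks.augment_missing_peaks(fid)
    normalized, fid = peaks.normalize_amplitude(filtered, fid)
    rr = RrSeries(z=np.diff(fid.times["r"]) * 1000.0, r0=float(fid.times["r"][0]))

    row: dict = {"subject_id": window.subject_id, "window_index": window.window_index,
                 "stage": window.stage, "severity": window.severity, "label": window.label}
    row.update(morph_mod.morphology_features(fid, rr))
    row.update(ts_mod.ts_feature_set(rr, config.eps_grid))
    row.update(dtcwt_mod.dtcwt_feature_set(dtcwt_mod.dtcwt_decompose(normalized)))
    row.update(hrv_mod.typical_hrv_features(rr))
    return row


def extract_record(record: EcgRecord, config: ExtractConfig | None = None) -> list[dict]:
    """Feature rows for every complete window of one record."""
    config = config or ExtractConfig()
    r_times = detect_beats(record, config)
    windows = preprocess.segment_windows(record, r_times, config.beats_per_window)
    rows = []
    for win in windows:
        try:
            rows.append(extract_window_features(win, config))
        except ValueError as err:
            warnings.warn(f"window {win.window_index} of {record.subject_id} "
                          f"skipped: {err}")
    return rows


def build_feature_table(records, config: ExtractConfig | None = None) -> pd.DataFrame:
    """Stack per-record rows into a windows-by-features table."""
    rows = []
    n_stages: dict[str, int] = {}
    for record in records:
        rows.extend(extract_record(record, config))
        n_stages[record.subject_id] = record.n_stages
    table = pd.DataFrame(rows)
    table.attrs["n_stages"] = n_stages
    return table
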