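"""Shared container types for the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical wave order within a beat.
WAVES = ("p", "q", "r", "s", "t")

#: Metadata columns of a feature table (everything else is a feature).
META_COLUMNS = ["subject_id", "window_index", "stage", "severity", "label"]


@dataclass
class RecordTruth:
    """Ground-truth annotations carried by simulated records."""

    r_times: np.ndarray                      # s, absolute
    fiducials: dict[str, np.ndarray]         # wave -> absolute times (s)
    fiducial_amps: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class EcgRecord:
    """A subject's continuous single-lead waveform with stage annotations.

    ``stage_bounds`` holds ``n_stages + 1`` sample indices: stage ``k``
    spans samples ``[stage_bounds[k], stage_bounds[k+1])``; stage 0 is the
    baseline.
    """

    samples: np.ndarray
    fs: float
    stage_bounds: np.ndarray
    subject_id: str
    truth: Optional[RecordTruth] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.stage_bounds = np.asarray(self.stage_bounds, dtype=int)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        b = self.stage_bounds
        if len(b) < 2 or np.any(np.diff(b) <= 0) or b[0] != 0 or b[-1] > len(self.samples):
            raise ValueError("stage_bounds must be strictly increasing within the record")

    @property
    def n_stages(self) -> int:
        return len(self.stage_bounds) - 1

    def stage_of_sample(self, index: int) -> int:
        """Stage containing a sample index."""
        k = int(np.searchsorted(self.stage_bounds, index, side="right") - 1)
        return min(max(k, 0), self.n_stages - 1)


@dataclass
class BeatWindow:
    """A tumbling window holding a fixed number of complete beats."""

    samples: np.ndarray
    fs: float
    r_times: np.ndarray                      # s, window-relative, one per beat
    subject_id: str
    window_index: int
    stage: int
    severity: float = float("nan")
    label: Optional[str] = None

    @property
    def beat_count(self) -> int:
        return len(self.r_times)

    def rr_series(self) -> "RrSeries":
        """Successive R-R intervals of this window, in milliseconds."""
        z = np.diff(self.r_times) * 1000.0
        return RrSeries(z=z, r0=float(self.r_times[0]))


@dataclass
class RrSeries:
    """Successive R-R intervals z_i = r_i - r_{i-1} (ms)."""

    z: np.ndarray
    r0: float = 0.0

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)

    @property
    def n(self) -> int:
        return len(self.z)

    def beat_times(self) -> np.ndarray:
        """Absolute beat times (s) implied by the interval series."""
        return self.r0 + np.cumsum(self.z) / 1000.0


class FiducialSet:
    """Per-beat P/Q/R/S/T peak times (s) and amplitudes.

    Missing waves are NaN until :func:`ecgstab.peaks.augment_missing_peaks`
    fills them; ``imputed`` records which entries were filled.
    """

    def __init__(self, times: dict[str, np.ndarray], amps: dict[str, np.ndarray],
                 imputed: Optional[dict[str, np.ndarray]] = None):
        self.times = {w: np.asarray(times[w], dtype=float) for w in WAVES}
        self.amps = {w: np.asarray(amps[w], dtype=float) for w in WAVES}
        n = len(self.times["r"])
        for w in WAVES:
            if len(self.times[w]) != n or len(self.amps[w]) != n:
                raise ValueError("all wave arrays must share one length")
        if imputed is None:
            imputed = {w: np.zeros(n, dtype=bool) for w in WAVES}
        self.imputed = {w: np.asarray(imputed[w], dtype=bool) for w in WAVES}

    @property
    def n_beats(self) -> int:
        return len(self.times["r"])

    def missing(self, wave: str) -> np.ndarray:
        return ~np.isfinite(self.times[wave])

    def copy(self) -> "FiducialSet":
        return FiducialSet({w: self.times[w].copy() for w in WAVES},
                           {w: self.amps[w].copy() for w in WAVES},
                           {w: self.imputed[w].copy() for w in WAVES})

    def validate_order(self):
        """Assert t_p < t_q < t_r < t_s < t_t per beat and increasing t_r."""
        t = self.times
        if np.any(np.diff(t["r"]) <= 0):
            raise ValueError("R times must be strictly increasing")
        for a, b in zip(WAVES[:-1], WAVES[1:]):
            ok = ~(np.isfinite(t[a]) & np.isfinite(t[b])) | (t[a] < t[b])
            if not np.all(ok):
                raise ValueError(f"wave order violated: t_{a} >= t_{b}")
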