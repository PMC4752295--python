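"""Synthetic multi-subject ECG cohorts with known ground truth.

Stands in for the (non-deposited) human study data: multi-stage records
with LF/HF heart-rate oscillations, a five-bump P-QRS-T beat template,
respiratory R-amplitude modulation, baseline wander, measurement noise,
and a monotone severity effect across stages (HRV amplitudes shrink,
T-wave amplitude drifts) so downstream classes are learnably separable.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import EcgRecord, RecordTruth, RrSeries, WAVES

FS = 500.0  # Hz, sampling rate of all simulated records

#: Default beat template: wave -> (amplitude, centre offset ms, width ms).
WAVE_TEMPLATE = {
    "p": (0.15, -160.0, 25.0),
    "q": (-0.12, -35.0, 12.0),
    "r": (1.00, 0.0, 10.0),
    "s": (-0.20, 30.0, 12.0),
    "t": (0.35, 250.0, 60.0),
}

#: Stage-count distribution mirroring the cohort's tolerance spread
#: (baseline + 4..8 stress stages).
STAGE_COUNTS = np.array([5, 6, 7, 8, 9])
STAGE_PROBS = np.array([56, 55, 47, 16, 4]) / 178.0


@dataclass
class SubjectParams:
    """Generative parameters for one simulated subject."""

    subject_id: str = "s000"
    baseline_hr: float = 72.0          # beats/min
    hf_amp: float = 35.0               # ms, respiratory sinus arrhythmia depth
    lf_amp: float = 25.0               # ms, Mayer-wave depth
    resp_freq: float = 0.25            # Hz
    lf_freq: float = 0.10              # Hz
    rr_jitter: float = 8.0             # ms, broadband white variability
    morphology: dict = field(default_factory=lambda: copy.deepcopy(WAVE_TEMPLATE))
    n_stages: int = 6
    severity_slope: float = 0.25       # per-stage shrink on HRV amplitudes
    t_drift: float = 0.03              # additive T-amplitude drift per stage
    r_mod_depth: float = 0.06          # respiratory R-amplitude modulation
    wander_amp: float = 0.12           # baseline wander sinusoid amplitude
    wander_freq: float = 0.08          # Hz
    poly_drift: float = 0.08           # low-order polynomial drift scale
    snr_db: float | None = 20.0        # additive Gaussian noise level; None = off
    stage_len_s: float = 180.0

    def validate(self):
        if not (40.0 <= self.baseline_hr <= 180.0):
            raise ValueError("baseline_hr must lie in [40, 180] BPM")
        if not (0.1 < self.resp_freq < 0.5):
            raise ValueError("resp_freq must lie in (0.1, 0.5) Hz")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if not (0.0 <= self.severity_slope < 1.0):
            raise ValueError("severity_slope must lie in [0, 1)")
        if self.hf_amp < 0 or self.lf_amp < 0 or self.rr_jitter < 0:
            raise ValueError("oscillation amplitudes must be non-negative")
        for w, (_, _, width) in self.morphology.items():
            if width <= 0:
                raise ValueError(f"morphology width for wave {w!r} must be positive")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _stage_rr(params: SubjectParams, duration: float, stage: int,
              rng: np.random.Generator, t0: float = 0.0) -> np.ndarray:
    """RR values (ms) for one stage; beat clock starts at ``t0`` seconds."""
    mean_rr = 60000.0 / params.baseline_hr
    atten = (1.0 - params.severity_slope) ** stage
    ph_hf, ph_lf = rng.uniform(0.0, 2 * np.pi, size=2)
    rr = []
    t = t0
    while True:
        val = (mean_rr
               + params.hf_amp * atten * np.sin(2 * np.pi * params.resp_freq * t + ph_hf)
               + params.lf_amp * atten * np.sin(2 * np.pi * params.lf_freq * t + ph_lf)
               + params.rr_jitter * atten * rng.standard_normal())
        val = max(val, 250.0)  # physiologic floor
        if t + val / 1000.0 - t0 > duration:
            break  # partial last beat discarded
        rr.append(val)
        t += val / 1000.0
    return np.array(rr)


def simulate_rr(params: SubjectParams, duration: float, stage_index: int, seed) -> RrSeries:
    """Simulate the R-R interval series of one stage.

    The series mean tracks ``60000 / baseline_hr`` ms; LF and HF
    oscillations are attenuated by ``(1 - severity_slope)**stage_index``.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 2 * 60.0 / params.baseline_hr:
        raise ValueError("duration too short for two beats at baseline_hr")
    rng = _as_rng(seed)
    z = _stage_rr(params, duration, stage_index, rng)
    return RrSeries(z=z, r0=0.0)


def simulate_ecg(params: SubjectParams, seed) -> EcgRecord:
    """Simulate a full multi-stage record at 500 Hz with truth fiducials."""
    params.validate()
    rng = _as_rng(seed)
    n_per_stage = int(round(params.stage_len_s * FS))
    n_total = n_per_stage * params.n_stages
    stage_bounds = np.arange(params.n_stages + 1) * n_per_stage

    # Beat placement: continuous clock across stages, RR model per stage.
    beat_times, beat_stages = [], []
    t = 0.25  # lead-in so the first beat's P wave is inside the record
    for s in range(params.n_stages):
        stage_end = (s + 1) * params.stage_len_s
        z = _stage_rr(params, stage_end - t, s, rng, t0=t)
        for rr in z:
            beat_times.append(t)
            beat_stages.append(s)
            t += rr / 1000.0
    beat_times = np.array(beat_times)
    beat_stages = np.array(beat_stages)

    ph_resp = rng.uniform(0.0, 2 * np.pi)
    tgrid = np.arange(n_total) / FS
    x = np.zeros(n_total)
    fid_t = {w: np.full(len(beat_times), np.nan) for w in WAVES}
    fid_a = {w: np.full(len(beat_times), np.nan) for w in WAVES}
    for k, (tk, sk) in enumerate(zip(beat_times, beat_stages)):
        atten = (1.0 - params.severity_slope) ** sk
        for w in WAVES:
            amp, off_ms, width_ms = params.morphology[w]
            if w == "t":
                amp = amp + params.t_drift * sk
            elif w == "r":
                amp = amp * (1.0 + params.r_mod_depth * atten
                             * np.sin(2 * np.pi * params.resp_freq * tk + ph_resp))
            tc = tk + off_ms / 1000.0
            sig = width_ms / 1000.0
            lo = max(int((tc - 4 * sig) * FS), 0)
            hi = min(int((tc + 4 * sig) * FS) + 1, n_total)
            if hi <= lo:
                continue
            x[lo:hi] += amp * np.exp(-0.5 * ((tgrid[lo:hi] - tc) / sig) ** 2)
            fid_t[w][k] = tc
            fid_a[w][k] = amp

    clean_power = float(np.mean(x ** 2))

    if params.wander_amp > 0:
        x = x + params.wander_amp * np.sin(2 * np.pi * params.wander_freq * tgrid
                                           + rng.uniform(0, 2 * np.pi))
    if params.poly_drift > 0:
        u = np.linspace(-1.0, 1.0, n_total)
        c = params.poly_drift * rng.normal(size=3)
        x = x + c[0] * u + c[1] * u ** 2 + c[2] * u ** 3
    if params.snr_db is not None:
        sigma = np.sqrt(clean_power / 10.0 ** (params.snr_db / 10.0))
        x = x + sigma * rng.standard_normal(n_total)

    truth = RecordTruth(r_times=fid_t["r"].copy(), fiducials=fid_t, fiducial_amps=fid_a)
    return EcgRecord(samples=x, fs=FS, stage_bounds=stage_bounds,
                     subject_id=params.subject_id, truth=truth)


#: Cohort-level parameter ranges (uniform draws unless overridden).
DEFAULT_COHORT_RANGES = {
    "baseline_hr": (55.0, 95.0),
    "hf_amp": (20.0, 50.0),
    "lf_amp": (12.0, 35.0),
    "resp_freq": (0.18, 0.35),
    "rr_jitter": (4.0, 12.0),
    "severity_slope": (0.15, 0.35),
}


def draw_subject_params(rng: np.random.Generator, subject_id: str,
                        config: dict | None = None) -> SubjectParams:
    """Draw one subject's parameters from the configured ranges."""
    cfg = dict(DEFAULT_COHORT_RANGES)
    overrides = dict(config or {})
    scalars = {}
    for key, val in list(overrides.items()):
        if isinstance(val, (tuple, list)) and len(val) == 2:
            lo, hi = float(val[0]), float(val[1])
            if hi < lo:
                raise ValueError(f"degenerate range for {key}: {val}")
            cfg[key] = (lo, hi)
            overrides.pop(key)
        else:
            scalars[key] = overrides.pop(key)

    params = SubjectParams(subject_id=subject_id)
    for key, (lo, hi) in cfg.items():
        setattr(params, key, float(rng.uniform(lo, hi)))
    params.n_stages = int(rng.choice(STAGE_COUNTS, p=STAGE_PROBS))
    # Inter-subject morphology variability: amplitude/offset/width jitter.
    morph = {}
    for w, (amp, off, width) in WAVE_TEMPLATE.items():
        morph[w] = (amp * rng.uniform(0.8, 1.2),
                    off + (rng.uniform(-10.0, 10.0) if w != "r" else 0.0),
                    width * rng.uniform(0.9, 1.1))
    params.morphology = morph
    for key, val in scalars.items():
        setattr(params, key, val)
    params.validate()
    return params


def iter_cohort(n_subjects: int, seed, config: dict | None = None):
    """Yield simulated records one by one (memory-friendly cohort access)."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = _as_rng(seed)
    for i in range(n_subjects):
        params = draw_subject_params(rng, subject_id=f"s{i:03d}", config=config)
        rec_seed = int(rng.integers(0, 2 ** 31 - 1))
        yield simulate_ecg(params, rec_seed)


def simulate_cohort(n_subjects: int, seed, config: dict | None = None) -> list[EcgRecord]:
    """Simulate a cohort of records; identical seed gives identical output."""
    return list(iter_cohort(n_subjects, seed, config))


def write_record_csv(record: EcgRecord, path) -> Path:
    """Write (t_seconds, amplitude) CSV plus a JSON truth/stage sidecar."""
    path = Path(path)
    t = np.arange(len(record.samples)) / record.fs
    np.savetxt(path, np.column_stack([t, record.samples]),
               fmt="%.6f,%.8f", header="t_seconds,amplitude", comments="")
    side = {
        "subject_id": record.subject_id,
        "fs": record.fs,
        "stage_bounds": record.stage_bounds.tolist(),
    }
    if record.truth is not None:
        side["truth"] = {
            "r_times": record.truth.r_times.tolist(),
            "fiducials": {w: v.tolist() for w, v in record.truth.fiducials.items()},
        }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(side))
    return sidecar


def read_record_csv(path) -> EcgRecord:
    """Read a record written by :func:`write_record_csv`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    truth = None
    if "truth" in meta:
        tr = meta["truth"]
        fid = {w: np.asarray(v, dtype=float) for w, v in tr["fiducials"].items()}
        truth = RecordTruth(r_times=np.asarray(tr["r_times"], dtype=float), fiducials=fid)
    return EcgRecord(samples=data[:, 1], fs=float(meta["fs"]),
                     stage_bounds=np.asarray(meta["stage_bounds"], dtype=int),
                     subject_id=meta["subject_id"], truth=truth)
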