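import numpy as np
import pytest

from ecgstab.datatypes import FiducialSet, WAVES
from ecgstab.peaks import (augment_missing_peaks, delineate_pqst, detect_r_peaks,
                           filter_lowfreq_wavelet, normalize_amplitude)
from ecgstab.synthetic import SubjectParams, simulate_ecg
from tests.conftest import random_fiducials

FS = 500.0


def _f1(detected, truth, tol=0.020):
    if len(detected) == 0:
        return 0.0
    d = np.abs(truth[:, None] - detected[None, :])
    tp = int(np.sum(d.min(axis=1) <= tol))
    prec = tp / len(detected)
    rec = tp / len(truth)
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


class TestLowfreqFilter:
    def test_dc_removed(self):
        out = filter_lowfreq_wavelet(np.full(4096, 5.0), FS)
        assert np.max(np.abs(out)) < 1e-6 * 5.0

    def test_r_locations_preserved(self, clean_record):
        x = clean_record.samples[:60000]
        out = filter_lowfreq_wavelet(x, FS)
        for tk in clean_record.truth.r_times:
            idx = int(tk * FS)
            if not 100 < idx < 59900:
                continue
            a = idx - 50 + np.argmax(x[idx - 50:idx + 50])
            b = idx - 50 + np.argmax(out[idx - 50:idx + 50])
            assert abs(int(a) - int(b)) <= 1

    def test_band_gains(self):
        t = np.arange(60000) / FS
        sine = 0.5 * np.sin(2 * np.pi * 0.05 * t)
        out_sine = filter_lowfreq_wavelet(sine, FS)
        core = slice(5000, 55000)  # away from pad edges
        atten = np.sqrt(np.mean(out_sine[core] ** 2) / np.mean(sine[core] ** 2))
        assert atten < 0.1  # >= 20 dB

        spikes = np.zeros(60000)
        locs = np.arange(5000, 55000, 400)
        for k in locs:
            spikes[k - 10:k + 11] += np.exp(-0.5 * ((np.arange(-10, 11)) / 2.0) ** 2)
        out_sp = filter_lowfreq_wavelet(spikes, FS)
        assert np.all(np.abs(out_sp[locs] - 1.0) < 0.1)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            filter_lowfreq_wavelet(np.array([1.0, np.nan] * 600), FS)


class TestDetectR:
    def test_flat_signal_empty(self):
        with pytest.warns(UserWarning):
            out = detect_r_peaks(np.zeros(5000), FS)
        assert len(out) == 0

    def test_clean_record_perfect(self, clean_record):
        filtered = filter_lowfreq_wavelet(clean_record.samples, FS)
        det = detect_r_peaks(filtered, FS)
        assert _f1(det, clean_record.truth.r_times) == 1.0

    def test_refractory_and_monotone(self, clean_record):
        filtered = filter_lowfreq_wavelet(clean_record.samples, FS)
        det = detect_r_peaks(filtered, FS)
        assert np.all(np.diff(det) >= 0.2)

    def test_inverted_polarity(self, clean_record):
        filtered = filter_lowfreq_wavelet(-clean_record.samples, FS)
        det = detect_r_peaks(filtered, FS)
        assert _f1(det, clean_record.truth.r_times) >= 0.99

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_records(self, seed):
        p = SubjectParams(n_stages=2, stage_len_s=60.0, snr_db=10.0)
        rec = simulate_ecg(p, seed)
        det = detect_r_peaks(filter_lowfreq_wavelet(rec.samples, FS), FS)
        assert _f1(det, rec.truth.r_times) >= 0.98


class TestDelineate:
    def test_matches_truth(self, clean_record):
        rec = clean_record
        x = filter_lowfreq_wavelet(rec.samples, FS)
        fid = delineate_pqst(x, FS, rec.truth.r_times)
        for w in WAVES:
            truth = rec.truth.fiducials[w]
            found = fid.times[w]
            ok = np.isfinite(found)
            assert ok.mean() > 0.9
            assert np.median(np.abs(found[ok] - truth[ok])) < 0.010

    def test_zeroed_p_marked_missing(self):
        p = SubjectParams(n_stages=2, stage_len_s=30.0, wander_amp=0.0,
                          poly_drift=0.0, snr_db=None)
        p.morphology["p"] = (0.0, -160.0, 25.0)
        p.morphology = {w: (0.0, o, wd) if w == "p" else (a, o, wd)
                        for w, (a, o, wd) in p.morphology.items()}
        rec = simulate_ecg(p, 0)
        fid = delineate_pqst(rec.samples, FS, rec.truth.r_times)
        assert fid.missing("p").mean() > 0.9

    def test_translation_invariance(self):
        # identical beats, constant RR -> identical per-beat offsets
        p = SubjectParams(hf_amp=0.0, lf_amp=0.0, rr_jitter=0.0, r_mod_depth=0.0,
                          t_drift=0.0, severity_slope=0.0, n_stages=2,
                          stage_len_s=30.0, wander_amp=0.0, poly_drift=0.0, snr_db=None)
        rec = simulate_ecg(p, 0)
        fid = delineate_pqst(rec.samples, FS, rec.truth.r_times)
        for w in ("p", "q", "s", "t"):
            off = fid.times[w] - fid.times["r"]
            off = off[np.isfinite(off)][1:-1]
            assert np.ptp(off) <= 1.0 / FS + 1e-12

    def test_needs_two_beats(self):
        with pytest.raises(ValueError):
            delineate_pqst(np.zeros(1000), FS, np.array([0.5]))


class TestAugment:
    def _fid(self):
        t_r = np.array([0.0, 1.0, 2.1])
        times = {w: t_r + off for w, off in
                 (("p", -0.15), ("q", -0.04), ("r", 0.0), ("s", 0.04), ("t", 0.3))}
        amps = {w: np.full(3, a) for w, a in
                (("p", 0.1), ("q", -0.1), ("r", 1.0), ("s", -0.2), ("t", 0.4))}
        return FiducialSet(times, amps)

    def test_stated_rule(self):
        fid = self._fid()
        fid.times["t"][2] = np.nan  # RR ratio = 1.1/1.0
        out = augment_missing_peaks(fid)
        assert np.isclose(out.times["t"][2] - out.times["r"][2], 0.3 * 1.1)
        assert out.amps["t"][2] == fid.amps["t"][1]
        assert out.imputed["t"][2]

    def test_no_missing_identity(self):
        fid = self._fid()
        out = augment_missing_peaks(fid)
        for w in WAVES:
            assert np.array_equal(out.times[w], fid.times[w])
            assert not out.imputed[w].any()

    def test_leading_fill(self):
        fid = self._fid()
        fid.times["p"][0] = np.nan
        out = augment_missing_peaks(fid)
        assert np.isclose(out.times["p"][0] - out.times["r"][0],
                          fid.times["p"][1] - fid.times["r"][1])

    def test_never_alters_present(self):
        rng = np.random.default_rng(0)
        fid = random_fiducials(rng, 30)
        fid.times["t"][::3] = np.nan
        out = augment_missing_peaks(fid)
        keep = np.isfinite(fid.times["t"])
        assert np.array_equal(out.times["t"][keep], fid.times["t"][keep])

    def test_all_missing_error(self):
        fid = self._fid()
        fid.times["s"][:] = np.nan
        with pytest.raises(ValueError):
            augment_missing_peaks(fid)

    def test_imputed_t_near_truth(self, clean_record):
        rec = clean_record
        truth_t = rec.truth.fiducials["t"].copy()
        times = {w: rec.truth.fiducials[w].copy() for w in WAVES}
        amps = {w: rec.truth.fiducial_amps[w].copy() for w in WAVES}
        times["t"][2::3] = np.nan
        out = augment_missing_peaks(FiducialSet(times, amps))
        err = np.abs(out.times["t"][2::3] - truth_t[2::3])
        assert np.max(err) < 0.025


class TestNormalize:
    def _simple(self):
        x = np.zeros(3001)
        r_idx = np.array([500, 1500, 2500])
        x[r_idx] = 2.0
        times = {w: r_idx / FS + off for w, off in
                 (("p", -0.15), ("q", -0.04), ("r", 0.0), ("s", 0.04), ("t", 0.3))}
        amps = {w: np.array([0.1, 0.1, 0.1]) for w in WAVES}
        amps["r"] = np.array([2.0, 2.0, 2.0])
        return x, FiducialSet(times, amps)

    def test_scaling(self):
        x, fid = self._simple()
        out_x, out_fid = normalize_amplitude(x, fid)
        assert np.allclose(out_fid.amps["r"], 1.0)
        assert abs(np.median(out_x)) < 1e-9

    def test_idempotent(self):
        x, fid = self._simple()
        x1, f1 = normalize_amplitude(x, fid)
        x2, f2 = normalize_amplitude(x1, f1)
        assert np.allclose(x1, x2, atol=1e-9)
        for w in WAVES:
            assert np.allclose(f1.amps[w], f2.amps[w], atol=1e-9)

    def test_affine_invariance(self):
        x, fid = self._simple()
        x1, f1 = normalize_amplitude(x, fid)
        fid2 = fid.copy()
        for w in WAVES:
            fid2.amps[w] = 3.5 * fid2.amps[w] + 0.7
        x2, f2 = normalize_amplitude(3.5 * x + 0.7, fid2)
        assert np.allclose(x1, x2, atol=1e-9)
        for w in WAVES:
            assert np.allclose(f1.amps[w], f2.amps[w], atol=1e-9)

    def test_zero_mean_r_error(self):
        x, fid = self._simple()
        fid.amps["r"] = np.zeros(3)
        x = np.zeros_like(x)
        with pytest.raises(ValueError):
            normalize_amplitude(x, fid)
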