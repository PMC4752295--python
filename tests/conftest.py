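import numpy as np
import pytest

from ecgstab.datatypes import FiducialSet, WAVES
from ecgstab.synthetic import SubjectParams, simulate_ecg


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, wander-free subject parameters."""
    return SubjectParams(subject_id="clean", n_stages=2, stage_len_s=120.0,
                         wander_amp=0.0, poly_drift=0.0, snr_db=None)


@pytest.fixture(scope="session")
def clean_record(clean_params):
    return simulate_ecg(clean_params, seed=7)


def random_fiducials(rng, n_beats=20):
    """Random but physiologically ordered fiducial set (test helper)."""
    t_r = np.cumsum(rng.uniform(0.6, 1.1, n_beats))
    offsets = {"p": -0.16, "q": -0.035, "r": 0.0, "s": 0.03, "t": 0.25}
    times = {w: t_r + offsets[w] + (rng.uniform(-0.01, 0.01, n_beats) if w != "r" else 0.0)
             for w in WAVES}
    amps = {w: rng.uniform(0.2, 1.5, n_beats) * (1 if w in ("p", "r", "t") else -1)
            for w in WAVES}
    return FiducialSet(times, amps)
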