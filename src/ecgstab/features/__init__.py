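"""Feature families and the frozen feature manifest.

The manifest enumerates every feature name with its family and kind; the
enumeration is deterministic and a frozen copy ships with the package
(``manifest.csv``) so changes to the feature space are detectable.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from ..datatypes import FiducialSet, RrSeries, WAVES


def _reference_fiducials(n_beats: int = 50) -> FiducialSet:
    """Small deterministic fiducial set used only to enumerate names."""
    k = np.arange(n_beats)
    t_r = np.cumsum(0.8 + 0.02 * np.sin(0.7 * k))
    offsets = {"p": -0.16, "q": -0.035, "r": 0.0, "s": 0.03, "t": 0.25}
    base_amp = {"p": 0.15, "q": -0.12, "r": 1.0, "s": -0.2, "t": 0.35}
    times = {w: t_r + offsets[w] for w in WAVES}
    amps = {w: base_amp[w] * (1.0 + 0.05 * np.cos(0.9 * k + i))
            for i, w in enumerate(WAVES)}
    return FiducialSet(times, amps)


def feature_manifest() -> pd.DataFrame:
    """Enumerate all feature names with family and kind tags."""
    from . import dtcwt as dtcwt_mod
    from . import hrv as hrv_mod
    from . import morphology as morph_mod
    from . import tautstring as ts_mod

    fid = _reference_fiducials()
    rr = RrSeries(z=np.diff(fid.times["r"]) * 1000.0)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in morph_mod.interval_ratio_features(fid):
            rows.append((name, "morphology", "interval_ratio"))
        for name in morph_mod.amplitude_features(fid):
            kind = ("amp_interaction" if "*" in name
                    else "amp_ratio" if "/" in name else "amp_base")
            rows.append((name, "morphology", kind))
        for name in morph_mod.hrv_spectral_extra(rr):
            rows.append((name, "morphology", "hrv_spectral"))
        edr = morph_mod.derive_respiration(fid)
        for name in morph_mod.respiratory_features(edr):
            rows.append((name, "morphology", "respiratory"))
        for name in ts_mod.ts_feature_set(rr):
            rows.append((name, "tautstring", "ts_stat"))
        rng = np.random.default_rng(0)
        decomp = dtcwt_mod.dtcwt_decompose(rng.normal(size=512))
        for name in dtcwt_mod.dtcwt_feature_set(decomp):
            rows.append((name, "dtcwt", "dtcwt_stat"))
        for name in hrv_mod.TYPICAL_HRV_FEATURES:
            rows.append((name, "hrv_traditional", "hrv_typical"))
    manifest = pd.DataFrame(rows, columns=["name", "family", "kind"])
    if manifest["name"].duplicated().any():
        raise RuntimeError("duplicate feature names in manifest")
    return manifest


def frozen_manifest() -> pd.DataFrame:
    """The manifest copy shipped with the package."""
    with resources.files(__package__).joinpath("manifest.csv").open() as fh:
        return pd.read_csv(fh)
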