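"""5-level dual-tree complex wavelet decomposition and feature family.

Two parallel orthonormal wavelet trees: level 1 shares one filter pair
between the trees with a one-sample delay, levels 2-5 use a Q-shift pair
(tree B = time reverse of tree A), giving the half-sample delay offset
that makes the complex subbands approximately analytic and therefore
approximately shift invariant. Because every tree is an orthonormal
periodic filter bank, the inverse transform is exact and subband energy
equals signal energy to machine precision.

Complex coefficients are (tree A + i * tree B) / sqrt(2), so the energy
of the complex subbands plus the lowpass remainder equals the energy of
the analysed (padded) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..wavelets import analysis_step, pad_to_multiple, qmf_highpass, synthesis_step
from ._filters import DB10, QSHIFT_14
from ._stats import basic_stats

N_LEVELS = 5

_H_L1 = DB10
_G_L1 = qmf_highpass(DB10)
_H_A = QSHIFT_14
_G_A = qmf_highpass(QSHIFT_14)
_H_B = QSHIFT_14[::-1].copy()
_G_B = qmf_highpass(_H_B)

#: Canonical names of the two selected features.
F1_NAME = "dt_res3_kurt"   # kurtosis of the residual after removing levels 1-3
F2_NAME = "dt_res5_mean"   # mean of the final (all-levels-removed) residual


@dataclass
class DtcwtDecomposition:
    """Dual-tree decomposition of one window.

    ``subbands[j]`` is the complex coefficient sequence of level j+1;
    ``lowpass`` the complex scaling remainder; ``residuals[j]`` the
    original-domain signal minus the cumulative reconstruction of levels
    1..j+1 (``residuals[-1]`` is the final residual waveform).
    """

    subbands: list        # complex arrays, finest first
    lowpass: np.ndarray   # complex
    residuals: list       # real arrays, original length
    input_len: int
    _tree_a: tuple = field(repr=False, default=None)
    _tree_b: tuple = field(repr=False, default=None)
    _pad_slice: slice = field(repr=False, default=None)
    _padded_len: int = field(repr=False, default=0)

    @property
    def levels(self) -> int:
        return len(self.subbands)

    def magnitudes(self, level: int) -> np.ndarray:
        return np.abs(self.subbands[level - 1])

    def energy_balance(self) -> tuple[float, float]:
        """(sum of subband + lowpass energies, energy of the analysed signal)."""
        sub = sum(float(np.sum(np.abs(c) ** 2)) for c in self.subbands)
        sub += float(np.sum(np.abs(self.lowpass) ** 2))
        return sub, self._analysed_energy

    _analysed_energy: float = 0.0


def _tree_decompose(xp: np.ndarray, first_h, first_g, h, g, levels: int):
    a, d0 = analysis_step(xp, first_h, first_g)
    details = [d0]
    for _ in range(1, levels):
        a, d = analysis_step(a, h, g)
        details.append(d)
    return a, details


def _tree_reconstruct(approx, details, first_h, first_g, h, g):
    a = approx
    for d in reversed(details[1:]):
        a = synthesis_step(a, d, h, g)
    return synthesis_step(a, details[0], first_h, first_g)


def dtcwt_decompose(samples: np.ndarray, levels: int = N_LEVELS) -> DtcwtDecomposition:
    """Decompose a window into complex subbands, lowpass and residuals."""
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if len(x) < (1 << levels):
        raise ValueError(f"need at least {1 << levels} samples")
    xp, sl = pad_to_multiple(x, 1 << levels)

    a_a, det_a = _tree_decompose(xp, _H_L1, _G_L1, _H_A, _G_A, levels)
    # Tree B sees the one-sample-advanced signal (periodic shift); combined
    # with the reversed Q-shift filters this makes the complex wavelets
    # nearly analytic (negative-frequency energy < 0.1% per level).
    a_b, det_b = _tree_decompose(np.roll(xp, -1), _H_L1, _G_L1, _H_B, _G_B, levels)

    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    subbands = [(da + 1j * db) * inv_sqrt2 for da, db in zip(det_a, det_b)]
    lowpass = (a_a + 1j * a_b) * inv_sqrt2

    decomp = DtcwtDecomposition(
        subbands=subbands, lowpass=lowpass, residuals=[], input_len=len(x),
        _tree_a=(a_a, det_a), _tree_b=(a_b, det_b), _pad_slice=sl,
        _padded_len=len(xp))
    decomp._analysed_energy = float(np.sum(xp ** 2))

    for j in range(1, levels + 1):  # remainder after removing levels 1..j
        da = [d if k >= j else np.zeros_like(d) for k, d in enumerate(det_a)]
        db = [d if k >= j else np.zeros_like(d) for k, d in enumerate(det_b)]
        ra = _tree_reconstruct(a_a, da, _H_L1, _G_L1, _H_A, _G_A)
        rb = np.roll(_tree_reconstruct(a_b, db, _H_L1, _G_L1, _H_B, _G_B), 1)
        decomp.residuals.append(((ra + rb) / 2.0)[sl])
    return decomp


def dtcwt_reconstruct(decomp: DtcwtDecomposition) -> np.ndarray:
    """Exact inverse: average of the two trees' reconstructions."""
    a_a, det_a = decomp._tree_a
    a_b, det_b = decomp._tree_b
    xa = _tree_reconstruct(a_a, det_a, _H_L1, _G_L1, _H_A, _G_A)
    xb = np.roll(_tree_reconstruct(a_b, det_b, _H_L1, _G_L1, _H_B, _G_B), 1)
    return ((xa + xb) / 2.0)[decomp._pad_slice]


def dtcwt_feature_set(decomp: DtcwtDecomposition) -> dict[str, float]:
    """Statistics of real/imaginary/magnitude parts per level and of the
    cumulative residual waveforms; includes the two selected features
    F1 = kurtosis of the level-3 residual, F2 = mean of the final residual."""
    out: dict[str, float] = {}
    for j, c in enumerate(decomp.subbands, start=1):
        for comp, arr in (("re", c.real), ("im", c.imag), ("mag", np.abs(c))):
            out.update(basic_stats(arr, f"dt_l{j}_{comp}"))
    for j, r in enumerate(decomp.residuals, start=1):
        out.update(basic_stats(r, f"dt_res{j}"))
    return out
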