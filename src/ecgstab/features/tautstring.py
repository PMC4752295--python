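"""Taut-string decomposition of the R-R series and its feature family.

For a tube of half-width epsilon around the interval series z, the taut
string x is the unique minimizer of the squared first-difference energy
subject to ``max|z - x| <= epsilon`` (free endpoints). The residual
y = z - x isolates variability of amplitude at or below epsilon; its mean
absolute first difference v(epsilon) is the variability index whose
epsilon = 32 ms member is the "Taut String 32" feature.

The solver is the greedy tube (string-funnel) construction: straight
segments between wall contacts, bending upward only on upper-wall
contacts and downward only on lower-wall contacts, flat at the free ends.
Each committed segment consumes its points, so runtime is linear in
practice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..datatypes import RrSeries
from ._stats import kurtosis, skewness

DEFAULT_EPS_GRID = (4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0)  # ms
TAUT_STRING_32 = "ts32_v"


@dataclass
class TautStringResult:
    epsilon: float
    x: np.ndarray   # taut-string estimate
    y: np.ndarray   # residual z - x

    def __post_init__(self):
        if np.max(np.abs(self.y), initial=0.0) > self.epsilon + 1e-9:
            raise ValueError("tube constraint violated")


def _fill_segment(x: np.ndarray, i0: int, y0: float, i1: int, y1: float):
    """Write the straight segment (i0,y0)->(i1,y1) into x[i0..i1]."""
    x[i0:i1 + 1] = np.linspace(y0, y1, i1 - i0 + 1)


def _taut_string_tube(lo: np.ndarray, up: np.ndarray) -> np.ndarray:
    n = len(lo)
    x = np.empty(n)
    if n == 1:
        x[0] = (lo[0] + up[0]) / 2.0
        return x

    # Free start: the string is flat until its first wall contact.
    U, ju = up[0], 0   # lowest ceiling so far (last index achieving it)
    L, jl = lo[0], 0   # highest floor so far
    apex = None
    for j in range(1, n):
        if lo[j] > U:          # floor forces the string up over the ceiling
            x[: ju + 1] = U
            apex = (ju, U)
            break
        if up[j] < L:          # ceiling forces it down over the floor
            x[: jl + 1] = L
            apex = (jl, L)
            break
        if up[j] <= U:
            U, ju = up[j], j
        if lo[j] >= L:
            L, jl = lo[j], j
    if apex is None:           # a flat string fits the whole tube
        x[:] = (L + U) / 2.0
        return x

    # Scalar-apex scans: straight runs between committed wall contacts.
    ia, a = apex
    while ia < n - 1:
        s_hi, j_hi = np.inf, None
        s_lo, j_lo = -np.inf, None
        bend = None
        for j in range(ia + 1, n):
            d = j - ia
            sh = (up[j] - a) / d
            sl = (lo[j] - a) / d
            if sl > s_hi:      # must rise above the tightest ceiling line
                bend = (j_hi, up[j_hi])
                break
            if sh < s_lo:      # must drop below the tightest floor line
                bend = (j_lo, lo[j_lo])
                break
            if sh <= s_hi:
                s_hi, j_hi = sh, j
            if sl >= s_lo:
                s_lo, j_lo = sl, j
        if bend is None:
            # Tail: flat if a zero slope fits, else straight to the
            # binding wall contact and re-scan from there.
            if s_lo <= 0.0 <= s_hi:
                x[ia:] = a
                x[ia] = a
                return x
            bend = (j_lo, lo[j_lo]) if s_lo > 0.0 else (j_hi, up[j_hi])
        _fill_segment(x, ia, a, bend[0], bend[1])
        ia, a = bend
    return x


def taut_string(z: RrSeries | np.ndarray, epsilon: float) -> TautStringResult:
    """Compute the taut-string decomposition z = x + y at tube width epsilon."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    v = z.z if isinstance(z, RrSeries) else np.asarray(z, dtype=float)
    x = _taut_string_tube(v - epsilon, v + epsilon)
    x = np.clip(x, v - epsilon, v + epsilon)  # shave float drift
    return TautStringResult(epsilon=float(epsilon), x=x, y=v - x)


def inflection_count(x: np.ndarray) -> int:
    """Sign changes of the second difference; zero-runs counted once."""
    d2 = np.diff(np.asarray(x, dtype=float), 2)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(x), initial=0.0)))
    s = np.sign(d2[np.abs(d2) > tol])
    if len(s) < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def variability_index(result: TautStringResult) -> float:
    """v(epsilon): mean absolute first difference of the residual."""
    return float(np.mean(np.abs(np.diff(result.y))))


def ts_feature_set(z: RrSeries | np.ndarray, eps_grid=DEFAULT_EPS_GRID) -> dict[str, float]:
    """Per-epsilon statistics of the estimate and residual.

    For each epsilon: moments of x and y, inflection count of x, and the
    variability index v(epsilon). ``ts32_v`` is the Taut String 32 feature.
    """
    if len(eps_grid) == 0:
        raise ValueError("eps_grid must be non-empty")
    out: dict[str, float] = {}
    for eps in sorted(eps_grid):
        res = taut_string(z, eps)
        tag = f"ts{eps:g}"
        for part, arr in (("x", res.x), ("y", res.y)):
            out[f"{tag}_{part}_mean"] = float(np.mean(arr))
            out[f"{tag}_{part}_std"] = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
            out[f"{tag}_{part}_skew"] = skewness(arr)
            out[f"{tag}_{part}_kurt"] = kurtosis(arr)
        out[f"{tag}_inflections"] = float(inflection_count(res.x))
        out[f"{tag}_v"] = variability_index(res)
    return out


def dump_decomposition(path, z: RrSeries | np.ndarray, eps_grid=DEFAULT_EPS_GRID) -> Path:
    """Write (epsilon, index, z, x, y) rows as CSV for diagnostics."""
    v = z.z if isinstance(z, RrSeries) else np.asarray(z, dtype=float)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epsilon", "index", "z", "x", "y"])
        for eps in sorted(eps_grid):
            res = taut_string(v, eps)
            for i, (zi, xi, yi) in enumerate(zip(v, res.x, res.y)):
                writer.writerow([eps, i, zi, xi, yi])
    return path
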