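"""Empirical mode decomposition by envelope sifting.

EMD splits a signal into intrinsic mode functions (IMFs) ordered from high to
low frequency.  Each sifting pass subtracts the mean of the cubic-spline
envelopes through the local maxima and minima; a candidate mode is accepted
when the Cauchy sifting ratio SD = Σ(h_prev − h)² / Σ h_prev² drops below the
configured threshold and the mode satisfies the two IMF restrictions
(|#extrema − #zero-crossings| ≤ 1 and near-zero envelope mean).  The residue
after the last extractable mode is monotone (≤ 2 extrema), and by construction
the modes plus the residue sum back to the input exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateSignalError

__all__ = ["SiftConfig", "IMFSet", "local_extrema", "envelope_mean", "sift", "decompose"]


@dataclass
class SiftConfig:
    """Sifting controls.

    sd_threshold is the Cauchy stop ratio (Huang's classic 0.2); max_sifts
    bounds iterations per mode; max_imfs bounds the number of extracted modes;
    boundary names the end-extension scheme (only ``mirror`` is implemented).
    """

    sd_threshold: float = 0.2
    max_sifts: int = 50
    max_imfs: int = 15
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sifts < 1:
            raise ValueError("max_sifts must be >= 1")


@dataclass
class IMFSet:
    """Ordered IMFs c_1..c_n plus the residue of one decomposition."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residue: np.ndarray | None = None
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct_full(self) -> np.ndarray:
        """Sum of every IMF plus the residue (equals the source signal)."""
        out = np.array(self.residue, dtype=float, copy=True)
        for c in self.imfs:
            out += c
        return out

    def as_matrix(self) -> np.ndarray:
        """(n_imfs + 1, N) array: one row per IMF, last row the residue."""
        return np.vstack(self.imfs + [self.residue])

    def to_csv(self, path) -> None:
        """Dump one column per IMF plus the residue, for plotting."""
        header = ",".join([f"c{i + 1}" for i in range(len(self.imfs))]
                          + ["residue"])
        np.savetxt(path, self.as_matrix().T, delimiter=",", header=header,
                   comments="")


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima.

    Plateaus (runs of equal samples) contribute their midpoint index, per the
    strict-sign-change convention on the plateau-compressed sequence.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.flatnonzero(np.diff(x) != 0)
    if change.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    run_starts = np.r_[0, change + 1]
    run_ends = np.r_[change, n - 1]
    mids = (run_starts + run_ends) // 2
    vals = x[run_starts]
    dv = np.sign(np.diff(vals))
    interior_max = np.flatnonzero((dv[:-1] > 0) & (dv[1:] < 0)) + 1
    interior_min = np.flatnonzero((dv[:-1] < 0) & (dv[1:] > 0)) + 1
    return mids[interior_max], mids[interior_min]


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def _is_imf(x: np.ndarray) -> bool:
    mx, mn = local_extrema(x)
    return abs((mx.size + mn.size) - _zero_crossings(x)) <= 1


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to two extrema about each end of the support [0, n-1]."""
    k = min(2, idx.size)
    left_t = (-idx[:k])[::-1]
    left_v = val[:k][::-1]
    right_t = (2 * (n - 1) - idx[-k:])[::-1]
    right_v = val[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([left_v, val, right_v])
    # reflections of an endpoint extremum coincide with itself; drop duplicates
    t, keep = np.unique(t, return_index=True)
    return t, v[keep]


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean m(t) of the upper/lower cubic-spline envelopes of ``x``.

    Raises DegenerateSignalError when fewer than two maxima or two minima
    exist (the caller treats such a signal as a residue).
    """
    x = np.asarray(x, dtype=float)
    mx, mn = local_extrema(x)
    if mx.size < 2 or mn.size < 2:
        raise DegenerateSignalError("too few extrema for envelope construction")
    n = x.size
    grid = np.arange(n)
    t_up, v_up = _mirror_extend(mx, x[mx], n)
    t_lo, v_lo = _mirror_extend(mn, x[mn], n)
    e1 = CubicSpline(t_up, v_up, bc_type="natural")(grid)
    e2 = CubicSpline(t_lo, v_lo, bc_type="natural")(grid)
    return (e1 + e2) / 2.0


def sift(x: np.ndarray, cfg: SiftConfig | None = None) -> np.ndarray:
    """Extract one IMF from ``x`` by repeated envelope-mean subtraction."""
    cfg = cfg or SiftConfig()
    h = np.array(x, dtype=float, copy=True)
    if not np.all(np.isfinite(h)):
        raise DegenerateSignalError("non-finite samples")
    if np.ptp(h) == 0:
        raise DegenerateSignalError("constant signal cannot be sifted")
    for _ in range(cfg.max_sifts):
        try:
            m = envelope_mean(h)
        except DegenerateSignalError:
            break
        h_new = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < cfg.sd_threshold and _is_imf(h):
            break
    else:
        warnings.warn("sifting did not converge within max_sifts", stacklevel=2)
    return h


def decompose(x: np.ndarray, cfg: SiftConfig | None = None, source_id: str = "") -> IMFSet:
    """Full EMD of ``x``: IMFs extracted high-to-low frequency plus residue.

    Stops when the running residue is monotone (≤ 2 extrema) or ``max_imfs``
    modes have been extracted.  Constant input yields zero IMFs with the
    input itself as residue.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateSignalError("non-finite samples")
    r = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        mx, mn = local_extrema(r)
        if mx.size + mn.size <= 2 or mx.size < 2 or mn.size < 2:
            break
        c = sift(r, cfg)
        if float(np.max(np.abs(c))) <= 1e-12 * max(float(np.max(np.abs(x))), 1e-300):
            break
        imfs.append(c)
        r = r - c
    return IMFSet(imfs=imfs, residue=r, source_id=source_id)
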