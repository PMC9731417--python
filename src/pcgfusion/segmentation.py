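"""S1/S2 localisation and the four cardiac reserve times.

The segmenter is a Shannon-energy envelope detector in the Liang style:
band-pass 25–150 Hz (where S1/S2 energy concentrates), per-sample Shannon
energy smoothed over 20 ms, adaptive detection threshold at mean + 0.5·SD of
the normalised envelope, burst merging across gaps shorter than 50 ms, and
burst boundary refinement at 10 % of each burst's peak smoothed energy.
S1 and S2 are told apart by the physiological rule that systole (S1→S2) is
shorter than diastole (S2→next S1).

The reserve times summarise one recording: T1 (S1 width), T2 (S2 width),
T12 (S1 onset to S2 onset) and T11 (cycle period, S1 onset to next S1
onset), each averaged across the detected cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import SegmentationError

__all__ = ["CycleSegmentation", "ReserveTimes", "segment", "reserve_times"]

BAND = (25.0, 150.0)       # Hz, S1/S2 passband
SMOOTH_WIN = 0.020         # s, envelope moving-average window
THRESH_SD = 0.5            # detection threshold: mean + THRESH_SD * SD
MERGE_GAP = 0.050          # s, bursts closer than this are merged
EDGE_FRACTION = 0.10       # burst boundary at this fraction of peak energy
MAX_BURST = 0.30           # s, longer bursts indicate segmentation failure
MAX_DUTY = 0.60            # supra-threshold duty cycle beyond this → noise
MAX_BURST_RATE = 5.0       # bursts/s; > 2 cycles/s × (S1+S2) is implausible
MAX_CYCLE_CV = 0.35        # coefficient of variation of S1→S1 intervals
MAX_SYS_DIA_RATIO = 0.85   # systole must be clearly shorter than diastole


@dataclass
class CycleSegmentation:
    """Detected cardiac cycles: (s1_start, s1_end, s2_start, s2_end) seconds."""

    cycles: list[tuple[float, float, float, float]]
    fs: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for (a, b, c, d) in self.cycles:
            if not (a < b < c < d):
                raise ValueError("cycle boundaries out of order")
            if a < prev_end:
                raise ValueError("cycles overlap")
            prev_end = d

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class ReserveTimes:
    """Per-recording cardiac reserve times, in seconds."""

    T1: float   # S1 width
    T2: float   # S2 width
    T11: float  # cycle period (S1 onset to next S1 onset)
    T12: float  # S1 onset to S2 onset within a cycle

    def as_dict(self) -> dict[str, float]:
        return {"T1": self.T1, "T2": self.T2, "T11": self.T11, "T12": self.T12}


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, win)
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(idx[0::2], idx[1::2]))


def _refine_burst(energy: np.ndarray, lo: int, hi: int, left_bound: int,
                  right_bound: int, fs: float) -> tuple[float, float] | None:
    """Boundary times at EDGE_FRACTION of the burst's peak smoothed energy."""
    peak_idx = lo + int(np.argmax(energy[lo:hi]))
    peak = energy[peak_idx]
    if peak <= 0:
        return None
    level = EDGE_FRACTION * peak
    i = peak_idx
    while i > left_bound and energy[i] > level:
        i -= 1
    # linear interpolation at the crossing
    if energy[i] <= level and i < peak_idx:
        e0, e1 = energy[i], energy[i + 1]
        frac = (level - e0) / (e1 - e0) if e1 > e0 else 0.0
        start = (i + frac) / fs
    else:
        start = i / fs
    j = peak_idx
    while j < right_bound - 1 and energy[j] > level:
        j += 1
    if energy[j] <= level and j > peak_idx:
        e0, e1 = energy[j - 1], energy[j]
        frac = (e0 - level) / (e0 - e1) if e0 > e1 else 1.0
        end = (j - 1 + frac) / fs
    else:
        end = j / fs
    return start, end


def segment(x, fs: float) -> CycleSegmentation:
    """Locate S1/S2 bursts and assemble complete cardiac cycles.

    Raises SegmentationError when no plausible burst train exists (fewer than
    three bursts, implausibly long bursts, or a noise-like duty cycle).
    """
    x = np.asarray(x, dtype=float)
    if x.size < int(1.2 * fs):
        raise SegmentationError("recording shorter than one cardiac cycle")
    sos = butter(4, BAND, btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, x)
    peak = np.max(np.abs(y))
    if peak == 0:
        raise SegmentationError("silent recording")
    y = y / peak

    win = int(round(SMOOTH_WIN * fs))
    y2 = y ** 2
    shannon = _moving_average(-y2 * np.log(y2 + 1e-12), win)
    energy = _moving_average(y2, win)

    nenv = (shannon - shannon.mean()) / (shannon.std() or 1.0)
    mask = nenv > THRESH_SD
    if mask.mean() > MAX_DUTY:
        raise SegmentationError("noise-like envelope (duty cycle too high)")
    runs = _runs(mask)
    if not runs:
        raise SegmentationError("no bursts above threshold")

    # merge bursts separated by short gaps
    gap = int(round(MERGE_GAP * fs))
    merged = [list(runs[0])]
    for lo, hi in runs[1:]:
        if lo - merged[-1][1] < gap:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    merged = [(lo, hi) for lo, hi in merged if (hi - lo) / fs > 0.010]
    if len(merged) < 3:
        raise SegmentationError("fewer than three bursts detected")
    if any((hi - lo) / fs > MAX_BURST for lo, hi in merged):
        raise SegmentationError("implausibly long burst")
    if len(merged) / (x.size / fs) > MAX_BURST_RATE:
        raise SegmentationError("implausibly many bursts (noise-like input)")

    bounds = []
    for i, (lo, hi) in enumerate(merged):
        left = 0 if i == 0 else (merged[i - 1][1] + lo) // 2
        right = x.size if i == len(merged) - 1 else (hi + merged[i + 1][0]) // 2
        b = _refine_burst(energy, lo, hi, left, right, fs)
        if b is not None:
            bounds.append(b)
    if len(bounds) < 3:
        raise SegmentationError("fewer than three refined bursts")

    onsets = np.array([b[0] for b in bounds])
    intervals = np.diff(onsets)
    even, odd = intervals[0::2], intervals[1::2]
    s1_first = even.mean() < odd.mean()  # shorter interval = systole follows S1
    short, long_ = (even, odd) if s1_first else (odd, even)
    if short.mean() > MAX_SYS_DIA_RATIO * long_.mean():
        raise SegmentationError("no systole/diastole asymmetry (noise-like input)")
    s1_idx = range(0 if s1_first else 1, len(bounds) - 1, 2)

    cycles = []
    for j in s1_idx:
        s1s, s1e = bounds[j]
        s2s, s2e = bounds[j + 1]
        if s1s < s1e < s2s < s2e:
            cycles.append((s1s, s1e, s2s, s2e))
    if not cycles:
        raise SegmentationError("no complete S1→S2 cycle found")
    s1_onsets = np.array([c[0] for c in cycles])
    if s1_onsets.size >= 3:
        gaps = np.diff(s1_onsets)
        if gaps.std() / gaps.mean() > MAX_CYCLE_CV:
            raise SegmentationError("irregular cycle train (noise-like input)")
    return CycleSegmentation(cycles=cycles, fs=fs)


def reserve_times(seg: CycleSegmentation) -> ReserveTimes:
    """Average T1/T2/T11/T12 over the detected cycles.

    T11 needs at least two S1 onsets; a single-cycle segmentation raises.
    """
    if len(seg) < 1:
        raise SegmentationError("no cycles")
    arr = np.asarray(seg.cycles)
    t1 = float(np.mean(arr[:, 1] - arr[:, 0]))
    t2 = float(np.mean(arr[:, 3] - arr[:, 2]))
    t12 = float(np.mean(arr[:, 2] - arr[:, 0]))
    if len(seg) < 2:
        raise SegmentationError("T11 undefined with a single S1 onset")
    t11 = float(np.mean(np.diff(arr[:, 0])))
    return ReserveTimes(T1=t1, T2=t2, T11=t11, T12=t12)
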