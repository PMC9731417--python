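"""Synthetic phonocardiogram generator with exact ground truth.

Each record is a train of Gabor bursts (Gaussian-windowed sinusoids) for the
first (S1) and second (S2) heart sounds, optionally a class-specific murmur
(band-passed noise in a stated band, placed in systole or diastole) or a
mid-systolic click, plus additive white noise at a stated SNR.  Burst widths
are quoted as the support between the 10 %-of-peak points of the energy
envelope, the same convention the segmenter uses to refine burst boundaries,
so generated onsets/offsets are directly comparable to detected ones.

The five default archetypes mirror the valve conditions distinguished in the
classification study — aortic stenosis (AS, harsh mid-systolic murmur),
mitral stenosis (MS, diastolic rumble), mitral regurgitation (MR, holo-
systolic murmur), mitral valve prolapse (MVP, mid-systolic click with a late
murmur) and normal heart sounds (NHS) — without any claim of clinical
realism beyond band placement and timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import PCGRecord, DatasetManifest, PIPELINE_FS
from .segmentation import CycleSegmentation

__all__ = ["SynthSpec", "generate", "generate_corpus", "default_class_specs"]

# energy envelope exp(-t^2/sigma^2) falls to 10% at t = sigma*sqrt(ln 10)
_WIDTH_TO_SIGMA = 1.0 / (2.0 * np.sqrt(np.log(10.0)))


@dataclass
class SynthSpec:
    """Parameters of one synthetic PCG class archetype."""

    class_name: str = "NHS"
    heart_rate: float = 75.0           # bpm
    s1_freq: float = 35.0              # Hz, dominant S1 burst frequency
    s2_freq: float = 60.0              # Hz
    s1_width: float = 0.09             # s, 10%-energy support
    s2_width: float = 0.08             # s
    s1_amp: float = 1.0
    s2_amp: float = 0.8
    systole_fraction: float = 0.37     # T12 as a fraction of the cycle
    murmur: str = "none"               # none | systolic | diastolic | click
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_level: float = 0.3          # amplitude relative to S1
    click_freq: float = 250.0          # Hz (murmur == "click")
    snr: float = 15.0                  # dB; np.inf for noiseless
    duration: float = 3.0              # s
    fs: float = PIPELINE_FS            # Hz
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.systole_fraction < 0.5:
            raise ValueError("systole_fraction must be in (0, 0.5)")
        top = max(self.s1_freq, self.s2_freq, self.murmur_band[1], self.click_freq)
        if self.fs < 2 * top:
            raise ValueError("fs below Nyquist for the requested frequencies")
        if not np.isfinite(self.heart_rate) or self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


def default_class_specs(snr: float = 15.0, duration: float = 3.0,
                        fs: float = PIPELINE_FS) -> dict[str, SynthSpec]:
    """The five valve-condition archetypes used throughout the test corpus."""
    base = dict(snr=snr, duration=duration, fs=fs)
    return {
        "NHS": SynthSpec(class_name="NHS", heart_rate=72, s1_freq=35, s2_freq=60,
                         murmur="none", **base),
        "AS": SynthSpec(class_name="AS", heart_rate=80, s1_freq=40, s2_freq=65,
                        murmur="systolic", murmur_band=(180.0, 420.0),
                        murmur_level=0.35, **base),
        "MR": SynthSpec(class_name="MR", heart_rate=84, s1_freq=30, s2_freq=55,
                        murmur="systolic", murmur_band=(90.0, 250.0),
                        murmur_level=0.3, **base),
        "MS": SynthSpec(class_name="MS", heart_rate=68, s1_freq=38, s2_freq=62,
                        murmur="diastolic", murmur_band=(100.0, 220.0),
                        murmur_level=0.3, **base),
        "MVP": SynthSpec(class_name="MVP", heart_rate=76, s1_freq=34, s2_freq=58,
                         murmur="click", murmur_band=(200.0, 400.0),
                         murmur_level=0.18, **base),
    }


def _gabor(t: np.ndarray, center: float, width: float, freq: float,
           amp: float, phase: float = 0.0) -> np.ndarray:
    sigma = width * _WIDTH_TO_SIGMA
    env = np.exp(-((t - center) ** 2) / (2.0 * sigma ** 2))
    return amp * env * np.sin(2 * np.pi * freq * (t - center) + phase)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    w = rng.standard_normal(n)
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, w)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _tukey_window(n: int, alpha: float = 0.5) -> np.ndarray:
    from scipy.signal.windows import tukey
    return tukey(n, alpha)


def generate(spec: SynthSpec) -> tuple[PCGRecord, CycleSegmentation, np.ndarray]:
    """Generate one record; returns (record, ground-truth cycles, clean signal).

    The record and the returned clean signal share one normalisation factor
    (max |noisy| = 1), so the additive-noise SNR against the clean signal is
    exactly ``spec.snr``.
    """
    rng = np.random.default_rng(spec.seed)
    fs, dur = spec.fs, spec.duration
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    period = 60.0 / spec.heart_rate
    t12 = spec.systole_fraction * period

    gap_sys = t12 - spec.s1_width
    gap_dia = period - t12 - spec.s2_width
    if gap_sys <= 0 or gap_dia <= 0:
        raise ValueError("infeasible spec: S1/S2 bursts overlap")

    clean = np.zeros(n)
    cycles = []
    k = 0
    t0 = 0.25 * period  # first S1 onset away from the record edge
    while True:
        s1_start = t0 + k * period
        s1_end = s1_start + spec.s1_width
        s2_start = s1_start + t12
        s2_end = s2_start + spec.s2_width
        if s1_end > dur:
            break
        clean += _gabor(t, (s1_start + s1_end) / 2, spec.s1_width,
                        spec.s1_freq, spec.s1_amp)
        if s2_end <= dur:
            clean += _gabor(t, (s2_start + s2_end) / 2, spec.s2_width,
                            spec.s2_freq, spec.s2_amp)
            cycles.append((s1_start, s1_end, s2_start, s2_end))
            if spec.murmur == "systolic":
                i0, i1 = int(s1_end * fs), int(s2_start * fs)
                if i1 - i0 > 32:
                    seg = _band_noise(rng, i1 - i0, fs, spec.murmur_band)
                    clean[i0:i1] += spec.murmur_level * seg * _tukey_window(i1 - i0)
            elif spec.murmur == "diastolic":
                i0 = int(s2_end * fs)
                i1 = min(int((s1_start + period) * fs), n)
                if i1 - i0 > 32:
                    seg = _band_noise(rng, i1 - i0, fs, spec.murmur_band)
                    clean[i0:i1] += spec.murmur_level * seg * _tukey_window(i1 - i0)
            elif spec.murmur == "click":
                c_mid = (s1_end + s2_start) / 2
                clean += _gabor(t, c_mid, 0.02, spec.click_freq,
                                2.0 * spec.murmur_level)
        k += 1

    if not cycles:
        raise ValueError("infeasible spec: no complete cardiac cycle fits")

    if np.isfinite(spec.snr):
        p_sig = float(np.mean(clean ** 2))
        p_noise = p_sig / (10.0 ** (spec.snr / 10.0))
        noisy = clean + rng.standard_normal(n) * np.sqrt(p_noise)
    else:
        noisy = clean.copy()
    scale = np.max(np.abs(noisy)) or 1.0
    noisy = noisy / scale
    clean = clean / scale

    rec = PCGRecord(id=f"synth-{spec.class_name}-{spec.seed}", samples=noisy,
                    fs=fs, label=spec.class_name)
    truth = CycleSegmentation(cycles=cycles, fs=fs)
    return rec, truth, clean


def generate_corpus(class_specs, n_per_class: int, seed: int = 0,
                    hr_jitter: float = 0.10, amp_jitter: float = 0.20,
                    level_jitter: float = 0.10):
    """Balanced labelled corpus with per-record jitter; deterministic per seed.

    ``class_specs`` is a mapping name -> SynthSpec or a list of SynthSpec.
    Returns (records, manifest, truths) where manifest paths are virtual
    ``<class>_<i>.wav`` names in class order.
    """
    if isinstance(class_specs, dict):
        specs = list(class_specs.values())
    else:
        specs = list(class_specs)
    if isinstance(n_per_class, int):
        counts = [n_per_class] * len(specs)
    else:
        counts = list(n_per_class)
    rng = np.random.default_rng(seed)
    records, entries, truths = [], [], []
    for spec, count in zip(specs, counts):
        for i in range(count):
            jspec = replace(
                spec,
                heart_rate=spec.heart_rate * rng.uniform(1 - hr_jitter, 1 + hr_jitter),
                s2_amp=spec.s2_amp * rng.uniform(1 - amp_jitter, 1 + amp_jitter),
                murmur_level=spec.murmur_level * rng.uniform(1 - level_jitter,
                                                             1 + level_jitter),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            rec, truth, _ = generate(jspec)
            rec.id = f"{spec.class_name}_{i}"
            records.append(rec)
            truths.append(truth)
            entries.append((f"{spec.class_name}_{i}.wav", spec.class_name))
    manifest = DatasetManifest(entries=entries,
                               class_names=[s.class_name for s in specs])
    return records, manifest, truths
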