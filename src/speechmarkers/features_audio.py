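"""Paralinguistic features from the speech waveform.

Four blocks, all computed after resampling to 16 kHz mono:

* temporal — syllable-nuclei based speech/articulation rates, speaking
  ratio, and a pronunciation score (fraction of nuclei in voiced frames);
* F0 — summary statistics of the autocorrelation pitch track (75–500 Hz);
* MFCC — mean/variance/skewness/kurtosis of the first 14 mel-frequency
  cepstral coefficients and their first (velocity) and second
  (acceleration) frame differences, 168 features;
* spectral — mean/max/min/std of seven frame-level descriptors (RMS,
  centroid, bandwidth, flatness, zero-crossing rate, loudness in dB,
  spectral flux), 28 features.

Syllable nuclei follow the intensity peak–dip method: a nucleus is an
intensity peak at least 2 dB above its surrounding dips and above the
silence threshold.  All frame parameters live in module constants so they
are auditable and overridable.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional

import numpy as np
from scipy.fft import rfft
from scipy.fftpack import dct
from scipy.signal import find_peaks, resample_poly
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .ingest import Waveform
from .vectors import MISSING, FeatureVector

__all__ = [
    "temporal_stats", "f0_stats", "mfcc_stats", "spectral_stats",
    "extract_audio_features", "PARALINGUISTIC_FEATURES",
    "TARGET_RATE", "FRAME_LENGTH_S", "FRAME_STEP_S",
]

TARGET_RATE = 16000
FRAME_LENGTH_S = 0.025
FRAME_STEP_S = 0.010
SILENCE_DB_BELOW_MAX = 25.0   # silence threshold relative to peak intensity
MIN_PAUSE_S = 0.3             # shorter gaps do not break a speaking interval
NUCLEUS_DIP_DB = 2.0          # minimum peak-over-dip prominence
F0_FLOOR, F0_CEIL = 75.0, 500.0
VOICING_THRESHOLD = 0.45      # normalized autocorrelation peak
N_MFCC = 14
N_MEL_FILTERS = 26
N_FFT = 512
PREEMPHASIS = 0.97
_EPS = 1e-12


def _to_target_rate(w: Waveform) -> Waveform:
    if w.rate == TARGET_RATE:
        return w
    g = math.gcd(int(w.rate), TARGET_RATE)
    samples = resample_poly(w.samples, TARGET_RATE // g, int(w.rate) // g)
    return Waveform(samples=samples, rate=TARGET_RATE)


def _frame_signal(x: np.ndarray, rate: int,
                  frame_s: float = FRAME_LENGTH_S,
                  step_s: float = FRAME_STEP_S) -> np.ndarray:
    flen = int(round(frame_s * rate))
    step = int(round(step_s * rate))
    if len(x) < flen:
        return np.empty((0, flen))
    n_frames = 1 + (len(x) - flen) // step
    idx = (np.arange(flen)[None, :] + step * np.arange(n_frames)[:, None])
    return x[idx]


def _intensity_db(frames: np.ndarray) -> np.ndarray:
    power = np.mean(frames ** 2, axis=1)
    return 10.0 * np.log10(power + _EPS)


def _voiced_flags(x: np.ndarray, rate: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame voicing flag and F0 estimate via normalized autocorrelation.

    Uses a 40 ms analysis frame (long enough for the 75 Hz floor) with the
    standard 10 ms step.
    """
    frames = _frame_signal(x, rate, frame_s=0.040)
    n = frames.shape[0]
    f0 = np.full(n, np.nan)
    voiced = np.zeros(n, dtype=bool)
    if n == 0:
        return voiced, f0
    inten = _intensity_db(frames)
    floor_db = inten.max() - SILENCE_DB_BELOW_MAX
    lag_min = int(rate / F0_CEIL)
    lag_max = min(int(rate / F0_FLOOR), frames.shape[1] - 1)
    for i in range(n):
        if inten[i] < floor_db:
            continue
        fr = frames[i] - frames[i].mean()
        denom = np.dot(fr, fr)
        if denom < _EPS:
            continue
        ac = np.correlate(fr, fr, mode="full")[len(fr) - 1:]
        ac = ac / denom
        seg = ac[lag_min:lag_max + 1]
        if seg.size == 0:
            continue
        k = int(np.argmax(seg))
        if seg[k] >= VOICING_THRESHOLD:
            voiced[i] = True
            f0[i] = rate / (lag_min + k)
    return voiced, f0


def _speaking_intervals(inten: np.ndarray, step_s: float,
                        floor_db: float) -> list[tuple[int, int]]:
    """Sounding frame runs; gaps shorter than MIN_PAUSE_S are bridged."""
    sounding = inten >= floor_db
    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(sounding):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(sounding)))
    if not runs:
        return []
    min_gap = int(round(MIN_PAUSE_S / step_s))
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def temporal_stats(w: Waveform) -> FeatureVector:
    """Speech timing features from intensity-based syllable nuclei."""
    w = _to_target_rate(w)
    fv = FeatureVector()
    total = w.duration_s
    frames = _frame_signal(w.samples, w.rate)
    inten = _intensity_db(frames)
    if inten.size == 0 or np.ptp(inten) < 1e-6:
        # digital silence / constant signal: nothing is spoken
        fv.add("syllable_count", 0.0, "paralinguistic")
        fv.add("total_duration", total, "paralinguistic")
        fv.add("speaking_duration", 0.0, "paralinguistic")
        fv.add("speech_rate", 0.0, "paralinguistic")
        fv.add("articulation_rate", MISSING, "paralinguistic")
        fv.add("ratio_speaking", 0.0, "paralinguistic")
        fv.add("pronunciation_score", MISSING, "paralinguistic")
        return fv
    floor_db = inten.max() - SILENCE_DB_BELOW_MAX
    peaks, _ = find_peaks(inten, height=floor_db,
                          prominence=NUCLEUS_DIP_DB)
    voiced, _f0 = _voiced_flags(w.samples, w.rate)
    intervals = _speaking_intervals(inten, FRAME_STEP_S, floor_db)
    speaking = sum((b - a) for a, b in intervals) * FRAME_STEP_S
    speaking = min(speaking, total)
    n_syll = float(len(peaks))
    fv.add("syllable_count", n_syll, "paralinguistic")
    fv.add("total_duration", total, "paralinguistic")
    fv.add("speaking_duration", speaking, "paralinguistic")
    fv.add("speech_rate", n_syll / total if total else MISSING,
           "paralinguistic")
    fv.add("articulation_rate",
           n_syll / speaking if speaking > 0 else MISSING, "paralinguistic")
    fv.add("ratio_speaking", speaking / total if total else MISSING,
           "paralinguistic")
    if len(peaks) and len(voiced):
        # the F0 track uses a longer analysis frame but the same step, so
        # peak indices map onto it directly (clamped at the tail)
        in_voiced = [bool(voiced[min(p, len(voiced) - 1)]) for p in peaks]
        fv.add("pronunciation_score", 100.0 * float(np.mean(in_voiced)),
               "paralinguistic")
    else:
        fv.add("pronunciation_score", MISSING, "paralinguistic")
    return fv


def f0_stats(w: Waveform) -> FeatureVector:
    """Mean/std/min/max/quartiles of F0 over voiced frames (Hz)."""
    w = _to_target_rate(w)
    fv = FeatureVector()
    voiced, f0 = _voiced_flags(w.samples, w.rate)
    vals = f0[voiced]
    names = ("f0_mean", "f0_std", "f0_min", "f0_max", "f0_q25", "f0_q75")
    if vals.size == 0:
        for n in names:
            fv.add(n, MISSING, "paralinguistic")
        return fv
    stats = (float(vals.mean()), float(vals.std()), float(vals.min()),
             float(vals.max()), float(np.percentile(vals, 25)),
             float(np.percentile(vals, 75)))
    for n, v in zip(names, stats):
        fv.add(n, v, "paralinguistic")
    return fv


# ---------------------------------------------------------------------------
# MFCC

def _hz_to_mel(hz):
    return 2595.0 * np.log10(1.0 + np.asarray(hz) / 700.0)


def _mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int = N_MEL_FILTERS, n_fft: int = N_FFT,
                   rate: int = TARGET_RATE) -> np.ndarray:
    """Triangular mel-spaced filterbank on the rfft bin grid."""
    low, high = _hz_to_mel(0.0), _hz_to_mel(rate / 2.0)
    mel_points = np.linspace(low, high, n_filters + 2)
    hz_points = _mel_to_hz(mel_points)
    bins = np.floor((n_fft + 1) * hz_points / rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for m in range(1, n_filters + 1):
        l, c, r = bins[m - 1], bins[m], bins[m + 1]
        for k in range(l, c):
            if c > l:
                fb[m - 1, k] = (k - l) / (c - l)
        for k in range(c, r):
            if r > c:
                fb[m - 1, k] = (r - k) / (r - c)
    return fb


def mfcc_frames(w: Waveform, n_coeff: int = N_MFCC) -> np.ndarray:
    """Frame-level MFCC matrix (frames x coefficients).

    Pre-emphasized, Hamming-windowed 25 ms frames at a 10 ms step; 26
    triangular mel filters over a 512-point rfft power spectrum; log filter
    energies; orthonormal DCT-II, first *n_coeff* coefficients kept.
    """
    w = _to_target_rate(w)
    x = np.append(w.samples[0], w.samples[1:] - PREEMPHASIS * w.samples[:-1])
    frames = _frame_signal(x, w.rate)
    if frames.shape[0] == 0:
        return np.empty((0, n_coeff))
    frames = frames * np.hamming(frames.shape[1])
    spec = np.abs(rfft(frames, n=N_FFT, axis=1)) ** 2 / N_FFT
    fb = mel_filterbank(rate=w.rate)
    energies = spec @ fb.T
    energies = np.log(energies + _EPS)
    ceps = dct(energies, type=2, axis=1, norm="ortho")[:, :n_coeff]
    return ceps


def _moment_stats(series: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(series.mean())
    var = float(series.var())
    if var < _EPS:
        return mean, var, 0.0, 0.0  # degenerate series: no shape
    return (mean, var, float(_skew(series)),
            float(_kurtosis(series, fisher=True)))


def mfcc_stats(w: Waveform) -> FeatureVector:
    """Summary statistics of MFCCs and their differences (168 features).

    Coefficient 0 is named ``energy``; velocity/acceleration are first and
    second frame-to-frame differences.  Zero-variance series report
    skewness and kurtosis of 0 rather than NaN.
    """
    fv = FeatureVector()
    ceps = mfcc_frames(w)
    names = ["energy"] + [f"mfcc{i}" for i in range(1, N_MFCC)]
    kinds = ("", "velocity_", "acceleration_")
    stats = ("mean", "variance", "skewness", "kurtosis")
    if ceps.shape[0] < 3:
        for name in names:
            for kind in kinds:
                for st in stats:
                    fv.add(f"{name}_{kind}{st}", MISSING, "paralinguistic")
        return fv
    vel = np.diff(ceps, axis=0)
    acc = np.diff(vel, axis=0)
    for mat, kind in zip((ceps, vel, acc), kinds):
        for j, name in enumerate(names):
            vals = _moment_stats(mat[:, j])
            for st, v in zip(stats, vals):
                fv.add(f"{name}_{kind}{st}", v, "paralinguistic")
    return fv


# ---------------------------------------------------------------------------
# Spectral descriptors

def spectral_stats(w: Waveform) -> FeatureVector:
    """Summary statistics of 7 frame-level spectral descriptors (28)."""
    w = _to_target_rate(w)
    fv = FeatureVector()
    frames = _frame_signal(w.samples, w.rate)
    descriptors: dict[str, np.ndarray] = {}
    if frames.shape[0] == 0:
        for name in ("rms", "centroid", "bandwidth", "flatness", "zcr",
                     "loudness", "flux"):
            for st in ("mean", "max", "min", "std"):
                fv.add(f"{name}_{st}", MISSING, "paralinguistic")
        return fv
    win = np.hanning(frames.shape[1])
    spec = np.abs(rfft(frames * win, n=N_FFT, axis=1))
    freqs = np.arange(spec.shape[1]) * w.rate / N_FFT
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    mag_sum = spec.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (spec * freqs).sum(axis=1) / mag_sum
        bandwidth = np.sqrt(
            (spec * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1)
            / mag_sum)
        power = spec ** 2
        flatness = (np.exp(np.mean(np.log(power + _EPS), axis=1))
                    / (np.mean(power, axis=1) + _EPS))
    # silent frames have no spectral location
    centroid[mag_sum < _EPS] = np.nan
    bandwidth[mag_sum < _EPS] = np.nan
    # crossings per second: indicator over the whole signal, then framed,
    # so frame boundaries lose no crossings
    signs = np.sign(w.samples)
    signs[signs == 0] = 1
    cross = np.abs(np.diff(signs)) / 2.0
    flen = frames.shape[1]
    cframes = _frame_signal(np.append(cross, 0.0), w.rate)[:frames.shape[0]]
    zcr = cframes.sum(axis=1) * w.rate / flen
    loudness = 20.0 * np.log10(rms + _EPS)
    norm = spec / (mag_sum[:, None] + _EPS)
    flux = np.r_[np.nan, np.sqrt(((np.diff(norm, axis=0)) ** 2).sum(axis=1))]
    descriptors = {"rms": rms, "centroid": centroid, "bandwidth": bandwidth,
                   "flatness": flatness, "zcr": zcr, "loudness": loudness,
                   "flux": flux}
    for name, series in descriptors.items():
        vals = series[~np.isnan(series)]
        if vals.size == 0:
            for st in ("mean", "max", "min", "std"):
                fv.add(f"{name}_{st}", MISSING, "paralinguistic")
            continue
        fv.add(f"{name}_mean", float(vals.mean()), "paralinguistic")
        fv.add(f"{name}_max", float(vals.max()), "paralinguistic")
        fv.add(f"{name}_min", float(vals.min()), "paralinguistic")
        fv.add(f"{name}_std", float(vals.std()), "paralinguistic")
    return fv


def extract_audio_features(w: Waveform, subject_id: str = "") -> FeatureVector:
    """All 209 paralinguistic features for one waveform."""
    fv = FeatureVector(subject_id=subject_id)
    fv.merge(temporal_stats(w))
    fv.merge(f0_stats(w))
    fv.merge(mfcc_stats(w))
    fv.merge(spectral_stats(w))
    return fv


def _paralinguistic_names() -> list[str]:
    names = ["syllable_count", "total_duration", "speaking_duration",
             "speech_rate", "articulation_rate", "ratio_speaking",
             "pronunciation_score",
             "f0_mean", "f0_std", "f0_min", "f0_max", "f0_q25", "f0_q75"]
    coef = ["energy"] + [f"mfcc{i}" for i in range(1, N_MFCC)]
    for kind in ("", "velocity_", "acceleration_"):
        for name in coef:
            for st in ("mean", "variance", "skewness", "kurtosis"):
                names.append(f"{name}_{kind}{st}")
    for name in ("rms", "centroid", "bandwidth", "flatness", "zcr",
                 "loudness", "flux"):
        for st in ("mean", "max", "min", "std"):
            names.append(f"{name}_{st}")
    return names


#: the full paralinguistic registry, in extraction order (209 names)
PARALINGUISTIC_FEATURES: tuple[str, ...] = tuple(_paralinguistic_names())
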