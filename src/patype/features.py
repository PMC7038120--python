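"""Per-segment accelerometer features: 61 time-domain + 24 frequency-domain.

Signals are the three device axes (x, y, z) and the total acceleration
(Euclidean norm).  The vector always has exactly 85 entries in a fixed
order; the general design concatenates all five positions (425 columns),
and the two GPS features (mean speed, elevation difference) may be appended
once, giving 87 per-position or 427 general columns.

Time domain (61):
    mean/sd/range of x,y,z,tot (12); Pearson correlation of (x,y),(x,z),
    (y,z) (3); kurtosis of x,y,z (3); skewness of x,y,z (3); average
    absolute difference from the mean of x,y,z,tot (4); counts in 10 fixed
    bins for x,y,z (30); mean inter-peak interval of x,y,z (3); peak count
    of x,y,z (3).

Frequency domain (24), per signal in {x,y,z,tot} on the demeaned series:
    mean periodogram over non-DC bins; spectral energy sum|X_k|^2 / N over
    non-DC bins (= N * variance by Parseval); mean frequency of the three
    largest-magnitude non-DC bins; and those three amplitudes (2|X_k|/N) in
    descending order.  Ties in magnitude resolve to the lower frequency.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import ACCEL_RATE, Segment

#: Fixed histogram range (g): global, so bin features compare across segments.
BIN_RANGE_G = (-3.0, 3.0)
N_BINS = 10
#: Peak definition: local maxima above mean + 0.5 sd, >= 0.2 s apart.
PEAK_SD_FACTOR = 0.5
PEAK_MIN_SEPARATION_S = 0.2

_AXES = ("x", "y", "z")
_SIGNALS = ("x", "y", "z", "tot")
_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))


def _build_names() -> list:
    names = []
    for stat in ("mean", "sd", "range"):
        names += [f"time_{stat}_{s}" for s in _SIGNALS]
    names += [f"time_corr_{a}{b}" for a, b in _PAIRS]
    names += [f"time_kurtosis_{a}" for a in _AXES]
    names += [f"time_skewness_{a}" for a in _AXES]
    names += [f"time_aad_{s}" for s in _SIGNALS]
    for a in _AXES:
        names += [f"time_bin{i}_{a}" for i in range(N_BINS)]
    names += [f"time_peakgap_{a}" for a in _AXES]
    names += [f"time_npeaks_{a}" for a in _AXES]
    for s in _SIGNALS:
        names += [
            f"freq_psd_{s}",
            f"freq_energy_{s}",
            f"freq_domfreq_mean_{s}",
            f"freq_domamp1_{s}",
            f"freq_domamp2_{s}",
            f"freq_domamp3_{s}",
        ]
    return names


#: Canonical feature order; length 85.
FEATURE_NAMES = tuple(_build_names())
N_TIME_FEATURES = 61
N_FREQ_FEATURES = 24
N_FEATURES = 85

GPS_FEATURE_NAMES = ("gps_mean_speed", "gps_elev_diff")


@dataclass
class FeatureVector:
    """An ordered 85-entry feature map plus segment metadata."""

    values: dict
    subject_id: str = ""
    position: str = ""
    t_start: float = 0.0
    t_end: float = 0.0
    label: str = ""

    def array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def _signals(arr: np.ndarray) -> dict:
    tot = np.sqrt((arr * arr).sum(axis=1))
    return {"x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2], "tot": tot}


def time_features(segment: Segment | np.ndarray) -> dict:
    """The 61 time-domain features of a segment (>= 2 samples required)."""
    arr = segment.array() if isinstance(segment, Segment) else np.asarray(segment, float)
    if arr.shape[0] < 2:
        raise ValueError("time features need at least 2 samples")
    sig = _signals(arr)
    out = {}
    means = {s: float(sig[s].mean()) for s in _SIGNALS}
    centered = {s: sig[s] - means[s] for s in _SIGNALS}
    sds = {s: float(np.sqrt((centered[s] ** 2).mean())) for s in _SIGNALS}
    for s in _SIGNALS:
        out[f"time_mean_{s}"] = means[s]
    for s in _SIGNALS:
        out[f"time_sd_{s}"] = sds[s]
    for s in _SIGNALS:
        out[f"time_range_{s}"] = float(sig[s].max() - sig[s].min())
    for a, b in _PAIRS:
        if sds[a] == 0.0 or sds[b] == 0.0:
            out[f"time_corr_{a}{b}"] = 0.0  # degenerate axis: flagged as 0
        else:
            out[f"time_corr_{a}{b}"] = float((centered[a] * centered[b]).mean() / (sds[a] * sds[b]))
    for a in _AXES:
        # Fisher kurtosis and biased skewness from central moments
        if sds[a] > 0:
            m2 = sds[a] ** 2
            out[f"time_kurtosis_{a}"] = float((centered[a] ** 4).mean() / m2**2 - 3.0)
            out[f"time_skewness_{a}"] = float((centered[a] ** 3).mean() / m2**1.5)
        else:
            out[f"time_kurtosis_{a}"] = 0.0
            out[f"time_skewness_{a}"] = 0.0
    for s in _SIGNALS:
        out[f"time_aad_{s}"] = float(np.abs(centered[s]).mean())
    for a in _AXES:
        clipped = np.clip(sig[a], BIN_RANGE_G[0], BIN_RANGE_G[1])
        counts, _ = np.histogram(clipped, bins=N_BINS, range=BIN_RANGE_G)
        for i in range(N_BINS):
            out[f"time_bin{i}_{a}"] = float(counts[i])
    distance = max(1, int(round(PEAK_MIN_SEPARATION_S * ACCEL_RATE)))
    for a in _AXES:
        height = sig[a].mean() + PEAK_SD_FACTOR * sds[a]
        peaks, _ = find_peaks(sig[a], height=height, distance=distance)
        out[f"time_npeaks_{a}"] = float(len(peaks))
        out[f"time_peakgap_{a}"] = float(np.diff(peaks).mean() / ACCEL_RATE) if len(peaks) >= 2 else 0.0
    return out


def dominant_frequencies(x: np.ndarray, sampling_rate: float = ACCEL_RATE, k: int = 3):
    """Frequencies and amplitudes (2|X|/N) of the k largest-magnitude
    non-DC bins of the demeaned signal, by descending magnitude; magnitude
    ties resolve to the lower frequency."""
    x = np.asarray(x, float)
    n = len(x)
    spectrum = np.fft.rfft(x - x.mean())
    k_max = n // 2
    mags = np.abs(spectrum[1 : k_max + 1])
    freqs = np.arange(1, k_max + 1) * sampling_rate / n
    order = np.argsort(-mags, kind="stable")[:k]
    amps = 2.0 * mags[order] / n
    top = freqs[order]
    if len(order) < k:
        amps = np.pad(amps, (0, k - len(order)))
        top = np.pad(top, (0, k - len(order)))
    return top, amps


def freq_features(segment: Segment | np.ndarray, sampling_rate: float = ACCEL_RATE) -> dict:
    """The 24 frequency-domain features (segment length >= 4 required)."""
    arr = segment.array() if isinstance(segment, Segment) else np.asarray(segment, float)
    n = arr.shape[0]
    if n < 4:
        raise ValueError("frequency features need at least 4 samples")
    sig = _signals(arr)
    out = {}
    for s in _SIGNALS:
        x = sig[s] - sig[s].mean()
        spectrum = np.fft.rfft(x)
        power = np.abs(spectrum) ** 2
        k_max = n // 2  # positive-frequency bins 1..n//2
        # Parseval: sum over all non-DC bins of |X|^2 / N == sum (x - mean)^2
        nonpos = power[1:].sum() - (0.5 * power[k_max] if n % 2 == 0 else 0.0)
        out[f"freq_energy_{s}"] = float(2.0 * nonpos / n)
        # one-sided periodogram (boxcar, mean removed): 2|X_k|^2 / (fs n),
        # Nyquist bin not doubled; summarized as its mean over non-DC bins
        pxx = 2.0 * power[1:] / (sampling_rate * n)
        if n % 2 == 0:
            pxx[-1] *= 0.5
        out[f"freq_psd_{s}"] = float(pxx.mean())
        mags = np.abs(spectrum[1 : k_max + 1])
        freqs = np.arange(1, k_max + 1) * sampling_rate / n
        order = np.argsort(-mags, kind="stable")[:3]  # tie -> lower frequency
        amps = 2.0 * mags[order] / n
        top_freqs = freqs[order]
        if len(order) < 3:  # pad and flag degenerate short spectra
            amps = np.pad(amps, (0, 3 - len(order)))
            top_freqs = np.pad(top_freqs, (0, 3 - len(order)))
        if np.allclose(mags, 0.0):
            out[f"freq_domfreq_mean_{s}"] = 0.0
            amps = np.zeros(3)
        else:
            out[f"freq_domfreq_mean_{s}"] = float(top_freqs.mean())
        out[f"freq_domamp1_{s}"] = float(amps[0])
        out[f"freq_domamp2_{s}"] = float(amps[1])
        out[f"freq_domamp3_{s}"] = float(amps[2])
    return out


def extract(segment: Segment, sampling_rate: float = ACCEL_RATE) -> FeatureVector:
    """Full 85-feature vector for one segment, in canonical order."""
    arr = segment.array() if isinstance(segment, Segment) else np.asarray(segment, float)
    values = time_features(arr)
    values.update(freq_features(arr, sampling_rate))
    ordered = {name: values[name] for name in FEATURE_NAMES}
    meta = {}
    if isinstance(segment, Segment):
        meta = dict(
            subject_id=segment.subject_id,
            position=segment.position,
            t_start=segment.t_start,
            t_end=segment.t_end,
            label=segment.label,
        )
    return FeatureVector(values=ordered, **meta)
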