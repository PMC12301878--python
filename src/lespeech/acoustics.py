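"""Acoustic voice features for dysarthria tracking.

Eleven features per recording: mean/SD of pitch, mean/SD of formants F1 and
F2, SD of the sound envelope, harmonics-to-noise ratio (HNR), local jitter,
local shimmer and cepstral peak prominence (CPP). Together with speaking
rate and transcriber confidence they form the 13-dimensional input of the
listener-effort prediction model.

Analysis conventions
--------------------
Pitch, HNR and CPP use 40 ms frames with a 10 ms hop (at least two glottal
periods at the 75 Hz pitch floor); the envelope uses 25 ms RMS frames.
Pitch is the peak of the frame-wise normalized autocorrelation within the
candidate lag band, with parabolic lag interpolation; a frame is voiced when
that peak reaches the voicing threshold (default 0.45). Formants come from
linear-prediction root-solving on audio resampled to 10 kHz with 0.97
pre-emphasis. All features are gain-invariant by construction. Missing
values are returned as NaN, never raised, at the `extract_features` level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .rates import Transcript, speaking_rate

__all__ = [
    "Waveform",
    "AcousticConfig",
    "F0Track",
    "AcousticFeatures",
    "FeatureVector",
    "FEATURE_NAMES",
    "f0_track",
    "pitch_stats",
    "formant_stats",
    "envelope_sd",
    "hnr",
    "jitter_local",
    "shimmer_local",
    "measure_cycles",
    "cpp",
    "extract_features",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] at a fixed sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate_hz < 8000:
            raise ValueError("sample rate below 8 kHz is unsupported")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class AcousticConfig:
    """Frame sizes, pitch band and analysis constants."""

    fmin_hz: float = 75.0
    fmax_hz: float = 500.0
    frame_s: float = 0.040
    hop_s: float = 0.010
    voicing_threshold: float = 0.45
    env_frame_s: float = 0.025
    env_hop_s: float = 0.010
    formant_rate_hz: int = 10000
    formant_bw_cap_hz: float = 400.0
    preemphasis: float = 0.97
    hnr_floor_db: float = -20.0
    hnr_ceil_db: float = 40.0


@dataclass
class F0Track:
    """Frame-wise pitch: NaN where unvoiced; `corr` is the autocorrelation peak."""

    times_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    corr: np.ndarray

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced]


def _frame(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    if len(x) < flen:
        return np.empty((0, flen))
    n = 1 + (len(x) - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _norm_autocorr(frames: np.ndarray) -> np.ndarray:
    """Per-frame normalized, lag-unbiased autocorrelation (lag axis = frame length)."""
    flen = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = 1 << int(math.ceil(math.log2(2 * flen)))
    spec = np.fft.rfft(frames, n=nfft)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft)[:, :flen]
    r0 = ac[:, :1].copy()
    r0[r0 <= 0] = np.inf
    lags = np.arange(flen)
    unbias = 1.0 - lags / flen
    return ac / r0 / unbias[None, :]


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete peak at index i; returns (offset in [-0.5, 0.5], value)."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0, float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, float(b - 0.25 * (a - c) * d)


def f0_track(w: Waveform, config: AcousticConfig | None = None) -> F0Track:
    """Autocorrelation pitch track with voiced/unvoiced decisions."""
    cfg = config or AcousticConfig()
    fs = w.sample_rate_hz
    if not (0 < cfg.fmin_hz < cfg.fmax_hz < fs / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    flen = int(round(cfg.frame_s * fs))
    hop = int(round(cfg.hop_s * fs))
    frames = _frame(w.samples, flen, hop)
    n = len(frames)
    times = (np.arange(n) * hop + flen / 2) / fs
    f0 = np.full(n, np.nan)
    corr = np.zeros(n)
    if n == 0:
        return F0Track(times, f0, np.zeros(0, dtype=bool), corr)
    r = _norm_autocorr(frames)
    lag_lo = max(2, int(math.floor(fs / cfg.fmax_hz)))
    lag_hi = min(flen - 2, int(math.ceil(fs / cfg.fmin_hz)))
    rms = np.sqrt(np.mean(frames**2, axis=1))
    silent = rms < 1e-6
    for i in range(n):
        if silent[i]:
            continue
        band = r[i, lag_lo : lag_hi + 1]
        vmax = band.max()
        # prefer the shortest-lag peak close to the global one: the peak at
        # twice the true period is equally strong, and picking it would halve F0
        maxima = np.nonzero(
            (band >= np.roll(band, 1)) & (band >= np.roll(band, -1)) & (band >= 0.9 * vmax)
        )[0]
        maxima = maxima[(maxima > 0) & (maxima < len(band) - 1)]
        j = (int(maxima[0]) if len(maxima) else int(np.argmax(band))) + lag_lo
        off, val = _parabolic(r[i], j)
        corr[i] = val
        if val >= cfg.voicing_threshold:
            f0[i] = fs / (j + off)
    voiced = ~np.isnan(f0)
    return F0Track(times, f0, voiced, corr)


def pitch_stats(track: F0Track) -> tuple[float, float]:
    """(mean, population SD) of F0 over voiced frames; NaN when all unvoiced."""
    v = track.voiced_f0
    if len(v) == 0:
        return math.nan, math.nan
    return float(np.mean(v)), float(np.std(v))


def hnr(w: Waveform, config: AcousticConfig | None = None) -> float:
    """Mean harmonics-to-noise ratio (dB) over voiced frames.

    Per voiced frame, r = normalized autocorrelation at the pitch lag and
    HNR = 10*log10(r / (1 - r)), clamped to [-20, 40] dB. NaN when no frame
    is voiced.
    """
    cfg = config or AcousticConfig()
    track = f0_track(w, cfg)
    if not track.voiced.any():
        return math.nan
    r = np.clip(track.corr[track.voiced], 1e-6, 1.0 - 1e-6)
    frame_db = 10.0 * np.log10(r / (1.0 - r))
    frame_db = np.clip(frame_db, cfg.hnr_floor_db, cfg.hnr_ceil_db)
    return float(np.mean(frame_db))


def formant_stats(
    w: Waveform, config: AcousticConfig | None = None
) -> tuple[float, float, float, float]:
    """(F1 mean, F1 SD, F2 mean, F2 SD) in Hz from LP analysis of voiced frames.

    Audio is resampled to ~10 kHz and pre-emphasized; per frame the first two
    LP roots with bandwidth under the cap, sorted by frequency, are F1 and
    F2. Returns NaNs when no frame yields two valid formants.
    """
    cfg = config or AcousticConfig()
    fs_t = cfg.formant_rate_hz
    fs = w.sample_rate_hz
    if fs != fs_t:
        g = math.gcd(fs_t, fs)
        x = sps.resample_poly(w.samples, fs_t // g, fs // g)
    else:
        x = w.samples.copy()
    x = np.append(x[0], x[1:] - cfg.preemphasis * x[:-1])
    track = f0_track(w, cfg)
    flen = int(round(0.025 * fs_t))
    hop = int(round(cfg.hop_s * fs_t))
    frames = _frame(x, flen, hop) * np.hamming(flen)
    order = 2 + round(fs_t / 1000)
    f1s, f2s = [], []
    n = min(len(frames), len(track.voiced))
    for i in range(n):
        if not track.voiced[i]:
            continue
        fr = frames[i]
        ac = np.correlate(fr, fr, "full")[flen - 1 : flen - 1 + order + 1]
        if ac[0] <= 0:
            continue
        try:
            a = solve_toeplitz(ac[:order], ac[1 : order + 1])
        except np.linalg.LinAlgError:
            continue
        roots = np.roots(np.concatenate(([1.0], -a)))
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs_t / (2 * np.pi)
        bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs_t / np.pi
        ok = (freqs > 90) & (freqs < fs_t / 2 - 50) & (bws < cfg.formant_bw_cap_hz)
        cand = np.sort(freqs[ok])
        if len(cand) >= 2:
            f1s.append(cand[0])
            f2s.append(cand[1])
    if not f1s:
        return (math.nan,) * 4
    f1s, f2s = np.asarray(f1s), np.asarray(f2s)
    return (
        float(f1s.mean()),
        float(f1s.std()),
        float(f2s.mean()),
        float(f2s.std()),
    )


def envelope_sd(w: Waveform, config: AcousticConfig | None = None) -> float:
    """Coefficient of variation of frame RMS energy (gain-invariant); NaN on silence."""
    cfg = config or AcousticConfig()
    fs = w.sample_rate_hz
    frames = _frame(w.samples, int(round(cfg.env_frame_s * fs)), int(round(cfg.env_hop_s * fs)))
    if len(frames) == 0:
        return math.nan
    rms = np.sqrt(np.mean(frames**2, axis=1))
    m = rms.mean()
    if m <= 1e-9:
        return math.nan
    return float(rms.std() / m)


def jitter_local(periods_s: np.ndarray | list[float]) -> float:
    """Local jitter: mean absolute successive period difference / mean period."""
    p = np.asarray(periods_s, dtype=float)
    if len(p) < 2:
        return math.nan
    return float(np.mean(np.abs(np.diff(p))) / np.mean(p))


def shimmer_local(amplitudes: np.ndarray | list[float]) -> float:
    """Local shimmer: mean absolute successive amplitude difference / mean amplitude."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 2:
        return math.nan
    return float(np.mean(np.abs(np.diff(a))) / np.mean(a))


def measure_cycles(
    w: Waveform, config: AcousticConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pitch-guided glottal cycle extraction: (periods_s, cycle peak amplitudes).

    Finds the strongest excursion of |x|, then walks outward one expected
    period at a time, picking the local |x| maximum in a +/-30% window and
    refining its position sub-sample by parabolic interpolation.
    """
    cfg = config or AcousticConfig()
    fs = w.sample_rate_hz
    x = np.abs(w.samples)
    track = f0_track(w, cfg)
    v = track.voiced_f0
    if len(v) == 0:
        return np.empty(0), np.empty(0)
    period = fs / float(np.median(v))
    lo, hi = int(0.70 * period), int(math.ceil(1.30 * period))
    # skip the filter onset transient and the clipped final cycle
    left_edge = int(0.1 * fs) if len(x) > int(0.5 * fs) else 0
    right_edge = len(x) - 1 - int(0.03 * fs) if len(x) > int(0.5 * fs) else len(x) - 1
    start = int(np.argmax(x[left_edge : right_edge + 1])) + left_edge
    floor_amp = 0.05 * x[start]
    peaks = [float(start + _parabolic(x, start)[0])]
    amps = [_parabolic(x, start)[1]]
    for direction in (1, -1):
        p = start
        while True:
            a = p + direction * hi if direction < 0 else p + direction * lo
            b = p + direction * lo if direction < 0 else p + direction * hi
            a, b = max(left_edge, a), min(right_edge, b)
            if b - a < 2:
                break
            j = int(np.argmax(x[a : b + 1])) + a
            if j in (a, b) or x[j] < floor_amp:
                break  # boundary hit: not a true cycle peak
            off, amp = _parabolic(x, j)
            peaks.append(j + off)
            amps.append(amp)
            p = j
    order = np.argsort(peaks)
    pk = np.asarray(peaks)[order]
    am = np.asarray(amps)[order]
    periods = np.diff(pk) / fs
    med = np.median(periods) if len(periods) else 0.0
    keep = (periods > 0.75 * med) & (periods < 1.25 * med)
    return periods[keep], am[1:][keep]


def cpp(w: Waveform, config: AcousticConfig | None = None) -> float:
    """Cepstral peak prominence in dB, averaged over analysis frames.

    Per frame: Hamming-windowed log-magnitude spectrum (dB) -> real cepstrum;
    the peak is searched in the quefrency band [1/fmax, 1/fmin]; prominence
    is the peak height above the linear regression of cepstrum on quefrency
    (fitted from 1 ms up to the maximum quefrency) evaluated at the peak.
    NaN on silence.
    """
    cfg = config or AcousticConfig()
    fs = w.sample_rate_hz
    flen = int(round(cfg.frame_s * fs))
    if flen < 2 * fs / cfg.fmin_hz:
        raise ValueError("analysis frame shorter than two periods at fmin")
    hop = int(round(cfg.hop_s * fs))
    frames = _frame(w.samples, flen, hop)
    if len(frames) == 0:
        return math.nan
    rms = np.sqrt(np.mean(frames**2, axis=1))
    frames = frames[rms > 1e-6]
    if len(frames) == 0:
        return math.nan
    win = np.hamming(flen)
    nfft = 1 << int(math.ceil(math.log2(flen)))
    spec = np.abs(np.fft.rfft(frames * win, n=nfft))
    logspec = 20.0 * np.log10(spec + 1e-12)
    ceps = np.fft.irfft(logspec, n=nfft)[:, : nfft // 2]
    q = np.arange(nfft // 2) / fs
    lo = int(math.ceil(fs / cfg.fmax_hz))
    hi = min(nfft // 2 - 1, int(math.floor(fs / cfg.fmin_hz)))
    fit_lo = int(round(0.001 * fs))
    proms = []
    for c in ceps:
        j = int(np.argmax(c[lo : hi + 1])) + lo
        slope, intercept = np.polyfit(q[fit_lo:], c[fit_lo:], 1)
        proms.append(c[j] - (slope * q[j] + intercept))
    return float(np.mean(proms))


FEATURE_NAMES = [
    "pitch_mean_hz",
    "pitch_sd_hz",
    "f1_mean_hz",
    "f1_sd_hz",
    "f2_mean_hz",
    "f2_sd_hz",
    "envelope_sd",
    "hnr_db",
    "jitter_local",
    "shimmer_local",
    "cpp_db",
    "speaking_rate_wpm",
    "asr_confidence",
]


@dataclass
class AcousticFeatures:
    pitch_mean_hz: float = math.nan
    pitch_sd_hz: float = math.nan
    f1_mean_hz: float = math.nan
    f1_sd_hz: float = math.nan
    f2_mean_hz: float = math.nan
    f2_sd_hz: float = math.nan
    envelope_sd: float = math.nan
    hnr_db: float = math.nan
    jitter_local: float = math.nan
    shimmer_local: float = math.nan
    cpp_db: float = math.nan


@dataclass
class FeatureVector(AcousticFeatures):
    """The 13 model inputs for one recording: 11 acoustic + rate + confidence."""

    speaking_rate_wpm: float = math.nan
    asr_confidence: float = math.nan
    recording_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(
    w: Waveform | None,
    t: Transcript | None = None,
    config: AcousticConfig | None = None,
) -> FeatureVector:
    """All 13 features for one recording; unavailable values come back NaN."""
    cfg = config or AcousticConfig()
    fv = FeatureVector(recording_id=t.recording_id if t else "")
    if w is not None:
        track = f0_track(w, cfg)
        fv.pitch_mean_hz, fv.pitch_sd_hz = pitch_stats(track)
        fv.f1_mean_hz, fv.f1_sd_hz, fv.f2_mean_hz, fv.f2_sd_hz = formant_stats(w, cfg)
        fv.envelope_sd = envelope_sd(w, cfg)
        fv.hnr_db = hnr(w, cfg)
        periods, amps = measure_cycles(w, cfg)
        fv.jitter_local = jitter_local(periods)
        fv.shimmer_local = shimmer_local(amps)
        try:
            fv.cpp_db = cpp(w, cfg)
        except ValueError:
            fv.cpp_db = math.nan
    if t is not None:
        try:
            fv.speaking_rate_wpm = speaking_rate(t)
        except ValueError:
            fv.speaking_rate_wpm = math.nan
        fv.asr_confidence = t.asr_confidence
    return fv
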