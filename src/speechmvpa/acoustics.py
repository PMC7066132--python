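"""Acoustic measures of recorded utterances.

Four measures per token: the speech envelope (zero-phase 150 Hz high-pass,
Hilbert analytic magnitude, zero-phase 8 Hz low-pass), loudness (mean
absolute signal in a 100 ms window centred at the envelope peak), a
short-time Fourier spectrogram (100-sample segments, 90% overlap, 128
frequency bins), and the first two formants from linear-prediction
polynomial roots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.linalg import solve_toeplitz

__all__ = [
    "AudioFeatures",
    "compute_envelope",
    "compute_loudness",
    "compute_spectrogram",
    "estimate_formants",
    "extract_audio_features",
]

_HP_CUT_HZ = 150.0
_LP_CUT_HZ = 8.0
_FILTER_ORDER = 4          # per pass; filtfilt doubles the effective order
_LOUDNESS_WIN_S = 0.1
_SPEC_SEGMENT = 100
_SPEC_HOP = 10             # 90% overlap of 100-sample segments
_SPEC_NFREQ = 128          # one-sided bins -> nfft = 2*(128-1)


@dataclass
class AudioFeatures:
    envelope: np.ndarray
    loudness: float
    spectrogram: np.ndarray      # (freq, time) magnitudes
    f1_hz: float | None
    f2_hz: float | None


def compute_envelope(waveform: np.ndarray, fs_hz: float) -> np.ndarray:
    """Speech envelope via the Hilbert transform.

    Pipeline (both filters Butterworth order 4, zero-phase forward-backward):
    high-pass at 150 Hz, analytic-signal magnitude, low-pass at 8 Hz.
    Output length equals input length; values are >= 0 up to filter ringing,
    clipped at 0.
    """
    x = np.asarray(waveform, dtype=float)
    if fs_hz <= 2 * _HP_CUT_HZ:
        raise ValueError("sampling rate too low for the 150 Hz high-pass")
    sos_hp = _sig.butter(_FILTER_ORDER, _HP_CUT_HZ, btype="high", fs=fs_hz, output="sos")
    x = _sig.sosfiltfilt(sos_hp, x)
    env = np.abs(_sig.hilbert(x))
    sos_lp = _sig.butter(_FILTER_ORDER, _LP_CUT_HZ, btype="low", fs=fs_hz, output="sos")
    env = _sig.sosfiltfilt(sos_lp, env)
    return np.clip(env, 0.0, None)


def compute_loudness(waveform: np.ndarray, envelope: np.ndarray, fs_hz: float) -> float:
    """Mean |signal| over the 100 ms window centred at the envelope peak.

    Ties at the maximum resolve to the earliest sample; the window is
    truncated at the signal edges.
    """
    x = np.asarray(waveform, dtype=float)
    env = np.asarray(envelope, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.shape != env.shape:
        raise ValueError("waveform and envelope must align")
    peak = int(np.argmax(env))
    half = int(round(_LOUDNESS_WIN_S * fs_hz / 2))
    lo = max(0, peak - half)
    hi = min(x.size, peak + half)
    return float(np.mean(np.abs(x[lo:hi])))


def compute_spectrogram(waveform: np.ndarray) -> np.ndarray:
    """Short-time Fourier magnitude, (128 freq bins) x frames.

    Periodic Hann window of 100 samples, hop 10 (90% overlap); an n-sample
    input yields ``floor((n-100)/10)+1`` frames.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size < _SPEC_SEGMENT:
        raise ValueError(f"input shorter than one {_SPEC_SEGMENT}-sample segment")
    win = _sig.get_window("hann", _SPEC_SEGMENT, fftbins=True)
    nfft = 2 * (_SPEC_NFREQ - 1)
    _, _, Z = _sig.stft(
        x,
        window=win,
        nperseg=_SPEC_SEGMENT,
        noverlap=_SPEC_SEGMENT - _SPEC_HOP,
        nfft=nfft,
        boundary=None,
        padded=False,
    )
    return np.abs(Z)


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear prediction coefficients [1, a1..ap]."""
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    if r[0] <= 0:
        raise np.linalg.LinAlgError("zero-energy segment")
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate([[1.0], a])


def estimate_formants(
    waveform: np.ndarray,
    fs_hz: float,
    order: int | None = None,
    min_hz: float = 90.0,
    max_bandwidth_hz: float = 400.0,
) -> tuple[float | None, float | None]:
    """F1/F2 from linear-prediction polynomial roots.

    Model order defaults to ``2 + round(fs/1000)``.  Roots with positive
    imaginary part are converted to frequencies, filtered to the open
    interval (``min_hz``, Nyquist) with bandwidth below
    ``max_bandwidth_hz``, sorted ascending; the first two are returned.
    Degenerate inputs yield ``(None, None)`` rather than silent nonsense.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size < int(0.03 * fs_hz):
        raise ValueError("need a steady segment of >= 30 ms")
    if order is None:
        order = 2 + int(round(fs_hz / 1000.0))
    x = x * np.hamming(x.size)
    try:
        a = _lpc(x, order)
    except np.linalg.LinAlgError:
        return None, None
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * fs_hz / (2 * np.pi)
    bw = -np.log(np.clip(np.abs(roots), 1e-12, None)) * fs_hz / np.pi
    ok = (freqs > min_hz) & (freqs < fs_hz / 2 - 50.0) & (bw < max_bandwidth_hz)
    freqs = np.sort(freqs[ok])
    if freqs.size < 2:
        return (float(freqs[0]) if freqs.size else None), None
    return float(freqs[0]), float(freqs[1])


def extract_audio_features(waveform: np.ndarray, fs_hz: float) -> AudioFeatures:
    """All four acoustic measures for one utterance."""
    env = compute_envelope(waveform, fs_hz)
    loud = compute_loudness(waveform, env, fs_hz)
    spec = compute_spectrogram(waveform)
    f1, f2 = estimate_formants(waveform, fs_hz)
    return AudioFeatures(env, loud, spec, f1, f2)
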