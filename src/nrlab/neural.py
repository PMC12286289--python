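"""Neural SNR: a single-number cortical index of speech-vs-noise encoding.

The index compares the evoked response to the target-word onset with the
evoked response to the preceding noise onset, on the 2–7 Hz temporal envelope
of the NR-off ERP rather than on any single component peak:

``neural_snr_db = 20 * log10(peak_word / peak_noise)``

where the peaks are envelope maxima in fixed windows — 50–250 ms after noise
onset and 100–400 ms after word onset. The 20·log10 convention is used
because envelope *amplitudes* (µV), not powers, are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .eeg import ERP, design_fir_bandpass, filtfilt_fir
from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "NOISE_WINDOW",
    "WORD_WINDOW_REL",
    "NeuralSNRResult",
    "erp_envelope",
    "window_peak",
    "compute_neural_snr",
]

NOISE_WINDOW = (0.05, 0.25)       # s after noise onset
WORD_WINDOW_REL = (0.10, 0.40)    # s after word onset


@dataclass(frozen=True)
class NeuralSNRResult:
    peak_noise: float
    peak_word: float
    neural_snr_db: float
    noise_window: tuple[float, float]
    word_window: tuple[float, float]


def erp_envelope(erp: ERP, band: tuple[float, float] = (2.0, 7.0)) -> np.ndarray:
    """2–7 Hz zero-phase bandpass, Hilbert transform, magnitude over time."""
    lo, hi = band
    if hi >= erp.fs / 2:
        raise InvalidArgumentError("band above the Nyquist frequency")
    if erp.fs < 4 * hi:
        raise InvalidArgumentError("sampling rate too low for this band")
    # a ~1.5 s filter: long enough for a clean 2-7 Hz passband, short enough
    # that time-domain ringing of one response cannot reach the other window
    taps = design_fir_bandpass(lo, hi, erp.fs, numtaps=int(1.5 * erp.fs) | 1)
    filtered = filtfilt_fir(erp.waveform, taps)
    return np.abs(hilbert(filtered))


def window_peak(envelope: np.ndarray, times: np.ndarray, t_start: float, t_end: float) -> float:
    """Maximum of the envelope over the closed interval [t_start, t_end]."""
    if t_start >= t_end:
        raise InvalidArgumentError("t_start must precede t_end")
    mask = (times >= t_start - 1e-9) & (times <= t_end + 1e-9)
    if not np.any(mask):
        raise InvalidArgumentError("window outside the waveform")
    return float(np.max(envelope[mask]))


def compute_neural_snr(
    erp: ERP,
    word_onset_s: float = 0.5,
    *,
    band: tuple[float, float] = (2.0, 7.0),
) -> NeuralSNRResult:
    """Neural SNR of an (NR-off) ERP, with the window peaks kept for audit."""
    env = erp_envelope(erp, band)
    times = erp.times
    noise_win = NOISE_WINDOW
    word_win = (word_onset_s + WORD_WINDOW_REL[0], word_onset_s + WORD_WINDOW_REL[1])
    peak_noise = window_peak(env, times, *noise_win)
    peak_word = window_peak(env, times, *word_win)
    if peak_noise <= 0:
        raise DegenerateInputError("zero envelope peak in the noise window")
    return NeuralSNRResult(
        peak_noise=peak_noise,
        peak_word=peak_word,
        neural_snr_db=20.0 * np.log10(peak_word / peak_noise),
        noise_window=noise_win,
        word_window=word_win,
    )
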