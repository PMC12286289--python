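"""Objective quantification of noise-reduction effects on stimuli.

Two complementary measures:

* **SNR enhancement** via the phase-inversion technique: the processor is run
  on ``s + n`` and on ``s - n`` (identical signals except for the noise
  phase); half-sum and half-difference of the outputs separate the post-NR
  speech and noise components, whose RMS ratio gives the post-NR SNR to be
  compared with the pre-NR SNR.
* **Speech distortion** via magnitude-squared coherence (MSC) between the
  clean speech and the post-NR speech component, averaged over frequency:
  1 means linearly identical, lower means distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import coherence as _scipy_coherence

from .audio import AudioSignal, TrialStimulus, rms
from .enhance import NRConfig, make_processor
from .exceptions import (
    ContractViolationError,
    DegenerateInputError,
    InsufficientAveragingError,
    InvalidArgumentError,
)

__all__ = [
    "NREffectReport",
    "phase_inversion_separate",
    "snr_rms_db",
    "snr_enhancement",
    "magnitude_squared_coherence",
    "mean_coherence_to",
    "evaluate_nr",
]


@dataclass(frozen=True)
class NREffectReport:
    """Summary of one NR evaluation on one stimulus."""

    variant: str
    snr_pre_db: float
    snr_post_db: float
    mean_coherence: float
    f_max_hz: float
    degenerate_noise: bool = False

    @property
    def snr_enhancement_db(self) -> float:
        return self.snr_post_db - self.snr_pre_db


def _as_array(sig) -> np.ndarray:
    return sig.samples if isinstance(sig, AudioSignal) else np.asarray(sig, float)


def phase_inversion_separate(processor, speech, noise, fs: float):
    """Separate post-processing speech and noise components.

    ``processor(x, fs)`` must be deterministic and length-preserving. Returns
    ``(speech_component, noise_component)`` with
    ``processor(s + n) == speech_component + noise_component`` exactly.
    """
    s = _as_array(speech)
    n = _as_array(noise)
    if len(s) != len(n):
        raise InvalidArgumentError("speech and noise must have equal length")
    y_plus = np.asarray(processor(s + n, fs), float)
    y_minus = np.asarray(processor(s - n, fs), float)
    if len(y_plus) != len(s) or len(y_minus) != len(s):
        raise ContractViolationError("processor changed the signal length")
    return (y_plus + y_minus) / 2.0, (y_plus - y_minus) / 2.0


def _segment_slice(n: int, fs: float, segment) -> slice:
    if segment is None:
        return slice(0, n)
    t0, t1 = segment
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if not (0 <= i0 < i1 <= n):
        raise InvalidArgumentError("segment outside the signals")
    return slice(i0, i1)


def snr_rms_db(speech_component, noise_component, fs: float, segment=None) -> float:
    """Non-weighted RMS SNR in dB over a time segment (whole signal if None)."""
    s = _as_array(speech_component)
    n = _as_array(noise_component)
    sl = _segment_slice(min(len(s), len(n)), fs, segment)
    rms_n = rms(n[sl])
    if rms_n == 0:
        raise DegenerateInputError("separated noise is exactly zero over the segment")
    return 20.0 * np.log10(rms(s[sl]) / rms_n)


def snr_enhancement(processor, speech, noise, fs: float, segment=None) -> float:
    """Post-NR minus pre-NR RMS SNR (dB) via phase inversion, same segment."""
    s_post, n_post = phase_inversion_separate(processor, speech, noise, fs)
    pre = snr_rms_db(speech, noise, fs, segment)
    post = snr_rms_db(s_post, n_post, fs, segment)
    return post - pre


def magnitude_squared_coherence(x, y, fs: float, nperseg: int = 1024):
    """Welch-averaged magnitude-squared coherence, ``|Pxy|^2 / (Pxx * Pyy)``.

    Hann windows with 50% overlap. Requires at least 8 averaging segments;
    with fewer, the estimator's bias makes the value meaningless.
    Returns ``(freqs, coherence)``.
    """
    x = _as_array(x)
    y = _as_array(y)
    if len(x) != len(y):
        raise InvalidArgumentError("signals must have equal length")
    n_segments = max(0, (len(x) - nperseg) // (nperseg // 2) + 1)
    if n_segments < 8:
        raise InsufficientAveragingError(
            f"only {n_segments} segments at nperseg={nperseg}; need >= 8"
        )
    freqs, coh = _scipy_coherence(
        x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, np.clip(coh, 0.0, 1.0)


def mean_coherence_to(freqs, coh_spectrum, f_max_hz: float, fs: float | None = None) -> float:
    """Unweighted mean of the coherence spectrum over ``0 < f <= f_max_hz``."""
    freqs = np.asarray(freqs, float)
    nyquist = fs / 2.0 if fs is not None else freqs[-1]
    if f_max_hz > nyquist + 1e-9:
        raise InvalidArgumentError("f_max_hz above the Nyquist frequency")
    mask = (freqs > 0) & (freqs <= f_max_hz + 1e-9)
    if not np.any(mask):
        raise InvalidArgumentError("no frequencies below f_max_hz")
    return float(np.mean(np.asarray(coh_spectrum, float)[mask]))


def evaluate_nr(
    stimulus: TrialStimulus,
    config: NRConfig,
    *,
    f_max_hz: float = 22000.0,
    nperseg: int = 1024,
    segment: tuple[float, float] | None = None,
) -> NREffectReport:
    """Full NR-effect evaluation of one trial stimulus.

    SNR enhancement and speech-distortion MSC are both measured over the
    word-overlap segment of the trial (configurable). The "pre-NR speech"
    for coherence is the clean word track; the "post-NR speech" is the
    phase-inversion speech component of the processed composite.
    """
    fs = stimulus.fs
    if segment is None:
        segment = stimulus.word_segment()
    processor = make_processor(config)
    s_post, n_post = phase_inversion_separate(
        processor, stimulus.word_track, stimulus.noise_track, fs
    )
    pre = snr_rms_db(stimulus.word_track, stimulus.noise_track, fs, segment)
    degenerate = False
    try:
        post = snr_rms_db(s_post, n_post, fs, segment)
    except DegenerateInputError:
        post, degenerate = np.nan, True

    sl = _segment_slice(len(s_post), fs, segment)
    freqs, coh = magnitude_squared_coherence(
        stimulus.word_track[sl], s_post[sl], fs, nperseg=nperseg
    )
    mean_coh = mean_coherence_to(freqs, coh, f_max_hz, fs=fs)
    return NREffectReport(
        variant=config.variant,
        snr_pre_db=pre,
        snr_post_db=post,
        mean_coherence=mean_coh,
        f_max_hz=f_max_hz,
        degenerate_noise=degenerate,
    )
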