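"""Stimulus construction for speech-in-noise trials.

The experimental trial this package models is a 1.5 s burst of speech-shaped
noise with a short target word starting 0.5 s after noise onset, the two mixed
at a nominal SNR (0 dB in the reference design) and the composite RMS-normalized
before presentation.

Because no recorded word corpus ships with the package, :func:`gen_target_token`
synthesizes a speech-like token (harmonic glottal source, time-varying
formant-style filtering, onset/offset ramps) and :func:`gen_speech_shaped_noise`
produces Gaussian noise shaped to a long-term-average-speech-spectrum (LTASS)
approximation: flat up to ``ltass_corner_hz`` and rolling off at a fixed dB/octave
rate above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "AudioSignal",
    "TrialStimulus",
    "rms",
    "gen_speech_shaped_noise",
    "gen_target_token",
    "mix_at_snr",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform with its sampling rate.

    Parameters
    ----------
    samples
        1-D float array, arbitrary amplitude units.
    fs
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InvalidArgumentError("samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("samples must be finite")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class TrialStimulus:
    """Composite noise+word trial with component bookkeeping.

    ``composite.samples == word_track + noise_track`` sample-for-sample, where
    the tracks already include the SNR scaling of the noise and the final
    RMS normalization of the composite, so the clean speech and noise paths
    can be reconstructed exactly after mixing.
    """

    composite: AudioSignal
    word_track: np.ndarray
    noise_track: np.ndarray
    word_onset_s: float
    noise_duration_s: float
    snr_db: float
    noise_onset_s: float = 0.0
    norm_gain: float = 1.0

    def __post_init__(self):
        if not (self.noise_onset_s <= self.word_onset_s < self.noise_duration_s):
            raise InvalidArgumentError(
                "word onset must lie inside the noise interval"
            )
        if self.composite.duration_s < self.noise_duration_s - 1e-9:
            raise InvalidArgumentError("composite shorter than the noise burst")

    @property
    def fs(self) -> float:
        return self.composite.fs

    def word_segment(self, word_duration_s: float | None = None) -> tuple[float, float]:
        """Time interval (s) over which the word overlaps the noise."""
        if word_duration_s is None:
            nz = np.flatnonzero(np.abs(self.word_track) > 0)
            end = (nz[-1] + 1) / self.fs if nz.size else self.word_onset_s
        else:
            end = self.word_onset_s + word_duration_s
        return self.word_onset_s, min(end, self.noise_duration_s)


def rms(signal: AudioSignal | np.ndarray) -> float:
    """Root-mean-square amplitude, ``sqrt(mean(x**2))``."""
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    if x.size == 0:
        raise InvalidArgumentError("empty signal has no RMS")
    return float(np.sqrt(np.mean(x**2)))


def _ltass_gain(freqs: np.ndarray, corner_hz: float, rolloff_db_per_oct: float) -> np.ndarray:
    """Amplitude gain of the LTASS approximation at the given frequencies."""
    gain = np.ones_like(freqs)
    above = freqs > corner_hz
    octaves = np.log2(freqs[above] / corner_hz)
    gain[above] = 10.0 ** (-rolloff_db_per_oct * octaves / 20.0)
    return gain


def gen_speech_shaped_noise(
    duration_s: float,
    fs: float,
    seed: int,
    *,
    ltass_corner_hz: float = 500.0,
    rolloff_db_per_oct: float = 9.0,
    rms_out: float = 0.1,
) -> AudioSignal:
    """Speech-shaped Gaussian noise.

    White Gaussian noise is shaped in the frequency domain by an LTASS
    approximation: flat below ``ltass_corner_hz`` and −``rolloff_db_per_oct``
    per octave above, then scaled to ``rms_out``. Bit-reproducible given
    identical arguments.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= _ltass_gain(freqs, ltass_corner_hz, rolloff_db_per_oct)
    shaped = np.fft.irfft(spec, n=n)
    shaped *= rms_out / rms(shaped)
    return AudioSignal(shaped, fs)


def _gate(n: int, fs: float, a: float, b: float, ramp_s: float) -> np.ndarray:
    """Unit gate over [a, b] seconds with raised-cosine edges."""
    w = np.zeros(n)
    ia, ib = int(round(a * fs)), min(int(round(b * fs)), n)
    nr = max(1, min(int(round(ramp_s * fs)), (ib - ia) // 2))
    w[ia:ib] = 1.0
    w[ia : ia + nr] = np.sin(np.linspace(0, np.pi / 2, nr)) ** 2
    w[ib - nr : ib] = np.cos(np.linspace(0, np.pi / 2, nr)) ** 2
    return w


def gen_target_token(
    duration_s: float,
    fs: float,
    seed: int,
    *,
    f0_hz: tuple[float, float] = (125.0, 95.0),
    fric_gain: float = 0.55,
    breathiness: float = 0.12,
    fric_band: tuple[float, float] = (1500.0, 10000.0),
    ramp_s: float = 0.05,
    rms_out: float = 0.1,
) -> AudioSignal:
    """A synthetic speech-like token standing in for a recorded CVC monosyllable.

    The token mimics the spectro-temporal balance of spoken monosyllables:
    a continuously voiced nucleus (harmonic source with a falling f0 glide,
    formant peaks, an LTASS-consistent high-frequency roll-off and a low
    breathiness floor) overlaid with noise-like consonant frication at the
    onset and, weaker, at the offset, roughly 5 dB below the vowel and
    extending through ``fric_band``. Raised-cosine ramps keep the first and
    last 10 ms near zero. Spectral energy is concentrated well below
    ``fs / 4``.
    """
    if not (0.2 <= duration_s <= 1.0):
        raise InvalidArgumentError("token duration must be in [0.2, 1.0] s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    ltass = _ltass_gain(np.maximum(freqs, 1.0), 500.0, 9.0)

    # voiced nucleus: harmonics with formant + LTASS spectral envelope
    f0 = np.linspace(f0_hz[0], f0_hz[1], n)
    phase0 = np.cumsum(2 * np.pi * f0 / fs)
    h_max = max(2, int(0.45 * fs / max(f0_hz)))
    source = np.zeros(n)
    for h in range(1, h_max + 1):
        source += np.cos(h * phase0 + rng.uniform(0, 2 * np.pi)) / np.sqrt(h)
    formants = np.zeros_like(freqs)
    for fc, bw in ((600.0, 130.0), (1400.0, 200.0), (2500.0, 250.0)):
        formants += 1.0 / (1.0 + ((freqs - fc) / bw) ** 2)
    vowel = np.fft.irfft(np.fft.rfft(source) * ltass * (formants + breathiness), n=n)
    vowel /= rms(vowel)

    # consonant frication: band-limited noise with the same long-term tilt
    lo, hi = fric_band
    gain = np.where(freqs > lo, 1.0, 0.0) * ltass
    gain *= np.exp(-np.maximum(freqs - hi, 0.0) / 5000.0)
    fric = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * gain, n=n)
    fric /= rms(fric)

    c_len = 0.24 * duration_s  # consonant intervals at the token edges
    token = vowel * _gate(n, fs, 0.0, duration_s, ramp_s)
    token += fric_gain * fric * _gate(n, fs, 0.0, c_len, 0.6 * ramp_s)
    token += 0.7 * fric_gain * fric * _gate(n, fs, duration_s - c_len, duration_s, 0.6 * ramp_s)

    token *= rms_out / rms(token)
    return AudioSignal(token, fs)


def mix_at_snr(
    word: AudioSignal,
    noise: AudioSignal,
    snr_db: float,
    word_onset_s: float,
    *,
    reference_rms: float = 0.1,
) -> TrialStimulus:
    """Insert ``word`` into ``noise`` at the requested SNR and RMS-normalize.

    The mixing SNR is defined over the noise samples temporally overlapping
    the word (the word occupies only part of the noise burst), i.e. the noise
    is scaled so that ``20*log10(rms(word) / rms(noise_overlap)) == snr_db``.
    The composite is then scaled to ``reference_rms``; both the clean word
    track and the noise track are returned with the same scaling applied, so
    ``word_track + noise_track`` reconstructs the composite exactly.
    """
    if word.fs != noise.fs:
        raise InvalidArgumentError("word and noise must share the sampling rate")
    fs = word.fs
    i0 = int(round(word_onset_s * fs))
    i1 = i0 + len(word)
    if i0 < 0 or i1 > len(noise):
        raise InvalidArgumentError("noise too short to contain the word at this onset")
    rms_word = rms(word)
    seg = noise.samples[i0:i1]
    rms_noise = rms(seg)
    if rms_word == 0 or rms_noise == 0:
        raise DegenerateInputError("zero-RMS word or noise segment")

    noise_gain = rms_word / (rms_noise * 10.0 ** (snr_db / 20.0))
    noise_track = noise.samples * noise_gain
    word_track = np.zeros(len(noise))
    word_track[i0:i1] = word.samples
    composite = word_track + noise_track

    norm_gain = reference_rms / rms(composite)
    return TrialStimulus(
        composite=AudioSignal(composite * norm_gain, fs),
        word_track=word_track * norm_gain,
        noise_track=noise_track * norm_gain,
        word_onset_s=word_onset_s,
        noise_duration_s=noise.duration_s,
        snr_db=snr_db,
        norm_gain=norm_gain,
    )


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file as float64."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise InvalidArgumentError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(data.astype(float), float(fs))


def write_wav(path, signal: AudioSignal) -> None:
    """Write a waveform as 32-bit float PCM WAV."""
    wavfile.write(path, int(signal.fs), signal.samples.astype(np.float32))
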