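"""Single-channel spectral-amplitude noise reduction (Ephraim-Malah family).

Two short-time spectral-amplitude estimators are provided:

* ``mmse`` — minimizes the mean-square error of the *linear* spectral
  amplitude (the classic MMSE-STSA gain, Bessel-function form);
* ``log_mmse`` — minimizes the error of the *logarithmic* spectral amplitude
  (exponential-integral form), which attenuates noise more aggressively.

Both share the same front end: overlapping Hamming-windowed frames (20 ms by
default), FFT, a noise-PSD estimate taken from the leading noise-only portion
of the stimulus, a decision-directed a-priori-SNR recursion, and overlap-add
resynthesis with the noisy phase.

The a priori SNR xi and a posteriori SNR gamma are per-bin, linear-scale:
``gamma = |Y|^2 / lambda_noise`` and

``xi_hat = alpha * A_prev^2 / lambda_noise + (1 - alpha) * max(gamma - 1, 0)``

floored at ``xi_min``. The gain is floored at ``gain_floor`` so the masker is
attenuated, not removed, matching hearing-aid practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from scipy.special import exp1, ive

from .audio import AudioSignal
from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "NRConfig",
    "frame_split",
    "overlap_add",
    "estimate_noise_psd",
    "mmse_gain",
    "log_mmse_gain",
    "decision_directed_xi",
    "apply_nr",
    "make_processor",
]


@dataclass(frozen=True)
class NRConfig:
    """Parameters of the spectral-subtraction-family NR pipeline.

    Defaults follow common Ephraim-Malah practice: 20 ms Hamming frames at
    50% hop, decision-directed smoothing ``alpha_dd = 0.98``, a priori SNR
    floor −25 dB, spectral gain floor −25 dB, and a 0.5 s noise-only lead
    used for the (fixed) noise-PSD estimate.
    """

    variant: str = "mmse"
    frame_ms: float = 20.0
    window: str = "hamming"
    hop_fraction: float = 0.5
    alpha_dd: float = 0.98
    xi_min_db: float = -25.0
    gain_floor: float = 10.0 ** (-25.0 / 20.0)
    noise_init_s: float = 0.5

    def __post_init__(self):
        if self.variant not in ("mmse", "log_mmse"):
            raise InvalidArgumentError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.hop_fraction < 1.0):
            raise InvalidArgumentError("hop_fraction must be in (0, 1)")
        if not (0.0 <= self.alpha_dd < 1.0):
            raise InvalidArgumentError("alpha_dd must be in [0, 1)")
        if not (0.0 < self.gain_floor <= 1.0):
            raise InvalidArgumentError("gain_floor must be in (0, 1]")
        if self.frame_ms <= 0 or self.noise_init_s <= 0:
            raise InvalidArgumentError("frame_ms and noise_init_s must be positive")

    def frame_len(self, fs: float) -> int:
        return int(round(self.frame_ms * fs / 1000.0))

    def hop(self, fs: float) -> int:
        hop = int(round(self.frame_len(fs) * self.hop_fraction))
        if hop < 1:
            raise InvalidArgumentError("hop shorter than one sample")
        return hop

    @property
    def xi_min(self) -> float:
        return 10.0 ** (self.xi_min_db / 10.0)


def frame_split(signal: AudioSignal, config: NRConfig) -> np.ndarray:
    """Split into overlapping windowed frames, shape (n_frames, frame_len)."""
    x = signal.samples
    frame_len = config.frame_len(signal.fs)
    hop = config.hop(signal.fs)
    if len(x) < frame_len:
        raise InvalidArgumentError("signal shorter than one frame")
    n_frames = (len(x) - frame_len) // hop + 1
    window = get_window(config.window, frame_len, fftbins=True)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx] * window[None, :]


def overlap_add(
    frames: np.ndarray, hop: int, window: np.ndarray, n_out: int | None = None
) -> np.ndarray:
    """Overlap-add synthesis with window-sum compensation.

    ``frames`` are assumed to already carry one application of ``window``
    (from :func:`frame_split`); dividing the accumulated output by the
    accumulated window sum inverts the analysis weighting, so
    ``overlap_add(frame_split(x), ...)`` reconstructs ``x``.
    """
    n_frames, frame_len = frames.shape
    total = hop * (n_frames - 1) + frame_len
    out = np.zeros(total)
    wsum = np.zeros(total)
    for i in range(n_frames):
        sl = slice(i * hop, i * hop + frame_len)
        out[sl] += frames[i]
        wsum[sl] += window
    out = out / np.maximum(wsum, 1e-12)
    return out[:n_out] if n_out is not None else out


def estimate_noise_psd(frames: np.ndarray, fs: float, config: NRConfig) -> np.ndarray:
    """Mean one-sided periodogram over the frames inside the noise-only lead.

    A frame counts as noise-only when it ends no later than
    ``config.noise_init_s``. The estimate is floored at a small positive
    value so downstream divisions are safe.
    """
    frame_len = config.frame_len(fs)
    hop = config.hop(fs)
    n_lead = int(round(config.noise_init_s * fs))
    n_noise = (n_lead - frame_len) // hop + 1
    if n_noise < 1:
        raise ConfigurationError("noise_init_s shorter than one frame")
    n_noise = min(n_noise, frames.shape[0])
    spec = np.fft.rfft(frames[:n_noise], axis=1)
    psd = np.mean(np.abs(spec) ** 2, axis=0)
    return np.maximum(psd, 1e-12 * max(psd.max(), 1.0))


def _validate_snrs(xi, gamma):
    xi = np.asarray(xi, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(xi <= 0) or np.any(gamma <= 0):
        raise InvalidArgumentError("xi and gamma must be strictly positive")
    return xi, gamma


def mmse_gain(xi, gamma):
    """MMSE short-time spectral-amplitude gain.

    With ``nu = xi * gamma / (1 + xi)``::

        G = (sqrt(pi)/2) * (sqrt(nu)/gamma) * exp(-nu/2)
            * [(1 + nu) * I0(nu/2) + nu * I1(nu/2)]

    evaluated with exponentially scaled Bessel functions so large ``nu``
    (strong speech dominance) stays finite; the Wiener gain is the limit.
    """
    xi, gamma = _validate_snrs(xi, gamma)
    nu = xi * gamma / (1.0 + xi)
    # the scaled Bessels lose accuracy (and eventually NaN) for huge nu;
    # there the estimator has converged to the Wiener gain anyway
    safe_nu = np.minimum(nu, 1e6)
    half = safe_nu / 2.0
    bracket = (1.0 + safe_nu) * ive(0, half) + safe_nu * ive(1, half)
    bessel_form = (np.sqrt(np.pi) / 2.0) * (np.sqrt(safe_nu) / gamma) * bracket
    return np.where(nu > 1e6, xi / (1.0 + xi), bessel_form)


def log_mmse_gain(xi, gamma):
    """Log-MMSE spectral-amplitude gain.

    ``G = xi/(1+xi) * exp(E1(nu)/2)`` with ``E1`` the exponential integral,
    clamped at 1 (the raw estimator can exceed unity when the a posteriori
    SNR is far below the a priori SNR; amplification is never wanted here).
    Sits below the MMSE gain everywhere, hence the stronger noise
    attenuation of this variant.
    """
    xi, gamma = _validate_snrs(xi, gamma)
    nu = xi * gamma / (1.0 + xi)
    return np.minimum(xi / (1.0 + xi) * np.exp(0.5 * exp1(nu)), 1.0)


def decision_directed_xi(prev_amp2, noise_psd, gamma, alpha_dd, xi_min):
    """Decision-directed a priori SNR estimate, floored at ``xi_min`` (linear)."""
    prev_amp2 = np.asarray(prev_amp2, dtype=float)
    noise_psd = np.asarray(noise_psd, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(noise_psd < 0):
        raise InvalidArgumentError("noise_psd must be nonnegative")
    if not (0.0 <= alpha_dd < 1.0):
        raise InvalidArgumentError("alpha_dd must be in [0, 1)")
    xi = alpha_dd * prev_amp2 / np.maximum(noise_psd, 1e-30) + (1.0 - alpha_dd) * np.maximum(
        gamma - 1.0, 0.0
    )
    return np.maximum(xi, xi_min)


_GAINS = {"mmse": mmse_gain, "log_mmse": log_mmse_gain}


def apply_nr(signal: AudioSignal, config: NRConfig) -> AudioSignal:
    """Run the full NR pipeline on a stimulus.

    Ends are reflect-padded by one frame so the output has exactly the input
    length; the noise PSD is estimated once from the leading noise-only
    interval of the *unpadded* signal and held fixed (stationary masker).
    """
    fs = signal.fs
    frame_len = config.frame_len(fs)
    hop = config.hop(fs)
    if len(signal) < frame_len:
        raise InvalidArgumentError("signal shorter than one frame")
    window = get_window(config.window, frame_len, fftbins=True)
    gain_fn = _GAINS[config.variant]

    # noise PSD from the unpadded lead
    frames_raw = frame_split(signal, config)
    noise_psd = estimate_noise_psd(frames_raw, fs, config)

    pad = frame_len
    x = np.pad(signal.samples, pad, mode="reflect")
    n_frames = (len(x) - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * window[None, :]
    spec = np.fft.rfft(frames, axis=1)
    mag2 = np.abs(spec) ** 2

    gamma = np.maximum(mag2 / noise_psd[None, :], 1e-12)
    out_frames = np.empty_like(frames)
    prev_amp2 = np.zeros(noise_psd.shape)
    for i in range(n_frames):
        xi = decision_directed_xi(
            prev_amp2, noise_psd, gamma[i], config.alpha_dd, config.xi_min
        )
        gain = np.maximum(gain_fn(xi, gamma[i]), config.gain_floor)
        enhanced = gain * spec[i]
        prev_amp2 = np.abs(enhanced) ** 2
        out_frames[i] = np.fft.irfft(enhanced, n=frame_len)

    y = overlap_add(out_frames, hop, window)
    y = y[pad : pad + len(signal)]
    return AudioSignal(y, fs)


def make_processor(config: NRConfig):
    """A ``samples -> samples`` callable over a fixed config, for use with the
    phase-inversion measurement in :mod:`nrlab.metrics`."""

    def processor(x: np.ndarray, fs: float) -> np.ndarray:
        return apply_nr(AudioSignal(np.asarray(x, float), fs), config).samples

    return processor
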