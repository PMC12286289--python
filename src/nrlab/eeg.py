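"""Epoched-EEG preprocessing and ERP computation.

The pipeline, in the order it is meant to be applied:

1. zero-phase FIR bandpass (1–50 Hz, two-pass forward/reverse),
2. re-reference to the average of the two mastoids,
3. baseline correction (mean of the 200 ms pre-stimulus window),
4. downsample to 256 Hz (polyphase, anti-aliased),
5. average over trials and the front-central channel set → ERP.

Epochs are time-locked to the noise onset of the speech-in-noise trial
(t = 0), spanning −0.5 to 2.5 s by convention. An ICA artifact-removal hook
exists as a pass-through: ocular artifact rejection in real recordings is a
manual, topography-guided step outside this package's scope, and synthetic
epochs contain none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import firwin2, resample_poly

from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "FRONT_CENTRAL",
    "MASTOIDS",
    "EpochSet",
    "ERP",
    "bandpass_zero_phase",
    "rereference_mastoids",
    "baseline_correct",
    "downsample",
    "average_erp",
    "remove_artifacts_hook",
    "preprocess",
    "save_epochs",
    "load_epochs",
]

FRONT_CENTRAL = ("Fz", "FCz", "FC1", "FC2", "Cz")
MASTOIDS = ("M1", "M2")


@dataclass(frozen=True)
class EpochSet:
    """EEG trials time-locked to noise onset.

    ``data`` has shape (n_trials, n_channels, n_samples) in µV; ``t0_s`` is
    the time of the first sample relative to noise onset (−0.5 s by default).
    """

    data: np.ndarray
    fs: float
    t0_s: float
    channel_names: tuple[str, ...]
    condition: str = "nr_off"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise InvalidArgumentError("data must be (trials, channels, samples)")
        if data.shape[1] != len(self.channel_names):
            raise InvalidArgumentError("channel_names length mismatch")
        if not (self.t0_s <= 0 < self.t0_s + data.shape[2] / self.fs):
            raise InvalidArgumentError("epoch must contain t = 0 (noise onset)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not present") from None


@dataclass(frozen=True)
class ERP:
    """Condition-averaged waveform (µV) over a channel set."""

    waveform: np.ndarray
    fs: float
    t0_s: float
    condition: str = "nr_off"

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.waveform)) / self.fs


def design_fir_bandpass(lo: float, hi: float, fs: float, numtaps: int | None = None) -> np.ndarray:
    """Windowed-sinc linear-phase bandpass used by the two-pass filters.

    Transition bands are half the low edge below ``lo`` and 10% above ``hi``;
    the default length targets ~0.8 Hz of frequency resolution at the low
    edge, which places the stopband comfortably below drift frequencies.
    """
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise InvalidArgumentError("need 0 < lo < hi < fs/2")
    if numtaps is None:
        numtaps = int(round(8.0 * fs / lo)) | 1
    # transitions no sharper than the filter can realize, else Gibbs ripple
    # bleeds into the passband
    trans = 3.3 * fs / numtaps
    lo_stop = max(lo / 2.0, lo - trans)
    hi_stop = min(hi + max(trans, 0.05 * hi), 0.999 * nyq)
    freqs = [0.0, lo_stop, lo, hi, hi_stop, nyq]
    gains = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return firwin2(numtaps, freqs, gains, fs=fs)


def filtfilt_fir(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Two-pass (forward and reverse) FIR filtering with reflection padding.

    The taps are symmetric (linear phase), so each centered pass is already
    zero-phase; applying the filter twice squares the magnitude response and
    guarantees exactly zero net phase shift.
    """
    x = np.asarray(x, float)
    x = np.moveaxis(x, axis, -1)
    pad = len(taps)
    # odd extension continues both value and slope, so near-periodic signals
    # see no artificial edge discontinuity
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect", reflect_type="odd")
    # both passes collapse into one convolution with the taps' self-convolution
    h2 = np.convolve(taps, taps)
    nfft = next_fast_len(xp.shape[-1] + len(h2) - 1)
    spec = np.fft.rfft(xp, n=nfft, axis=-1) * np.fft.rfft(h2, n=nfft)
    full = np.fft.irfft(spec, n=nfft, axis=-1)
    delay = len(taps) - 1  # center of h2
    out = full[..., delay + pad : delay + pad + x.shape[-1]]
    return np.moveaxis(out, -1, axis)


def bandpass_zero_phase(epochs: EpochSet, lo: float = 1.0, hi: float = 50.0) -> EpochSet:
    """Two-pass zero-phase FIR bandpass applied to every trial and channel."""
    taps = design_fir_bandpass(lo, hi, epochs.fs)
    return replace(epochs, data=filtfilt_fir(epochs.data, taps, axis=-1))


def rereference_mastoids(epochs: EpochSet) -> EpochSet:
    """Subtract the average of M1 and M2 from every channel, per sample."""
    for m in MASTOIDS:
        epochs.channel_index(m)
    i1, i2 = (epochs.channel_index(m) for m in MASTOIDS)
    ref = (epochs.data[:, i1, :] + epochs.data[:, i2, :]) / 2.0
    return replace(epochs, data=epochs.data - ref[:, None, :])


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the pre-stimulus window."""
    t0, t1 = window
    if t1 > 0 or t0 >= t1:
        raise InvalidArgumentError("baseline window must precede t = 0")
    times = epochs.times
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    if not np.any(mask):
        raise InvalidArgumentError("baseline window outside the epoch")
    base = epochs.data[:, :, mask].mean(axis=2)
    return replace(epochs, data=epochs.data - base[:, :, None])


def downsample(epochs: EpochSet, target_fs: float = 256.0) -> EpochSet:
    """Polyphase anti-aliased resampling to ``target_fs``."""
    if target_fs > epochs.fs:
        raise InvalidArgumentError("target_fs above the original rate")
    if target_fs == epochs.fs:
        return epochs
    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    data = resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1, padtype="line")
    return replace(epochs, data=data, fs=epochs.fs * frac.numerator / frac.denominator)


def average_erp(epochs: EpochSet, channels=FRONT_CENTRAL) -> ERP:
    """Mean over trials, then over the named channels."""
    if len(channels) == 0:
        raise InvalidArgumentError("empty channel selection")
    if epochs.data.shape[0] < 1:
        raise InvalidArgumentError("need at least one trial")
    idx = [epochs.channel_index(c) for c in channels]
    wave = epochs.data.mean(axis=0)[idx, :].mean(axis=0)
    return ERP(wave, epochs.fs, epochs.t0_s, epochs.condition)


def remove_artifacts_hook(epochs: EpochSet) -> EpochSet:
    """Pass-through placeholder for manual ocular-artifact rejection."""
    return epochs


def preprocess(
    epochs: EpochSet,
    *,
    band: tuple[float, float] = (1.0, 50.0),
    baseline: tuple[float, float] = (-0.2, 0.0),
    target_fs: float = 256.0,
    channels=FRONT_CENTRAL,
) -> ERP:
    """The full fixed-order pipeline: filter → re-reference → baseline →
    downsample → average."""
    out = bandpass_zero_phase(epochs, *band)
    out = rereference_mastoids(out)
    out = remove_artifacts_hook(out)
    out = baseline_correct(out, baseline)
    out = downsample(out, target_fs)
    return average_erp(out, channels)


def save_epochs(path, epochs: EpochSet) -> None:
    """Write an EpochSet as a compressed .npz plus a JSON sidecar."""
    path = str(path)
    np.savez_compressed(path if path.endswith(".npz") else path + ".npz", data=epochs.data)
    meta = {
        "fs": epochs.fs,
        "t0_s": epochs.t0_s,
        "channel_names": list(epochs.channel_names),
        "condition": epochs.condition,
    }
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_epochs(path) -> EpochSet:
    path = str(path)
    stem = path[:-4] if path.endswith(".npz") else path
    data = np.load(stem + ".npz")["data"]
    with open(stem + ".json") as fh:
        meta = json.load(fh)
    return EpochSet(
        data,
        fs=meta["fs"],
        t0_s=meta["t0_s"],
        channel_names=tuple(meta["channel_names"]),
        condition=meta["condition"],
    )
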