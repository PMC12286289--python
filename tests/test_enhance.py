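"""Spectral-amplitude NR: framing, noise PSD, gain functions, full pipeline."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import get_window
from scipy.special import i0e

from nrlab.audio import AudioSignal, gen_speech_shaped_noise, gen_target_token, rms
from nrlab.enhance import (
    NRConfig,
    apply_nr,
    decision_directed_xi,
    estimate_noise_psd,
    frame_split,
    log_mmse_gain,
    mmse_gain,
    overlap_add,
)
from nrlab.exceptions import ConfigurationError, InvalidArgumentError

FS = 44100.0
CFG = NRConfig()


def test_frame_split_counts_and_window():
    sig = gen_speech_shaped_noise(1.5, FS, seed=1)
    frames = frame_split(sig, CFG)
    frame_len = int(round(0.020 * FS))
    hop = frame_len // 2
    assert frames.shape == ((len(sig) - frame_len) // hop + 1, frame_len)
    assert frames.shape == (149, 882)
    ones = AudioSignal(np.ones(4 * frame_len), FS)
    w = get_window("hamming", frame_len, fftbins=True)
    np.testing.assert_allclose(frame_split(ones, CFG)[2], w, atol=1e-12)
    with pytest.raises(InvalidArgumentError):
        frame_split(AudioSignal(np.ones(10), FS), CFG)


def test_frame_overlap_add_round_trip(rng):
    sig = AudioSignal(rng.standard_normal(int(0.3 * FS)), FS)
    frames = frame_split(sig, CFG)
    frame_len = frames.shape[1]
    hop = frame_len // 2
    w = get_window("hamming", frame_len, fftbins=True)
    rec = overlap_add(frames, hop, w)
    interior = slice(frame_len, len(rec) - frame_len)
    np.testing.assert_allclose(rec[interior], sig.samples[interior], atol=1e-8)


def test_noise_psd_flat_for_white_noise(rng):
    # >= 50 averaged frames inside a long noise-only lead
    cfg = NRConfig(noise_init_s=0.6)
    x = rng.standard_normal(int(0.7 * FS))
    frames = frame_split(AudioSignal(x, FS), cfg)
    psd = estimate_noise_psd(frames, FS, cfg)
    assert len(psd) == 882 // 2 + 1
    inner = psd[1:-1]  # DC/Nyquist carry half weight under a one-sided DFT
    assert inner.max() / inner.min() < 3.0


def test_noise_psd_sine_concentration():
    frame_len = int(round(0.020 * FS))
    t = np.arange(int(0.6 * FS)) / FS
    f_bin = 10 * FS / frame_len  # exactly bin 10
    x = np.sin(2 * np.pi * f_bin * t)
    frames = frame_split(AudioSignal(x, FS), CFG)
    psd = estimate_noise_psd(frames, FS, CFG)
    assert psd[8:13].sum() / psd.sum() > 0.95
    with pytest.raises(ConfigurationError):
        estimate_noise_psd(frames, FS, NRConfig(noise_init_s=0.001))


def _mmse_gain_quadrature(xi, gamma):
    """Posterior-mean amplitude of the Rician posterior, by direct quadrature.

    The Rice density is written with the exponentially scaled Bessel i0e so
    the integrand stays finite at large arguments.
    """
    r = np.sqrt(gamma)  # noise PSD normalized to 1
    mu = xi / (1 + xi) * r
    sigma2 = xi / (1 + xi) / 2.0
    pdf = lambda a: (
        a / sigma2 * np.exp(-((a - mu) ** 2) / (2 * sigma2)) * i0e(a * mu / sigma2)
    )
    hi = mu + 12 * np.sqrt(sigma2)
    num = quad(lambda a: a * pdf(a), 0, hi)[0]
    den = quad(pdf, 0, hi)[0]
    return num / den / r


@pytest.mark.parametrize("xi,gamma", [(1.0, 1.0), (0.3, 2.0), (3.0, 0.5), (10.0, 10.0)])
def test_mmse_gain_matches_conditional_mean_quadrature(xi, gamma):
    assert mmse_gain(xi, gamma) == pytest.approx(_mmse_gain_quadrature(xi, gamma), abs=1e-6)


def test_gain_wiener_limits_and_monotonicity():
    # the high-SNR (Wiener) regime is nu -> infinity, i.e. both SNRs large
    assert abs(mmse_gain(1e6, 1e6) - 1.0) < 1e-3
    assert abs(log_mmse_gain(1e6, 1e6) - 1.0) < 1e-3
    xi = np.logspace(-2, 2, 50)
    g = mmse_gain(xi, np.full_like(xi, 2.0))
    assert np.all(np.diff(g) > 0)


def test_log_mmse_below_mmse_on_grid():
    xi, gamma = np.meshgrid(np.logspace(-2, 2, 25), np.logspace(-2, 2, 25))
    g_log = log_mmse_gain(xi, gamma)
    g_lin = mmse_gain(xi, gamma)
    assert np.all(g_log <= g_lin + 1e-12)
    assert np.all(g_log <= 1.0 + 1e-12)
    # strict for moderate nu
    assert log_mmse_gain(1.0, 1.0) < mmse_gain(1.0, 1.0)


def test_log_mmse_matches_exp1_quadrature():
    xi = gamma = 1.0
    nu = xi * gamma / (1 + xi)
    e1 = quad(lambda t: np.exp(-t) / t, nu, np.inf)[0]
    expected = xi / (1 + xi) * np.exp(e1 / 2)
    assert log_mmse_gain(xi, gamma) == pytest.approx(expected, abs=1e-6)


def test_gains_reject_nonpositive_inputs():
    for fn in (mmse_gain, log_mmse_gain):
        with pytest.raises(InvalidArgumentError):
            fn(0.0, 1.0)
        with pytest.raises(InvalidArgumentError):
            fn(1.0, -1.0)


def test_decision_directed_xi_contracts():
    assert decision_directed_xi(0.0, 1.0, 2.0, 0.0, 1e-3) == pytest.approx(1.0)
    assert decision_directed_xi(0.0, 1.0, 0.5, 0.5, 1e-3) == pytest.approx(1e-3)
    with pytest.raises(InvalidArgumentError):
        decision_directed_xi(0.0, -1.0, 2.0, 0.5, 1e-3)
    with pytest.raises(InvalidArgumentError):
        NRConfig(alpha_dd=1.0)


def test_apply_nr_deterministic_and_length_preserving(trial_stimulus):
    y1 = apply_nr(trial_stimulus.composite, CFG)
    y2 = apply_nr(trial_stimulus.composite, CFG)
    np.testing.assert_array_equal(y1.samples, y2.samples)
    assert len(y1) == len(trial_stimulus.composite)
    assert y1.fs == FS


def test_apply_nr_passes_clean_signal_through():
    # near-silent lead, then a clean token: noise PSD ~ 0, gains ~ 1
    token = gen_target_token(0.5, FS, seed=4)
    lead = np.full(int(0.5 * FS), 1e-8)
    x = AudioSignal(np.concatenate([lead, token.samples]), FS)
    y = apply_nr(x, CFG)
    seg = slice(int(0.55 * FS), len(x))
    err = rms(y.samples[seg] - x.samples[seg]) / rms(x.samples[seg])
    assert err < 0.05


def test_apply_nr_attenuates_stationary_noise():
    noise = gen_speech_shaped_noise(1.5, FS, seed=9)
    for variant in ("mmse", "log_mmse"):
        y = apply_nr(noise, NRConfig(variant))
        assert rms(y) < rms(noise)


def test_log_mmse_attenuates_noise_segment_more(trial_stimulus):
    seg = slice(int(1.1 * FS), int(1.5 * FS))  # noise-only tail
    out = {
        v: apply_nr(trial_stimulus.composite, NRConfig(v)).samples[seg]
        for v in ("mmse", "log_mmse")
    }
    assert rms(out["log_mmse"]) < rms(out["mmse"])


def test_noise_psd_invariant_to_noise_phase_inversion(trial_stimulus):
    s, n = trial_stimulus.word_track, trial_stimulus.noise_track
    f_plus = frame_split(AudioSignal(s + n, FS), CFG)
    f_minus = frame_split(AudioSignal(s - n, FS), CFG)
    np.testing.assert_array_equal(
        estimate_noise_psd(f_plus, FS, CFG), estimate_noise_psd(f_minus, FS, CFG)
    )
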