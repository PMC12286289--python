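"""Synthetic cohorts: EEG epochs, subjective ratings, and behavioral outcomes.

Every generator is a pure function of its arguments, including the seed, and
plants known ground truth so downstream estimators can be validated by
parameter recovery:

* :func:`gen_eeg_epochs` embeds noise-onset and word-onset evoked responses
  with a programmable amplitude ratio (the true neural SNR) in 1/f background
  EEG;
* :func:`gen_rating_dataset` draws participants from planted clusters in
  weighted-rating space and emits the raw absolute ratings and paired
  comparisons that reproduce those weighted ratings in expectation;
* :func:`gen_outcomes` links behavioral accuracies to the neural SNR through
  a linear-Gaussian model with configurable target correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import FRONT_CENTRAL, MASTOIDS, EpochSet
from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "DOMAINS",
    "DOMAIN_PAIRS",
    "NeuralProfile",
    "ClusterSpec",
    "RatingDataset",
    "OutcomeLink",
    "gen_eeg_epochs",
    "gen_neural_profiles",
    "gen_rating_dataset",
    "gen_outcomes",
]

DOMAINS = ("noise_annoyance", "speech_interference", "listening_effort")
DOMAIN_PAIRS = (
    ("noise_annoyance", "speech_interference"),
    ("noise_annoyance", "listening_effort"),
    ("speech_interference", "listening_effort"),
)

#: relative evoked-response gain per channel; mastoids see no evoked activity
#: so mastoid re-referencing leaves the front-central responses intact.
CHANNEL_GAINS = {
    "Fz": 1.0, "FCz": 1.0, "FC1": 0.9, "FC2": 0.9, "Cz": 1.0, "M1": 0.0, "M2": 0.0,
}


@dataclass(frozen=True)
class NeuralProfile:
    """Ground-truth evoked amplitudes of one simulated participant.

    ``20*log10(a_word / a_noise)`` is the participant's true neural SNR.
    Latencies are relative to the respective onsets; ``background_sd`` scales
    the 1/f background EEG (µV, single-trial broadband standard deviation).
    """

    a_noise: float
    a_word: float
    latency_noise_s: float = 0.15
    latency_word_s: float = 0.25
    background_sd: float = 15.0

    def __post_init__(self):
        if self.a_noise <= 0 or self.a_word <= 0:
            raise InvalidArgumentError("evoked amplitudes must be positive")
        if self.background_sd < 0:
            raise InvalidArgumentError("background_sd must be nonnegative")

    @property
    def true_neural_snr_db(self) -> float:
        return 20.0 * np.log10(self.a_word / self.a_noise)


def _evoked_wavelet(times, peak_t, amplitude, freq_hz=4.5, duration_s=0.3):
    """Hann-windowed cosine burst whose envelope peaks at ``amplitude``.

    Centered in the 2–7 Hz analysis band so the Hilbert-envelope maximum
    tracks the programmed amplitude.
    """
    rel = times - peak_t
    half = duration_s / 2.0
    win = np.where(np.abs(rel) <= half, np.cos(np.pi * rel / duration_s) ** 2, 0.0)
    return amplitude * win * np.cos(2 * np.pi * freq_hz * rel)


def _pink_noise(rng, shape, n_samples, fs):
    """1/f-amplitude background noise, unit standard deviation, i.i.d. traces."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    gain[0] = 0.0
    pink = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    return pink / pink.std()


def gen_eeg_epochs(
    profile: NeuralProfile,
    n_trials: int,
    fs: float = 1024.0,
    seed: int = 0,
    *,
    channel_names: tuple[str, ...] = FRONT_CENTRAL + MASTOIDS,
    word_onset_s: float = 0.5,
    t0_s: float = -0.5,
    duration_s: float = 3.0,
    condition: str = "nr_off",
) -> EpochSet:
    """Simulated epochs spanning −0.5 to 2.5 s around noise onset.

    Each trial contains i.i.d. 1/f background noise on every channel plus two
    deterministic evoked bursts on the front-central channels: one peaking
    ``latency_noise_s`` after the noise onset (t = 0) with amplitude
    ``a_noise`` and one peaking ``latency_word_s`` after the word onset with
    amplitude ``a_word``.
    """
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    if fs < 256:
        raise InvalidArgumentError("fs must be >= 256 Hz")
    required = set(FRONT_CENTRAL) | set(MASTOIDS)
    if not required.issubset(channel_names):
        raise ConfigurationError(
            f"channel set must include {sorted(required)}"
        )
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    times = t0_s + np.arange(n_samples) / fs

    evoked = _evoked_wavelet(times, profile.latency_noise_s, profile.a_noise)
    evoked = evoked + _evoked_wavelet(
        times, word_onset_s + profile.latency_word_s, profile.a_word
    )
    gains = np.array([CHANNEL_GAINS.get(c, 0.0) for c in channel_names])

    data = np.broadcast_to(
        gains[None, :, None] * evoked[None, None, :],
        (n_trials, len(channel_names), n_samples),
    ).copy()
    if profile.background_sd > 0:
        data += profile.background_sd * _pink_noise(
            rng, (n_trials, len(channel_names)), n_samples, fs
        )
    return EpochSet(data, fs=fs, t0_s=t0_s, channel_names=channel_names, condition=condition)


def gen_neural_profiles(
    n_participants: int,
    seed: int,
    *,
    snr_range_db: tuple[float, float] = (-4.0, 8.0),
    a_noise_mean: float = 5.0,
    a_noise_cv: float = 0.25,
    background_sd: float = 15.0,
) -> list[NeuralProfile]:
    """A cohort of neural profiles with true neural SNRs spread over a range.

    Noise-onset amplitudes are lognormal around ``a_noise_mean`` µV (a typical
    front-central onset-response scale); the word amplitude is set from a
    uniformly drawn true neural SNR.
    """
    rng = np.random.default_rng(seed)
    snrs = rng.uniform(*snr_range_db, size=n_participants)
    sigma = np.sqrt(np.log(1 + a_noise_cv**2))
    a_noise = a_noise_mean * np.exp(rng.normal(-sigma**2 / 2, sigma, size=n_participants))
    return [
        NeuralProfile(
            a_noise=float(an),
            a_word=float(an * 10 ** (s / 20.0)),
            background_sd=background_sd,
        )
        for an, s in zip(a_noise, snrs)
    ]


# ---------------------------------------------------------------------------
# subjective ratings


@dataclass(frozen=True)
class ClusterSpec:
    """Planted cluster structure in weighted-rating space.

    ``centroids`` is a (k, 3) array of mean weighted ratings per domain, each
    entry in [0, 10]; ``spread`` is the within-cluster SD of the latent
    weighted vector; ``proportions`` are the mixing weights.
    """

    centroids: np.ndarray
    spread: float = 1.0
    proportions: np.ndarray | None = None

    def __post_init__(self):
        cent = np.atleast_2d(np.asarray(self.centroids, float))
        if cent.shape[1] != 3:
            raise InvalidArgumentError("centroids must be k x 3")
        if np.any(cent < 0) or np.any(cent > 10):
            raise InvalidArgumentError("centroid entries must lie in [0, 10]")
        if self.spread < 0:
            raise InvalidArgumentError("spread must be nonnegative")
        props = self.proportions
        if props is None:
            props = np.full(len(cent), 1.0 / len(cent))
        props = np.asarray(props, float)
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("proportions must be nonnegative and sum to 1")
        object.__setattr__(self, "centroids", cent)
        object.__setattr__(self, "proportions", props)

    @property
    def k(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class RatingDataset:
    """Raw noise-tolerance task data plus the planted ground truth."""

    ratings: pd.DataFrame       # participant, sentence, domain, rating
    comparisons: pd.DataFrame   # participant, sentence, domain_a, domain_b, choice
    true_labels: np.ndarray
    latent: np.ndarray          # (n, 3) latent weighted-rating vectors


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _choice_probs(latent: np.ndarray, slope: float) -> dict:
    """P(first domain of the pair is chosen), logistic in the latent difference."""
    idx = {d: i for i, d in enumerate(DOMAINS)}
    return {
        (a, b): _sigmoid(slope * (latent[idx[a]] - latent[idx[b]]))
        for a, b in DOMAIN_PAIRS
    }


def _win_shares(probs: dict) -> np.ndarray:
    """Expected per-domain win proportion over its two pairs per sentence."""
    wins = dict.fromkeys(DOMAINS, 0.0)
    for (a, b), p in probs.items():
        wins[a] += p
        wins[b] += 1.0 - p
    return np.array([wins[d] / 2.0 for d in DOMAINS])


def gen_rating_dataset(
    spec: ClusterSpec,
    n_participants: int,
    n_sentences: int = 10,
    seed: int = 0,
    *,
    slope: float = 1.0,
    rating_sd: float = 1.0,
    derandomize: bool = False,
) -> RatingDataset:
    """Absolute ratings and paired comparisons with planted cluster structure.

    Each participant's latent weighted-rating vector is drawn from its
    cluster (centroid + ``spread`` × noise, clipped to [0, 10]). Pairwise
    choice probabilities are logistic in the latent domain difference with
    the given ``slope``; the implied mean absolute rating of a domain is the
    latent weighted rating divided by its expected win share, so that the
    weighted-rating statistic recovers the latent vector in expectation.

    With ``derandomize=True`` each pair's wins are allocated at their
    expected count instead of sampled, for noise-free limit checks.
    """
    if n_sentences < 1:
        raise InvalidArgumentError("n_sentences must be >= 1")
    if n_participants < spec.k:
        raise InvalidArgumentError("need at least one participant per cluster")
    rng = np.random.default_rng(seed)
    labels = rng.choice(spec.k, size=n_participants, p=spec.proportions)
    latent = spec.centroids[labels] + spec.spread * rng.standard_normal((n_participants, 3))
    latent = np.clip(latent, 0.0, 10.0)

    rating_rows, comparison_rows = [], []
    for pid in range(n_participants):
        probs = _choice_probs(latent[pid], slope)
        shares = _win_shares(probs)
        mean_rating = np.where(shares > 1e-12, latent[pid] / np.maximum(shares, 1e-12), 1.0)
        mean_rating = np.clip(mean_rating, 1.0, 10.0)
        for d, domain in enumerate(DOMAINS):
            vals = mean_rating[d] + rating_sd * rng.standard_normal(n_sentences)
            vals = np.clip(np.round(vals), 1, 10).astype(int)
            for s in range(n_sentences):
                rating_rows.append((pid, s, domain, vals[s]))
        for (a, b), p in probs.items():
            if derandomize:
                n_a = int(round(p * n_sentences))
                choices = [a] * n_a + [b] * (n_sentences - n_a)
            else:
                choices = np.where(rng.random(n_sentences) < p, a, b)
            for s in range(n_sentences):
                comparison_rows.append((pid, s, a, b, choices[s]))

    ratings = pd.DataFrame(rating_rows, columns=["participant", "sentence", "domain", "rating"])
    comparisons = pd.DataFrame(
        comparison_rows, columns=["participant", "sentence", "domain_a", "domain_b", "choice"]
    )
    return RatingDataset(ratings, comparisons, labels, latent)


# ---------------------------------------------------------------------------
# behavioral outcomes


@dataclass(frozen=True)
class OutcomeLink:
    """Linear-Gaussian link between neural SNR and behavioral outcomes.

    Target Pearson correlations (with the neural SNR) and means/SDs of the
    NR-off accuracy and the two NR-driven accuracy changes. ``noise_scale``
    scales the residual term; 0 gives deterministic (|r| = 1) outcomes.
    """

    rho_acc_nr_off: float = 0.54
    rho_d_acc_nr1: float = -0.34
    rho_d_acc_nr2: float = -0.39
    mean_acc_nr_off: float = 77.75
    sd_acc_nr_off: float = 7.39
    mean_d_acc_nr1: float = 2.55
    sd_d_acc_nr1: float = 7.0
    mean_d_acc_nr2: float = -4.24
    sd_d_acc_nr2: float = 7.0
    noise_scale: float = 1.0

    def __post_init__(self):
        for rho in (self.rho_acc_nr_off, self.rho_d_acc_nr1, self.rho_d_acc_nr2):
            if abs(rho) >= 1.0:
                raise InvalidArgumentError("target correlations must satisfy |rho| < 1")


def gen_outcomes(
    neural_snr_db,
    link: OutcomeLink = OutcomeLink(),
    seed: int = 0,
) -> pd.DataFrame:
    """Behavioral outcome table with planted neural-SNR correlations.

    ``neural_snr_db`` may be an array of per-participant values or a list of
    :class:`NeuralProfile` (their true values are used). Accuracies are
    generated by ``y = mean + sd * (rho * z + noise_scale * sqrt(1-rho^2) * eps)``
    with ``z`` the standardized neural SNR, then clipped to [0, 100]; the
    Δaccuracy columns are recomputed after clipping so they equal the stated
    differences exactly.
    """
    snr = np.array(
        [p.true_neural_snr_db if isinstance(p, NeuralProfile) else float(p) for p in neural_snr_db]
    )
    rng = np.random.default_rng(seed)
    sd = snr.std()
    z = (snr - snr.mean()) / sd if sd > 0 else np.zeros_like(snr)

    def draw(rho, mean, scale):
        eps = rng.standard_normal(len(snr))
        return mean + scale * (rho * z + link.noise_scale * np.sqrt(1 - rho**2) * eps)

    acc_off = np.clip(draw(link.rho_acc_nr_off, link.mean_acc_nr_off, link.sd_acc_nr_off), 0, 100)
    d1 = draw(link.rho_d_acc_nr1, link.mean_d_acc_nr1, link.sd_d_acc_nr1)
    d2 = draw(link.rho_d_acc_nr2, link.mean_d_acc_nr2, link.sd_d_acc_nr2)
    acc_nr1 = np.clip(acc_off + d1, 0, 100)
    acc_nr2 = np.clip(acc_off + d2, 0, 100)
    return pd.DataFrame(
        {
            "participant": np.arange(len(snr)),
            "acc_nr_off": acc_off,
            "acc_nr1": acc_nr1,
            "acc_nr2": acc_nr2,
            "d_acc_nr1": acc_nr1 - acc_off,
            "d_acc_nr2": acc_nr2 - acc_off,
            "neural_snr_db": snr,
        }
    )
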