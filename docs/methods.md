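# Methods

This note documents the models, parameter choices and numerical decisions
behind `nrlab`, and what the synthetic-data generators do and do not
emulate.

## Stimuli

A trial is 1.5 s of speech-shaped noise with a target word starting 0.5 s
after noise onset, mixed at a nominal SNR (0 dB by default) and RMS-
normalized. Two generator choices were open and are fixed as follows.

**Speech-shaped noise.** Gaussian noise shaped by a long-term-average-
speech-spectrum (LTASS) approximation: flat below 500 Hz, −9 dB/octave
above. The exact masker spectrum used in comparable experiments varies by
recording corpus; this two-parameter curve captures its defining features
(low-frequency plateau, steady high-frequency roll-off) and both parameters
are arguments of `gen_speech_shaped_noise`.

**Speech token.** `gen_target_token` stands in for recorded
consonant–vowel–consonant (CVC) words. It is a continuously voiced nucleus —
harmonic source with a 125→95 Hz f0 glide, formant peaks near 600/1400/2500
Hz, the same LTASS tilt, and a −18 dB breathiness floor so the spectrum is
not empty between and above the formants — overlaid with noise-like
consonant frication (band 1.5–10 kHz) at the token edges, about 5 dB below
the vowel, with 50 ms raised-cosine ramps. These numbers are phonetically
conventional (consonants are weaker than vowel nuclei; voiceless frication
concentrates between roughly 2 and 10 kHz). The token's long-term spectrum
therefore resembles the masker's, which is what makes the 0 dB mixing
condition meaningful per frequency band and not just broadband.

**Mixing convention.** The mixing SNR is defined over the noise samples that
temporally overlap the word, because the word occupies only a third of the
noise burst; the noise is scaled to the target ratio and the composite is
then normalized to a reference RMS, with the same scale applied to the
stored clean word and noise tracks so they still sum to the composite
exactly.

## Noise reduction

Both variants share the front end: 20 ms Hamming-windowed frames at 50%
hop, FFT size equal to the frame length, one-sided spectra; noise PSD fixed
as the mean periodogram of the frames inside the 0.5 s noise-only lead (the
masker is stationary, so no adaptive tracking); a posteriori SNR
`gamma = |Y|²/λ`, decision-directed a priori SNR with `alpha = 0.98` floored
at −25 dB, spectral gain floored at −25 dB, noisy phase kept, overlap-add
resynthesis with window-sum compensation, and one frame of odd-symmetric
reflection padding at each end so output length equals input length.

The MMSE gain is evaluated in the exponentially scaled Bessel form; above
`nu = 1e6` the code switches to the Wiener limit `xi/(1+xi)` because the
scaled Bessels lose accuracy there. The Log-MMSE gain
`xi/(1+xi)·exp(E1(nu)/2)` is clamped at 1: the raw estimator exceeds unity
when the a posteriori SNR is far below the a priori SNR, and amplification
is never wanted in this application. Note two limits that are easy to
mis-state: at fixed `gamma` the MMSE gain does *not* tend to 1 as `xi → ∞`
(it tends to the Rice mean at `nu = gamma`, e.g. ≈1.28 at `gamma = 1`); the
Wiener limit requires `nu → ∞`.

**A structural property worth knowing.** A gain applied to a noisy bin
multiplies its speech and noise content equally, so uniform extra
attenuation changes no within-bin SNR; broadband SNR enhancement comes only
from the *contrast* between speech-dominated and noise-dominated
time-frequency cells. With the floors above, the two variants' minimum
attenuation nearly coincides (≈ −26 vs −27.5 dB at the xi floor), so
Log-MMSE's measured SNR-enhancement advantage over MMSE on these stimuli is
real but small (~0.2–0.4 dB at the word segment) and can invert on
individual noise draws, while its distortion cost (lower coherence) is
consistent. Configurations without an a-priori-SNR floor differentiate the
variants more but are not the defaults here.

## NR-effect metrics

SNR enhancement uses the phase-inversion technique: the processor runs on
`s+n` and `s−n`; half-sum and half-difference of the outputs are the
post-NR speech and noise components, and the enhancement is the post-minus-
pre RMS SNR over the word-overlap segment (the segment is configurable; the
whole-stimulus alternative includes a second of noise-only material and
roughly doubles the numbers). Distortion is the Welch magnitude-squared
coherence (Hann, nperseg 1024, 50% overlap, ≥8 segments enforced) between
the clean word track and the phase-inversion speech component, averaged
unweighted over 0 < f ≤ 22 kHz. Where the clean token has little energy the
coherence of the extracted component is intrinsically low, so this average
depends visibly on the token's spectral reach — one reason distortion
numbers for recorded words and synthetic tokens need not coincide.

## EEG pipeline and neural SNR

Epochs span −0.5 to 2.5 s around noise onset, 7 channels (Fz, FCz, FC1,
FC2, Cz and two mastoids), 1024 Hz by default (configurable to 4096 Hz; the
analysis is band-limited far below either Nyquist). The fixed pipeline is:
1–50 Hz two-pass zero-phase windowed-sinc FIR (the two passes collapse into
one convolution with the taps' self-convolution; odd-symmetric reflection
padding avoids artificial edge discontinuities), mastoid re-referencing,
−200–0 ms baseline correction, polyphase resampling to 256 Hz
(`padtype="line"` so constant offsets survive), and averaging over trials
then over the five front-central channels. Filter transitions are widened
to the length the filter can realize (`3.3·fs/numtaps`) — sharper
specifications only buy Gibbs ripple in the passband. An artifact-removal
hook exists and is a pass-through: ocular-artifact rejection in real
recordings is a manual, topography-guided step, and synthetic epochs
contain none.

The neural SNR of the NR-off ERP is `20·log10(peak_word/peak_noise)` of the
2–7 Hz Hilbert envelope, peaks taken over closed windows 0.05–0.25 s after
noise onset and 0.10–0.40 s after word onset. `20·log10` (not `10·`) because
envelope amplitudes, not powers, are compared. The envelope filter is
deliberately short (≈1.5 s of taps): a longer filter's time-domain ringing
carries the (larger) word response into the noise window and biases the
ratio. Scale invariance and monotonicity in the word amplitude are tested
properties.

## Synthetic EEG

Each trial is i.i.d. 1/f-amplitude background noise (std `background_sd`,
default 15 µV broadband — a typical single-trial EEG scale) on every channel
plus two deterministic evoked bursts on the front-central channels: Hann-
windowed 4.5 Hz cosines (0.3 s long, centered in the 2–7 Hz analysis band so
the envelope peak equals the programmed amplitude), peaking 0.15 s after
noise onset and 0.25 s after word onset. Mastoids carry background but no
evoked signal, so re-referencing adds noise without disturbing the evoked
amplitudes. Cohorts draw the noise-onset amplitude lognormally around 5 µV
(a typical front-central onset-response envelope) and the true neural SNR
uniformly over −4…+8 dB. What this generator does *not* emulate: spatially
correlated background across channels, alpha rhythms, latency jitter across
trials, or ocular artifacts — so passing recovery tests demonstrate the
estimator's correctness and its behavior under additive 1/f noise, not
robustness to every property of real recordings.

## Ratings and profiling

The latent participant variable is the 3-vector of *weighted ratings*
(noise annoyance, speech interference, listening effort), each in [0, 10].
Cluster structure is planted directly in that space. Paired-comparison
choices are logistic in the latent domain difference (slope 1 by default);
each domain's implied mean absolute rating is the latent weighted rating
divided by its expected win share, so the weighted-rating statistic
(mean rating × wins/appearances, 2 appearances per sentence) recovers the
latent vector in expectation. A `derandomize` option allocates pair wins at
their expected counts for noise-free limit checks; exact centroid
reproduction then holds when the implied ratings are integers. Absolute
ratings are rounded and clipped to the 1–10 integer scale, which at the
scale edges introduces a small bias the tests avoid by using interior
centroids.

Clustering runs on the raw weighted ratings without standardization (all
three domains already share the 0–10 scale), k-means++ with 50 restarts and
a fixed seed; labels are reordered by descending noise-annoyance centroid.
The adjustment rule mirrors the study procedure: start at the elbow
suggestion capped at 3 (or an explicit `start_k`), require every pairwise
group comparison (Tukey HSD after one-way ANOVA) to be significant at
α = 0.05 in every domain, drop k by one otherwise, recompute the silhouette
at each k, and validate a final two-cluster solution with per-domain Welch
t-tests. The elbow is advisory; it is flagged "clear" only when the
suggested k removes most of the improvable within-cluster sum of squares
(residual < 25% of the k-min value), which a single Gaussian blob fails.

## Outcome statistics

The outcome table holds per-participant accuracies for NR-off/NR-1/NR-2 and
the two NR-driven accuracy changes. The battery: one-way repeated-measures
ANOVA (uncorrected df `(c−1, (c−1)(n−1))`; a sphericity correction is out of
scope), paired t-tests with ×3 Bonferroni adjustment, Pearson correlations,
Welch two-sample t-tests (fractional Welch–Satterthwaite df — the natural
choice whenever group variances are not assumed equal), and step-down
Holm–Bonferroni correction across the three outcome measures in the
cluster comparison; the neural-SNR cluster test is reported uncorrected.
`compare_clusters` reports statistics and the corrections applied but
encodes no significance verdict for the corrected family. Degenerate inputs
are defined rather than propagated as 0/0: identical paired vectors give
t = 0, p = 1, and a design with no within-subject variation gives F = 0.

The outcome generator links accuracies to the neural SNR through
`y = mean + sd·(ρ·z + noise·sqrt(1−ρ²)·ε)` with `z` the standardized neural
SNR, then clips to [0, 100] and recomputes the change columns so they stay
exact differences. Default targets: ρ = 0.54 with NR-off accuracy and
−0.34/−0.39 with the NR-1/NR-2 accuracy changes; means/SDs 77.75/7.39
(NR off), change means +2.55 and −4.24. The SDs of the change scores are
not separately constrained by the reference design and default to 7.0,
consistent with the per-condition SDs of ≈7.4–8.0.

## Problem sizes

The test suite validates parameter recovery on a 30-participant cohort with
165 trials each at 1024 Hz (the full per-participant trial count of the
study design), NR metrics on 20 seeded stimuli at 44.1 kHz, and profiling
on cohorts of 24–42 participants; these sizes keep the whole suite
reproducible on a single CPU in a few minutes while leaving every estimator
at its intended operating point.

## Known limitations

* The NR-effect numbers depend on the synthetic token's spectro-temporal
  balance; recorded CVC words will shift them (the distortion average most
  of all, see above).
* With the default floors the two NR variants' per-seed SNR-enhancement
  ordering is not strict — only their central tendency and the distortion
  ordering are.
* The EEG generator's independence assumptions (channels, trials) make
  trial averaging slightly more effective than in real recordings.
* No raw-EEG-format ingestion, no artifact rejection heuristics, no
  perceptual audio metrics (PESQ/STOI), and no alternative clustering
  families — each is outside the package's scope.
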