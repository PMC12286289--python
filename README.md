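# nrlab

Tools for studying how single-channel noise reduction (NR) interacts with
individual differences in speech-in-noise listening. The package implements,
as a tested and reusable library, the computational chain of an auditory
neuroscience study design in which listeners hear monosyllabic words in
speech-shaped noise at 0 dB SNR under three conditions (NR off and two NR
algorithms), while EEG is recorded and subjective noise-tolerance ratings are
collected:

1. **Stimulus construction** — synthetic speech-like tokens and LTASS-shaped
   noise, mixed at a stated SNR and RMS-normalized (`nrlab.audio`).
2. **Noise reduction** — the two Ephraim–Malah short-time spectral-amplitude
   estimators: MMSE ("NR 1", mild) and Log-MMSE ("NR 2", strong), with
   Hamming-windowed 20 ms frames, a decision-directed a priori SNR and a
   noise PSD taken from the noise-only stimulus lead (`nrlab.enhance`).
3. **Objective NR metrics** — SNR enhancement via the phase-inversion
   technique and speech distortion via magnitude-squared coherence
   (`nrlab.metrics`).
4. **EEG / ERP pipeline** — zero-phase FIR bandpass, mastoid re-referencing,
   baseline correction, downsampling, front-central averaging
   (`nrlab.eeg`).
5. **Neural SNR** — `20·log10(peak_word / peak_noise)` of the 2–7 Hz Hilbert
   envelope of the NR-off ERP, with peaks taken 100–400 ms after word onset
   and 50–250 ms after noise onset (`nrlab.neural`).
6. **Noise-tolerance profiling** — weighted domain ratings (mean absolute
   rating × paired-comparison win share) and k-means subgrouping with an
   elbow start, an all-pairwise-significance adjustment rule and silhouette
   validation (`nrlab.profiles`).
7. **Outcome statistics** — repeated-measures ANOVA, Bonferroni-corrected
   paired post hocs, Pearson correlations with the neural SNR, and Welch
   two-sample cluster comparisons with Holm–Bonferroni correction
   (`nrlab.stats`).

A synthetic-data module (`nrlab.simulate`) generates EEG epochs, rating
datasets and behavioral outcomes with planted ground truth, so the entire
chain runs and is validated end-to-end without any recorded data.

## Worked example

```sh
python examples/01_noise_reduction_effects.py
```

```
stimulus: 1.5 s, word at +0.5 s, mixed at 0 dB SNR
NR 1 (MMSE, mild): SNR enhancement +4.09 dB, mean coherence 0.600
NR 2 (Log-MMSE, strong): SNR enhancement +4.91 dB, mean coherence 0.536
```

The MMSE variant improves the word-segment SNR by ~4 dB while keeping the
processed speech component fairly coherent with the clean word (0.60); the
Log-MMSE variant removes more noise at the cost of more spectral distortion
(lower coherence). The other example scripts walk through neural-SNR
extraction from simulated EEG (`02`), noise-tolerance profiling with the
3 → 2 cluster adjustment (`03`), and the cohort-level statistics (`04`);
each prints the quantities it computes together with a one-line reading.

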