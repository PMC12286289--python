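"""Extract the neural SNR from simulated EEG of one participant.

Simulates 165 speech-in-noise trials with known evoked amplitudes to the
noise onset (5 µV) and word onset (7 µV) in realistic 1/f background EEG,
runs the ERP pipeline (1-50 Hz zero-phase bandpass, mastoid re-reference,
baseline correction, downsampling to 256 Hz, front-central average), and
compares the estimated neural SNR against the programmed ground truth.
"""

from nrlab.eeg import preprocess
from nrlab.neural import compute_neural_snr
from nrlab.simulate import NeuralProfile, gen_eeg_epochs

profile = NeuralProfile(a_noise=5.0, a_word=7.0, background_sd=15.0)
epochs = gen_eeg_epochs(profile, n_trials=165, seed=5)
erp = preprocess(epochs)
result = compute_neural_snr(erp, word_onset_s=0.5)

print(f"envelope peak after noise onset  ({result.noise_window} s): {result.peak_noise:.2f} uV")
print(f"envelope peak after word onset   ({result.word_window} s): {result.peak_word:.2f} uV")
print(f"estimated neural SNR: {result.neural_snr_db:+.2f} dB "
      f"(programmed: {profile.true_neural_snr_db:+.2f} dB)")
print("Positive values mean the cortex responds more strongly to the word "
      "than to the noise onset - more efficient speech-vs-noise encoding.")
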