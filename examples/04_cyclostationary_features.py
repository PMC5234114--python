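"""Cyclic spectral density and NMF compression of a breathing minute.

Amplitude modulation at the breath rate puts mass at cyclic frequency
alpha = 1/period; stationary noise keeps all its mass at alpha = 0. The mean
CSD grid is compressed through a rank-45 NMF into 693 statistics.
"""

import numpy as np

from osasev import (
    AudioSignal,
    cyclic_spectral_density,
    fit_shared_basis,
    otsu_mask,
    project_activations,
    subject_running_mean,
    summarize_statistics,
)

rate = 8000
t = np.arange(rate * 120) / rate
rng = np.random.default_rng(0)
x = (1 + np.cos(2 * np.pi * t / 4.0)) * rng.standard_normal(len(t)) * 0.2
signal = AudioSignal(np.clip(x, -1, 1), rate)

grid = cyclic_spectral_density(AudioSignal(signal.samples[: rate * 60], rate))
pos = grid.alpha_grid > 0
marginal = grid.magnitudes[:, pos].sum(axis=0)
print(f"CSD grid {grid.magnitudes.shape}; "
      f"strongest cyclic frequency {grid.alpha_grid[pos][np.argmax(marginal)]:.3f} Hz "
      "(breath rate 0.25 Hz)")

rms = subject_running_mean(signal)
masked = otsu_mask(rms.rms)
print(f"running mean over {rms.k} windows; Otsu threshold {masked.threshold:.2e} "
      f"zeroes {(masked.masked == 0).mean():.2%} of entries")

basis = fit_shared_basis([masked.masked], rank=45, seed=0)
H = project_activations(basis, masked.masked)
feats = summarize_statistics(H)
print(f"activation matrix {H.H.shape} -> {len(feats)} statistics")
print(f"  e.g. c_alpha_f_max_1 = {feats['c_alpha_f_max_1']:.4g}, "
      f"c_f_alpha_kurtosis_2 = {feats['c_f_alpha_kurtosis_2']:.4g}")
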