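"""Decompose a two-tone trivariate signal with NA-MEMD.

A 2 Hz and a 20 Hz tone (more than three octaves apart) are mixed on three
variates.  The decomposition should place each tone in its own intrinsic
mode function, reconstruct the input exactly, and order the modes from
fast to slow.
"""

import numpy as np

from neoprog import SiftConfig, na_memd
from scipy.signal import periodogram

fs = 256.0
t = np.arange(1024) / fs
x = np.vstack(
    [np.sin(2 * np.pi * 2 * t + p) + 0.7 * np.sin(2 * np.pi * 20 * t + 2 * p)
     for p in (0.0, 1.0, 2.0)]
)

imfs, residue = na_memd(x, SiftConfig(seed=0))
recon_err = np.abs(sum(imfs) + residue - x).max() / np.abs(x).max()
print(f"{len(imfs)} modes extracted; reconstruction error {recon_err:.2e}")

for k, imf in enumerate(imfs):
    freqs, psd = periodogram(imf, fs=fs, axis=-1)
    pooled = psd.mean(axis=0)
    centroid = (freqs * pooled).sum() / pooled.sum()
    c2 = abs(np.corrcoef(imf[0], np.sin(2 * np.pi * 2 * t))[0, 1])
    c20 = abs(np.corrcoef(imf[0], np.sin(2 * np.pi * 20 * t))[0, 1])
    print(f"mode {k}: centroid {centroid:5.1f} Hz | corr with 2 Hz tone "
          f"{c2:.2f}, with 20 Hz tone {c20:.2f}")

print("\nEach planted tone should dominate exactly one mode (correlation "
      "near 1), with centroids decreasing mode by mode.")
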