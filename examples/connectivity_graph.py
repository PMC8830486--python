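"""Phase-coupling recovery: WPLI matrix and global graph metrics.

Channel T3 receives C3's narrowband carrier shifted by a quarter cycle;
O1 carries independent band noise.  The weighted phase-lag index of the
coupled pair should approach 1 while independent pairs stay near the
estimator's noise floor, and the graph metrics summarize the resulting
weighted network.
"""

import numpy as np
from scipy.signal import butter, filtfilt

from neoprog import analytic_signal, graph_metrics, wpli_matrix

rng = np.random.default_rng(0)
fs, n_epochs, n_samp = 256.0, 30, 512
b, a = butter(4, [8 / 128.0, 20 / 128.0], btype="band")
carrier = filtfilt(b, a, rng.standard_normal(n_epochs * n_samp))
shifted = np.real(analytic_signal(carrier) * np.exp(-1j * np.pi / 2))
independent = filtfilt(b, a, rng.standard_normal(n_epochs * n_samp))

epochs = np.stack([carrier, shifted, independent]).reshape(3, n_epochs, n_samp)
w = wpli_matrix(epochs, ["C3", "T3", "O1"])

print("epoch-averaged WPLI matrix (30 x 2-s epochs):")
for lab, row in zip(w.channel_labels, w.values):
    print(f"  {lab}: " + "  ".join(f"{v:.3f}" for v in row))

metrics = graph_metrics(w)
print("\nglobal graph metrics (lengths = 1/weight):")
for name, value in metrics.as_dict().items():
    print(f"  {name:28s} {value:.3f}")

print("\nWPLI(C3,T3) near 1 reflects the planted quarter-cycle lag; the "
      "other entries show the finite-sample floor of the per-epoch "
      "estimator for independent narrowband signals.")
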