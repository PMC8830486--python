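"""Generate a small synthetic EEG cohort and inspect its planted structure.

Builds 8 subjects x 3 channels at 64 Hz with a delta-band regularity
gradient on C3 coupled to cognitive-composite scores, then prints the
scores next to the planted per-subject feature.  The final line reports
the planted population correlation the score model encodes.
"""

import numpy as np

from neoprog import demo_profile
from neoprog.synthetic import generate_cohort

cohort = generate_cohort(demo_profile(seed=1).cohort)

print("subject    score   planted delta-SpEn")
for rec in cohort.recordings:
    feature = cohort.ground_truth["feature_values"][rec.subject_id]
    score = cohort.scores[rec.subject_id]
    print(f"{rec.subject_id}   {score:6.1f}   {feature:.3f}")

r = np.corrcoef(
    list(cohort.ground_truth["feature_values"].values()), cohort.scores
)[0, 1]
print(f"\nplanted population rho = {cohort.ground_truth['planted_rho']:.2f}; "
      f"realized sample r = {r:.2f} (n = {len(cohort.scores)})")
print("Scores sit on the 74-145 cognitive-composite scale; the feature is the "
      "spectral entropy of each subject's delta-band component.")
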