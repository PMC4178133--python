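"""Build a population-average FDG-PET template by recursive register-average.

Six phantom subjects (shared anatomy, individual geometric variability and
noise) are registered to the current target, averaged, and the loop repeats
until the relative mean squared residual between successive targets drops
below 5%.  The resulting average resembles the common anatomy better than
any single noisy subject does.
"""

import numpy as np

from ratpet import PhantomSpec, build_average_template, make_ground_truth
from ratpet.phantom import make_subject

spec = PhantomSpec(dims=(40, 32, 26))
gt = make_ground_truth(spec)
scans = [make_subject(gt, spec, subject_seed=100 + i).volume for i in range(6)]

template, trace = build_average_template(scans, initial_index=0, threshold=0.05, cutoff=3)

print("iteration   d (intensity^2)   rel")
for rec in trace:
    print(f"{rec.iteration:9d}   {rec.d:15.4f}   {rec.rel:.4f}")

corr_template = np.corrcoef(template.data.ravel(), gt.pet.data.ravel())[0, 1]
corr_best_subject = max(
    np.corrcoef(s.data.ravel(), gt.pet.data.ravel())[0, 1] for s in scans
)
print(f"\ncorrelation with ground truth: template {corr_template:.4f} "
      f"vs best single subject {corr_best_subject:.4f}")
print("rel < 0.05 stops the loop; d is the raw mean squared residual difference.")
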