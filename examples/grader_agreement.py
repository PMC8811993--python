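"""Inter-grader agreement of the leakage scores, measured by ICC(2,1).

The only manual step of the pipeline is picking the foveal centre, so two
graders produce slightly different scores.  This example simulates a
cohort's true scores, adds independent grader noise calibrated to a target
agreement, and shows the two-way random-effects absolute-agreement ICC
recovering it.
"""

import numpy as np

from faleak import generate_grader_pair, grader_noise_for_icc, icc_agreement

rng = np.random.default_rng(4)
subject_sd = 15.1  # between-eye spread of the perifoveal score
truth = np.maximum(rng.normal(23.3, subject_sd, 89), 0.0)

for target in (0.95, 0.90, 0.75):
    noise_sd = grader_noise_for_icc(subject_sd, target)
    est = np.mean([
        icc_agreement(*generate_grader_pair(truth, noise_sd, rng))
        for _ in range(200)
    ])
    print(f"grader noise sd {noise_sd:5.2f} -> target ICC {target:.2f}, "
          f"estimated {est:.3f} (mean of 200 replicates, n = 89 eyes)")

print("\nICC near 1 means the semi-automated scores barely depend on which")
print("grader picked the fovea; the study-level agreement (~0.92-0.97)")
print("corresponds to a grader noise of only a few gray levels.")
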