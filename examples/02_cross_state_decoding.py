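"""Cross-state decoding: train LDA on sleep, test on wake, cluster statistics.

Generates an 8-participant cohort with planted same-timebase reactivation,
runs the smoothing + sleep-PCA + timepoints-as-observations LDA pipeline per
participant, and tests the group of wake CCR time courses against the 0.25
chance level with a cluster-based sign-flip permutation test.
"""

import numpy as np

from tmrdecode import (
    CohortConfig,
    cluster_permutation_vs_chance,
    decode_participant,
    generate_cohort,
)

cohort = generate_cohort(CohortConfig(), n_participants=8, master_seed=3)
timecourses = [
    decode_participant(rec.sleep, rec.wake, participant_id=i)
    for i, rec in enumerate(cohort)
]

for tc in timecourses:
    t_peak = tc.times[np.argmax(tc.ccr)]
    print(f"participant {tc.participant_id}: max CCR {tc.max_ccr:.2f} "
          f"at {t_peak * 1000:.0f} ms after the wake cue")

res = cluster_permutation_vs_chance(timecourses, n_permutations=2000, seed=0)
print(f"\ncluster test vs chance 0.25 ({res.n_permutations} permutations):")
for (a, b), mass, p in zip(res.clusters, res.masses, res.p_values):
    t0, t1 = timecourses[0].times[a], timecourses[0].times[b - 1]
    print(f"  cluster {t0 * 1000:.0f}-{t1 * 1000:.0f} ms, mass {mass:.1f}, p = {p:.4f}")
print("a cluster p below 0.05 means reactivation decoded above chance over "
      "that stretch of the wake trial")
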