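"""Behavior linkage: does decoding strength predict the cueing benefit?

Generates a cohort whose reactivation SNR varies across participants and
whose cued-sequence reaction times improve in proportion, then scores peak
performance (median of the fastest 5% of blocks), tests cued vs uncued
improvement, and correlates each participant's maximum CCR with their
cueing benefit (with an encoding-RT partial correlation).
"""

from tmrdecode import CohortConfig, decode_participant, generate_cohort
from tmrdecode.behavior import (
    cueing_benefit,
    cueing_test,
    improvement,
    reactivation_benefit_correlation,
)

cfg = CohortConfig(snr_range=(0.2, 1.5))
cohort = generate_cohort(cfg, n_participants=14, master_seed=6)

max_ccr, benefit, encoding, pairs = [], [], [], []
for rec in cohort:
    pid = rec.truth.participant_id
    max_ccr.append(decode_participant(rec.sleep, rec.wake).max_ccr)
    benefit.append(cueing_benefit(rec.behavior, pid))
    cued = improvement(rec.behavior, pid, "cued")
    uncued = improvement(rec.behavior, pid, "uncued")
    encoding.append(cued.pre_score_ms)
    pairs.append((cued, uncued))

wil = cueing_test(pairs)
print(f"cued vs uncued improvement: z = {wil.z:.2f}, p = {wil.p_value:.4f} "
      f"(n = {wil.n_used})")

corr = reactivation_benefit_correlation(max_ccr, benefit, encoding)
print(f"Spearman(max CCR, 24h cueing benefit): r = {corr['spearman_r']:.2f}, "
      f"p = {corr['spearman_p']:.4f}")
print(f"partial (controlling encoding RT):     r = {corr['partial_r']:.2f}, "
      f"p = {corr['partial_p']:.4f}")
print("\npositive r: participants whose reactivation decodes more strongly "
      "gained more from cueing")
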