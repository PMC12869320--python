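"""Behavioral consolidation scoring and its linkage to decoded reactivation.

Reaction-time tables hold one row per (participant, session, sequence,
block).  A session's score is the median of its fastest 5% of blocks (peak
performance estimates motor consolidation better than the mean); improvement
is pre-sleep minus post-sleep score, and the cueing benefit is the post-sleep
uncued-minus-cued reaction time.  Group tests: a signed-rank comparison of
cued versus uncued improvement, and Spearman (plus rank-based partial)
correlation between each participant's maximum decoding CCR and their
cueing benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import SignedRankResult, partial_spearman, signed_rank_test, spearman

__all__ = [
    "ImprovementSummary",
    "best_percentile_score",
    "improvement",
    "cueing_benefit",
    "cueing_test",
    "reactivation_benefit_correlation",
]

PRE_SESSION = "pre"
POST_SESSIONS = ("24h", "10d", "6-8w")
#: The follow-up used for the headline reactivation-benefit correlation:
#: the first session after the stimulation night.
BENEFIT_SESSION = "24h"

REQUIRED_COLUMNS = ("participant", "session", "sequence", "block", "rt_ms")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    if (table["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")


def best_percentile_score(
    blocks: np.ndarray, keep_fraction: float = 0.05, min_blocks: int = 20
) -> float:
    """Median of the fastest ``keep_fraction`` of block reaction times.

    ``ceil(keep_fraction * n)`` fastest blocks are kept, so 24 blocks keep
    two and the score is their midpoint.
    """
    rts = np.asarray(blocks, dtype=float)
    if rts.size < min_blocks:
        raise ValueError(f"need at least {min_blocks} blocks, got {rts.size}")
    k = math.ceil(keep_fraction * rts.size)
    fastest = np.sort(rts)[:k]
    return float(np.median(fastest))


@dataclass
class ImprovementSummary:
    """Pre/post peak-performance scores for one participant and sequence."""

    participant: int
    sequence: str
    pre_score_ms: float
    post_score_ms: float  # median over post-sleep session scores

    @property
    def improvement_ms(self) -> float:
        """pre - post: positive values mean the participant got faster."""
        return self.pre_score_ms - self.post_score_ms


def improvement(
    table: pd.DataFrame,
    participant: int,
    sequence: str,
    keep_fraction: float = 0.05,
) -> ImprovementSummary:
    """Peak-performance improvement for one participant and sequence.

    Each session is scored separately with :func:`best_percentile_score`
    (keeping per-session balance); the post-sleep score is the median of the
    per-session scores across the three follow-ups.
    """
    _check_table(table)
    sub = table[(table["participant"] == participant) & (table["sequence"] == sequence)]
    have = set(sub["session"])
    missing = [s for s in (PRE_SESSION, *POST_SESSIONS) if s not in have]
    if PRE_SESSION in missing or len(missing) == len(POST_SESSIONS):
        raise ValueError(f"missing sessions for scoring: {missing}")
    pre = best_percentile_score(
        sub.loc[sub["session"] == PRE_SESSION, "rt_ms"].to_numpy(), keep_fraction
    )
    post_scores = [
        best_percentile_score(
            sub.loc[sub["session"] == s, "rt_ms"].to_numpy(), keep_fraction
        )
        for s in POST_SESSIONS
        if s in have
    ]
    return ImprovementSummary(
        participant=participant,
        sequence=sequence,
        pre_score_ms=pre,
        post_score_ms=float(np.median(post_scores)),
    )


def cueing_benefit(
    table: pd.DataFrame,
    participant: int,
    session: str = BENEFIT_SESSION,
    keep_fraction: float = 0.05,
) -> float:
    """Uncued minus cued peak reaction time in one post-sleep session
    (positive values mean the cued sequence was faster)."""
    _check_table(table)
    sub = table[(table["participant"] == participant) & (table["session"] == session)]
    scores = {}
    for seq in ("cued", "uncued"):
        rts = sub.loc[sub["sequence"] == seq, "rt_ms"].to_numpy()
        if rts.size == 0:
            raise ValueError(f"no {seq} blocks for participant {participant}")
        scores[seq] = best_percentile_score(rts, keep_fraction)
    return scores["uncued"] - scores["cued"]


def cueing_test(
    summaries: list[tuple[ImprovementSummary, ImprovementSummary]],
) -> SignedRankResult:
    """Two-sided signed-rank test of cued-minus-uncued improvement.

    ``summaries`` pairs each participant's cued and uncued summaries.
    Positive z means the cued sequence improved more.
    """
    if len(summaries) < 6:
        raise ValueError("need at least 6 participants")
    diffs = []
    for cued, uncued in summaries:
        if cued.sequence != "cued" or uncued.sequence != "uncued":
            raise ValueError("each pair must be (cued, uncued)")
        diffs.append(cued.improvement_ms - uncued.improvement_ms)
    return signed_rank_test(np.array(diffs), alternative="two-sided")


def reactivation_benefit_correlation(
    max_ccr: np.ndarray,
    benefit_ms: np.ndarray,
    encoding_rt_ms: np.ndarray,
) -> dict[str, float]:
    """Spearman correlation of per-participant maximum CCR with cueing
    benefit, plus a rank-based partial correlation controlling for the
    pre-sleep (encoding) reaction-time score."""
    max_ccr = np.asarray(max_ccr, float)
    benefit_ms = np.asarray(benefit_ms, float)
    encoding_rt_ms = np.asarray(encoding_rt_ms, float)
    if max_ccr.size < 10:
        raise ValueError("need at least 10 participants")
    r, p = spearman(max_ccr, benefit_ms)
    pr, pp = partial_spearman(max_ccr, benefit_ms, encoding_rt_ms)
    return {"spearman_r": r, "spearman_p": p, "partial_r": pr, "partial_p": pp}
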