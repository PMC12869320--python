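"""Sigma-power gating of reactivation decoding.

Post-cue spindle-band activity is scored per sleep trial as the mean
instantaneous 11-16 Hz Hilbert power at Cz over the first 2.5 s after the
cue.  Trials are median-split within participant into high- and low-sigma
halves, a separate decoder is trained on each half and applied to all wake
data, and the two CCR time courses are compared: high-half versus the 0.25
chance level, and high versus low with a paired cluster permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .decoding import CCRTimecourse, decode_participant
from .epochs import CLASSES, EpochSet
from .stats import ClusterResult, cluster_permutation_onesample

__all__ = ["SigmaScore", "sigma_power", "split_decode", "split_decode_group"]


@dataclass
class SigmaScore:
    """Per-trial sigma power scores and the within-participant median split."""

    power: np.ndarray  # mean instantaneous power per trial (signal units^2)
    median: float
    high: np.ndarray  # bool per trial
    channel: str
    band: tuple[float, float]
    window: tuple[float, float]


def _median_split(power: np.ndarray) -> np.ndarray:
    """Balanced high/low split: sort ascending (stable), the upper half is
    'high'.  Trials exactly at the median fall to the low group; the split
    sizes never differ by more than one, even with ties."""
    n = power.size
    order = np.argsort(power, kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[(n + 1) // 2 :]] = True
    return high


def sigma_power(
    sleep: EpochSet,
    channel: str = "Cz",
    band: tuple[float, float] = (11.0, 16.0),
    window: tuple[float, float] = (0.0, 2.5),
    edge_s: float = 0.1,
) -> SigmaScore:
    """Mean post-cue sigma power per trial at one channel.

    Each trial's channel signal is band-pass filtered (zero-phase Butterworth
    order 4), the analytic signal is taken with the Hilbert transform, and
    instantaneous power (squared magnitude) is averaged over ``window``.
    ``edge_s`` seconds at each end of the filtered segment are excluded from
    the average so filter/Hilbert edge artifacts do not leak into scores.
    """
    if channel not in sleep.channel_names:
        raise ValueError(f"channel {channel} not present")
    ci = sleep.channel_names.index(channel)
    rate = sleep.rate
    if np.any(sleep.lengths_s < window[1]):
        raise ValueError("a trial is shorter than the scoring window")
    sos = sig.butter(4, band, btype="bandpass", fs=rate, output="sos")
    power = np.zeros(sleep.n_trials)
    for i, trial in enumerate(sleep.trials):
        x = trial[ci]
        filt = sig.sosfiltfilt(sos, x)
        inst = np.abs(sig.hilbert(filt)) ** 2
        t = sleep.times(i)
        lo = max(window[0], t[0] + edge_s)
        hi = min(window[1], t[-1] - edge_s)
        mask = (t >= lo) & (t <= hi)
        power[i] = inst[mask].mean()
    return SigmaScore(
        power=power,
        median=float(np.median(power)),
        high=_median_split(power),
        channel=channel,
        band=band,
        window=window,
    )


def _half_usable(sleep: EpochSet, mask: np.ndarray) -> bool:
    labels = sleep.labels[mask]
    return all(np.sum(labels == c) >= 2 for c in CLASSES)


def split_decode(
    sleep: EpochSet,
    wake: EpochSet,
    scores: SigmaScore,
    explained: float = 0.95,
    smooth_ms: float | None = 100.0,
    participant_id: int | None = None,
) -> tuple[CCRTimecourse, CCRTimecourse]:
    """Train separate decoders on the high- and low-sigma halves and apply
    both to all wake trials of the participant.

    Raises ``ValueError`` if either half lacks two trials of some class (the
    caller should exclude such participants).
    """
    for name, mask in (("high", scores.high), ("low", ~scores.high)):
        if not _half_usable(sleep, mask):
            raise ValueError(f"{name}-sigma half is missing a class")
    high_tc = decode_participant(
        sleep.subset(np.flatnonzero(scores.high)),
        wake,
        explained=explained,
        smooth_ms=smooth_ms,
        participant_id=participant_id,
    )
    low_tc = decode_participant(
        sleep.subset(np.flatnonzero(~scores.high)),
        wake,
        explained=explained,
        smooth_ms=smooth_ms,
        participant_id=participant_id,
    )
    return high_tc, low_tc


@dataclass
class SplitDecodeGroupResult:
    """Group-level outcome of the sigma median-split analysis."""

    high: list[CCRTimecourse]
    low: list[CCRTimecourse]
    high_vs_chance: ClusterResult
    low_vs_chance: ClusterResult
    high_vs_low: ClusterResult  # paired (sign-flip on high-low differences)
    excluded: list[int]  # participant ids skipped for missing classes


def split_decode_group(
    participants: list[tuple[EpochSet, EpochSet]],
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = 0,
    explained: float = 0.95,
    smooth_ms: float | None = 100.0,
) -> SplitDecodeGroupResult:
    """Run the sigma median-split decoding over a cohort and test the high
    half against chance and against the low half (paired)."""
    highs, lows, excluded = [], [], []
    for pid, (sleep, wake) in enumerate(participants):
        scores = sigma_power(sleep)
        try:
            h, lo = split_decode(
                sleep, wake, scores, explained=explained,
                smooth_ms=smooth_ms, participant_id=pid,
            )
        except ValueError:
            excluded.append(pid)
            continue
        highs.append(h)
        lows.append(lo)
    if len(highs) < 5:
        raise ValueError("fewer than 5 usable participants after exclusions")
    dev_high = np.array([tc.ccr - tc.chance for tc in highs])
    dev_low = np.array([tc.ccr - tc.chance for tc in lows])
    kw = dict(
        alpha_sample=alpha_sample,
        alpha_cluster=alpha_cluster,
        n_permutations=n_permutations,
    )
    return SplitDecodeGroupResult(
        high=highs,
        low=lows,
        high_vs_chance=cluster_permutation_onesample(dev_high, seed=seed, **kw),
        low_vs_chance=cluster_permutation_onesample(dev_low, seed=seed, **kw),
        high_vs_low=cluster_permutation_onesample(dev_high - dev_low, seed=seed, **kw),
        excluded=excluded,
    )
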