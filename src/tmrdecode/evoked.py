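"""Cue-locked quality-control analyses: time-frequency power change and ERP.

Before any decoding it is worth confirming that the cues evoke a brain
response at all: a Morlet-wavelet time-frequency map expressed as percent
power change from a pre-cue baseline ([-0.3, -0.1] s), and the cue-locked
ERP (trial-average, baseline-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

__all__ = ["TFRMap", "tfr_percent_change", "erp_average"]

BASELINE = (-0.3, -0.1)


@dataclass
class TFRMap:
    """Percent power change from baseline, frequencies x times."""

    freqs: np.ndarray
    times: np.ndarray  # seconds relative to cue
    percent_change: np.ndarray  # (n_freqs, n_times)
    baseline: tuple[float, float] = BASELINE


def _equal_length_array(epochs: EpochSet) -> np.ndarray:
    arr = epochs.to_array()
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    return arr


def tfr_percent_change(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    baseline: tuple[float, float] = BASELINE,
    n_cycles: float = 7.0,
) -> TFRMap:
    """Trial-averaged Morlet power as percent change from baseline.

    Power is computed per trial with 7-cycle Morlet wavelets on frequencies
    2-25 Hz (1 Hz steps) unless given, averaged over trials and channels,
    then expressed per frequency as ``100 * (P - P_base) / P_base`` with
    ``P_base`` the mean power over the baseline window.  The epochs must
    include pre-cue samples covering the baseline.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = np.arange(2.0, 26.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    arr = _equal_length_array(epochs)
    times = epochs.times(0)
    if baseline[0] < times[0] or baseline[1] > times[-1]:
        raise ValueError("baseline window lies outside the epochs")
    power = tfr_array_morlet(
        arr, sfreq=epochs.rate, freqs=freqs, n_cycles=n_cycles,
        output="avg_power", zero_mean=True, verbose="error",
    )  # (n_channels, n_freqs, n_times)
    power = power.mean(axis=0)
    base_mask = (times >= baseline[0]) & (times <= baseline[1])
    p_base = power[:, base_mask].mean(axis=1, keepdims=True)
    pc = 100.0 * (power - p_base) / p_base
    return TFRMap(freqs=freqs, times=times, percent_change=pc, baseline=baseline)


def erp_average(
    epochs: EpochSet, baseline: tuple[float, float] = BASELINE
) -> tuple[np.ndarray, np.ndarray]:
    """Cue-locked ERP: pointwise trial mean per channel, baseline-corrected.

    Returns ``(times, erp)`` with ``erp`` of shape (n_channels, n_times).
    When the epochs carry no pre-cue samples the baseline correction is
    skipped (nothing to correct against).
    """
    arr = _equal_length_array(epochs)
    erp = arr.mean(axis=0)
    times = epochs.times(0)
    base_mask = (times >= baseline[0]) & (times <= baseline[1])
    if base_mask.any():
        erp = erp - erp[:, base_mask].mean(axis=1, keepdims=True)
    return times, erp
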