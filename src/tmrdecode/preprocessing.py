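"""EEG cleaning: re-referencing, filtering, resampling, Tukey-fence outlier
screening with neighbor interpolation, and moving-average smoothing.

The cleaning chain mirrors standard sleep-EEG practice: mastoid
re-referencing, a 0.1-30 Hz zero-phase band-pass with per-channel centering,
resampling to 200 Hz, then a per-trial/per-channel outlier screen on three
statistics (variance, max, min) against Tukey fences computed across trials.
Trials bad on more than 25% of channels overall -- or more than 25% of a
motor-area channel subset, because the task is motor-related -- are rejected;
otherwise bad channels are interpolated from triangulation neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .epochs import (
    MASTOIDS,
    MOTOR_CHANNELS,
    ContinuousRecording,
    EpochSet,
    channel_positions_2d,
    delaunay_neighbors,
)

__all__ = [
    "OutlierReport",
    "rereference_mastoids",
    "bandpass_center",
    "resample_to",
    "tukey_outlier_screen",
    "interpolate_bad_channels",
    "moving_average_smooth",
]


def rereference_mastoids(
    rec: ContinuousRecording, drop: bool = True
) -> ContinuousRecording:
    """Re-reference to the average of the mastoids (TP9, TP10).

    The mastoid average is subtracted from every channel; with ``drop=True``
    (default) the mastoids are then removed, leaving the scalp analysis set.
    """
    for m in MASTOIDS:
        if m not in rec.channel_names:
            raise ValueError(f"mastoid channel {m} missing from recording")
    i9 = rec.channel_names.index(MASTOIDS[0])
    i10 = rec.channel_names.index(MASTOIDS[1])
    ref = 0.5 * (rec.data[i9] + rec.data[i10])
    data = rec.data - ref
    names = list(rec.channel_names)
    if drop:
        keep = [i for i, n in enumerate(names) if n not in MASTOIDS]
        data = data[keep]
        names = [names[i] for i in keep]
    return ContinuousRecording(data, rec.rate, names, reference="mastoids")


def _butter_sos(low_hz: float, high_hz: float, rate: float, order: int = 4):
    return sig.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos"
    )


def bandpass_center(
    rec: ContinuousRecording, low_hz: float = 0.1, high_hz: float = 30.0
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (4th order per pass) plus centering.

    Zero-phase (forward-backward) filtering protects event-related latencies.
    The per-channel mean is removed afterwards.
    """
    if not 0 < low_hz < high_hz < rec.rate / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = _butter_sos(low_hz, high_hz, rec.rate)
    # the low edge's impulse response is ~1/low_hz seconds long; pad
    # generously so boundary transients stay at the boundaries
    padlen = int(min(rec.n_samples - 1, 3 * rec.rate / low_hz))
    data = sig.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    data = data - data.mean(axis=1, keepdims=True)
    return ContinuousRecording(data, rec.rate, list(rec.channel_names), rec.reference)


def resample_to(rec: ContinuousRecording, target_hz: float) -> ContinuousRecording:
    """Anti-aliased downsampling to ``target_hz`` (polyphase resampling).

    Upsampling is refused: the pipeline only ever reduces 500/250 Hz
    recordings to the 200 Hz analysis rate.
    """
    if target_hz > rec.rate:
        raise ValueError("upsampling not supported")
    if target_hz == rec.rate:
        return ContinuousRecording(
            rec.data.copy(), rec.rate, list(rec.channel_names), rec.reference
        )
    from fractions import Fraction

    frac = Fraction(target_hz / rec.rate).limit_denominator(1000)
    data = sig.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return ContinuousRecording(data, target_hz, list(rec.channel_names), rec.reference)


# ---------------------------------------------------------------------------
# Outlier screen
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Per-trial/per-channel bad flags and per-trial keep/interpolate/reject
    decisions from the Tukey-fence screen."""

    bad: np.ndarray  # (n_trials, n_channels) bool
    decisions: list[str]  # "keep" | "interpolate" | "reject"
    frac_bad: np.ndarray  # per trial, over all channels
    frac_bad_motor: np.ndarray  # per trial, over the motor subset
    channel_names: list[str]
    motor_channels: list[str]


def _tukey_flags(stat: np.ndarray) -> np.ndarray:
    """Flag entries strictly outside Q3 + 1.5 IQR / Q1 - 1.5 IQR of their
    channel's distribution across trials.

    Quartiles use linear interpolation between order statistics (type 7).
    When the IQR is zero the fences collapse to the common value and only
    strictly different values are flagged, so identical trials yield none.
    """
    q1 = np.percentile(stat, 25, axis=0)
    q3 = np.percentile(stat, 75, axis=0)
    iqr = q3 - q1
    return (stat > q3 + 1.5 * iqr) | (stat < q1 - 1.5 * iqr)


def tukey_outlier_screen(
    epochs: EpochSet,
    motor_channels: tuple[str, ...] = MOTOR_CHANNELS,
    reject_fraction: float = 0.25,
) -> OutlierReport:
    """Screen trials on variance, max and min against per-channel Tukey fences.

    A trial x channel cell is bad if any of the three statistics falls
    strictly outside its channel's fences across trials.  A trial is rejected
    when bad on more than ``reject_fraction`` of all channels or of the motor
    subset; interpolated when it has any bad channel; kept otherwise.
    """
    if epochs.n_trials < 8:
        raise ValueError("need at least 8 trials for meaningful quartiles")
    missing = [m for m in motor_channels if m not in epochs.channel_names]
    if missing:
        raise ValueError(f"motor channels missing from epochs: {missing}")
    var = np.array([t.var(axis=1) for t in epochs.trials])
    mx = np.array([t.max(axis=1) for t in epochs.trials])
    mn = np.array([t.min(axis=1) for t in epochs.trials])
    bad = _tukey_flags(var) | _tukey_flags(mx) | _tukey_flags(mn)
    motor_idx = [epochs.channel_names.index(m) for m in motor_channels]
    frac = bad.mean(axis=1)
    frac_motor = (
        bad[:, motor_idx].mean(axis=1)
        if motor_idx
        else np.zeros(epochs.n_trials)
    )
    decisions = []
    for i in range(epochs.n_trials):
        if frac[i] > reject_fraction or frac_motor[i] > reject_fraction:
            decisions.append("reject")
        elif bad[i].any():
            decisions.append("interpolate")
        else:
            decisions.append("keep")
    return OutlierReport(
        bad=bad,
        decisions=decisions,
        frac_bad=frac,
        frac_bad_motor=frac_motor,
        channel_names=list(epochs.channel_names),
        motor_channels=list(motor_channels),
    )


def default_neighbor_map(channel_names: list[str]):
    """Delaunay-triangulation neighbor map from template 10-10 positions."""
    pos = channel_positions_2d(channel_names)
    return delaunay_neighbors(pos), pos


def interpolate_bad_channels(
    epochs: EpochSet,
    report: OutlierReport,
    neighbor_map: dict[str, set[str]] | None = None,
    positions: dict[str, np.ndarray] | None = None,
) -> EpochSet:
    """Replace bad channels by inverse-distance-weighted averages of their
    good triangulation neighbors; drop rejected trials.

    Every bad channel must have at least two good neighbors in the map.
    """
    if neighbor_map is None or positions is None:
        neighbor_map, positions = default_neighbor_map(list(epochs.channel_names))
    keep_idx = [i for i, d in enumerate(report.decisions) if d != "reject"]
    out = epochs.subset(keep_idx)
    name_to_row = {n: i for i, n in enumerate(epochs.channel_names)}
    for new_i, old_i in enumerate(keep_idx):
        if report.decisions[old_i] != "interpolate":
            continue
        trial = out.trials[new_i]
        bad_here = set(
            np.array(epochs.channel_names)[report.bad[old_i]].tolist()
        )
        for ch in sorted(bad_here):
            good_nb = [
                n for n in neighbor_map.get(ch, set()) if n not in bad_here
            ]
            if len(good_nb) < 2:
                raise ValueError(
                    f"channel {ch} has fewer than 2 good neighbors; cannot interpolate"
                )
            dists = np.array(
                [np.linalg.norm(positions[ch] - positions[n]) for n in good_nb]
            )
            w = 1.0 / np.maximum(dists, 1e-12)
            w = w / w.sum()
            rows = [name_to_row[n] for n in good_nb]
            trial[name_to_row[ch]] = w @ trial[rows]
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _smooth_matrix(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving mean along the last axis with edge truncation.

    Uses prefix sums: window sums are differences of the cumulative sum with
    indices clipped at the edges, divided by the actual window size there.
    """
    half = win // 2
    n = x.shape[-1]
    cs = np.cumsum(x, axis=-1)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), cs], axis=-1)
    hi = np.minimum(np.arange(n) + half + 1, n)
    lo = np.maximum(np.arange(n) - half, 0)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def moving_average_smooth(epochs: EpochSet, window_ms: float = 100.0) -> EpochSet:
    """Replace each timepoint by the mean of the ``window_ms`` around it.

    The window is centred and truncated at trial edges (no padding, so no
    fabricated data at cue onset).  At 200 Hz a 100 ms window is realized as
    21 samples (centre plus or minus 10).
    """
    half = round(window_ms / 2000.0 * epochs.rate)
    win = 2 * half + 1
    out = epochs.copy()
    smoothed = []
    for t in out.trials:
        if win >= t.shape[1]:
            raise ValueError("smoothing window must be shorter than the trial")
        smoothed.append(_smooth_matrix(t, win))
    out.trials = smoothed
    return out
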