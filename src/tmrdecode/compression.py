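"""Temporal compression/dilation scan of sleep reactivation.

For each sleep/wake duration ratio on a grid spanning 20x-faster to
2.2x-slower, 10 ms-stepped sliding windows are cut from every sleep trial,
linearly resized to the 1.15 s wake-trial length, and used to train a
classifier on the concatenated (PCs x timepoints) feature vectors; wake
trials are the test observations.  A per-ratio group signed-rank test of the
correct classification rate against the 0.25 chance level identifies the
ratios at which the rescaled sleep patterns line up with wake activity.

Data are deliberately *not* smoothed here: at 20x compression the whole
motif spans tens of milliseconds and a 100 ms moving average would erase it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import fit_lda, fit_pca_on_sleep, project
from .epochs import CLASSES, EpochSet
from .stats import SignedRankResult, signed_rank_test

__all__ = [
    "RatioGrid",
    "RatioScanResult",
    "build_ratio_grid",
    "extract_resized_windows",
    "scan_ratios",
    "ratio_significance",
]

#: Hard bounds of the ratio axis (sleep window duration / wake duration).
#: 1/20 keeps the fastest window at 57 ms (>= ~10 samples at 200 Hz);
#: 2.5/1.15 matches the shortest sleep trial so every trial contributes.
RATIO_MIN = 1.0 / 20.0
RATIO_MAX = 2.5 / 1.15


@dataclass
class RatioGrid:
    """Ordered compression/dilation ratios with human-readable labels."""

    ratios: np.ndarray  # strictly increasing, in [RATIO_MIN, RATIO_MAX]
    labels: list[str]

    @property
    def speed_factors(self) -> np.ndarray:
        """How many times faster (>1) or slower (<1) than wake."""
        return 1.0 / self.ratios

    def nearest_index(self, speed_factor: float) -> int:
        return int(np.argmin(np.abs(np.log(self.speed_factors / speed_factor))))


def _speed_label(speed: float) -> str:
    if speed >= 1:
        return f"{speed:.2g}x faster"
    return f"{1 / speed:.2g}x slower"


def build_ratio_grid(n_points: int = 12) -> RatioGrid:
    """Log-spaced ratio grid over [1/20, 2.5/1.15], snapping the nearest
    point to exactly 1.0 (no compression or dilation)."""
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    ratios = np.geomspace(RATIO_MIN, RATIO_MAX, n_points)
    ratios[np.argmin(np.abs(np.log(ratios)))] = 1.0
    if not np.all(np.diff(ratios) > 0):
        raise ValueError("grid not strictly increasing after snapping to 1.0")
    return RatioGrid(ratios, [_speed_label(1 / r) for r in ratios])


def _resize_matrix_linear(x: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation of (channels, n_in) onto n_out time points."""
    n_in = x.shape[-1]
    if n_in == n_out:
        return x.copy()
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.minimum(pos.astype(int), n_in - 2)
    frac = pos - i0
    return x[..., i0] * (1 - frac) + x[..., i0 + 1] * frac


def extract_resized_windows(
    sleep_trial: np.ndarray,
    ratio: float,
    rate: float,
    step_ms: float = 10.0,
    target_len: int = 230,
    wake_len_s: float = 1.15,
) -> np.ndarray:
    """Sliding windows of duration ``ratio * wake_len_s``, each resized to
    ``target_len`` samples by linear interpolation along time.

    Windows start at sample 0 and advance ``step_ms`` until they no longer
    fit (half-open sample ranges).  Returns (n_windows, channels,
    target_len); empty when the window exceeds the trial.
    """
    n = sleep_trial.shape[-1]
    # length in samples of the wake trial, then floor of ratio times it
    # (guarding against float representation of e.g. 1.15 * 200)
    wake_samples = round(wake_len_s * rate)
    wlen = int(np.floor(ratio * wake_samples + 1e-9))
    step = max(1, round(step_ms / 1000.0 * rate))
    if wlen < 2:
        raise ValueError("window shorter than 2 samples")
    if wlen > n:
        return np.empty((0, sleep_trial.shape[0], target_len))
    starts = np.arange(0, n - wlen + 1, step)
    # All windows share one source-position grid relative to their start.
    pos = np.linspace(0.0, wlen - 1.0, target_len)
    i0 = np.minimum(pos.astype(int), max(wlen - 2, 0))
    frac = pos - i0
    idx = starts[:, None] + i0[None, :]  # (n_windows, target_len)
    a = sleep_trial[:, idx]  # (channels, n_windows, target_len)
    b = sleep_trial[:, np.minimum(idx + 1, n - 1)]
    out = a * (1 - frac) + b * frac
    return np.ascontiguousarray(np.transpose(out, (1, 0, 2)))


def window_count(trial_len: int, window_len: int, step: int) -> int:
    """floor((len - window) / step) + 1 for a fitting window, else 0."""
    if window_len > trial_len:
        return 0
    return (trial_len - window_len) // step + 1


@dataclass
class RatioScanResult:
    """Per-ratio wake classification accuracy for one participant."""

    grid: RatioGrid
    ccr: np.ndarray  # per ratio
    n_windows: np.ndarray  # training windows used per ratio
    participant_id: int | None = None

    @property
    def best_speed_factor(self) -> float:
        return float(self.grid.speed_factors[int(np.argmax(self.ccr))])


def scan_ratios(
    sleep: EpochSet,
    wake: EpochSet,
    grid: RatioGrid | None = None,
    explained: float = 0.95,
    step_ms: float = 10.0,
    participant_id: int | None = None,
) -> RatioScanResult:
    """Run the compression/dilation scan for one participant.

    Per ratio: spatial PCA is (re)fitted on the unsmoothed sleep data and
    shared with wake; every resized sleep window is one training observation
    with feature vector PCs x target_len (flattened) and its trial's label;
    each wake trial is one test observation; the CCR is the fraction of wake
    trials classified correctly.
    """
    grid = grid or build_ratio_grid()
    rate = sleep.rate
    target_len = round(1.15 * rate)
    wake_arr = wake.to_array()
    if wake_arr.shape[2] != target_len:
        target_len = wake_arr.shape[2]

    pca = fit_pca_on_sleep(sleep, explained=explained)
    sleep_pcs = project(pca, sleep)
    wake_pcs = project(pca, wake).to_array().astype(np.float32)  # (n, d, T)
    n_wake, d, T = wake_pcs.shape
    X_test = wake_pcs.reshape(n_wake, d * T)

    ccrs = np.zeros(grid.ratios.size)
    n_windows = np.zeros(grid.ratios.size, dtype=int)
    for gi, ratio in enumerate(grid.ratios):
        feats, labs = [], []
        for trial, lab in zip(sleep_pcs.trials, sleep_pcs.labels):
            w = extract_resized_windows(
                np.asarray(trial, dtype=np.float32),
                ratio,
                rate,
                step_ms=step_ms,
                target_len=T,
            )
            if w.shape[0] == 0:
                continue  # trial shorter than the window; skipped
            feats.append(w.reshape(w.shape[0], d * T))
            labs.append(np.full(w.shape[0], lab))
        X = np.concatenate(feats, axis=0)
        y = np.concatenate(labs)
        missing = [c for c in CLASSES if not np.any(y == c)]
        if missing:
            raise ValueError(f"classes without training windows: {missing}")
        model = fit_lda(X, y)
        pred = model.predict(X_test)
        ccrs[gi] = float(np.mean(pred == wake.labels))
        n_windows[gi] = X.shape[0]
    return RatioScanResult(grid, ccrs, n_windows, participant_id)


def ratio_significance(
    results: list[RatioScanResult], chance: float = 0.25
) -> list[SignedRankResult]:
    """One-sided signed-rank test of per-participant CCR against chance at
    each ratio (exact null for n <= 25), uncorrected across ratios."""
    if len(results) < 6:
        raise ValueError("need at least 6 participants")
    grid = results[0].grid
    if any(r.grid.ratios.size != grid.ratios.size for r in results):
        raise ValueError("grids differ across participants")
    ccr = np.array([r.ccr for r in results])  # (participants, ratios)
    return [
        signed_rank_test(ccr[:, j] - chance, alternative="greater")
        for j in range(grid.ratios.size)
    ]
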