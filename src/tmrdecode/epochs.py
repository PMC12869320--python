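"""Core data containers for cue-locked EEG analysis.

The two central objects are :class:`ContinuousRecording` (a channels x samples
matrix with a sampling rate) and :class:`EpochSet` (a collection of cue-locked
trials, possibly of unequal length, each carrying a class label 1-4, a
cued/uncued condition flag and a brain state tag).  Sleep trials vary in
duration because inter-cue intervals are jittered between 2.5 and 3.5 s; wake
imagery trials all share one length (1.15 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 58-channel scalp analysis set (10-10 names) left after dropping the
#: mastoid references TP9/TP10 from a 60-channel montage.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

#: Channels over the sensorimotor strip used for the stricter trial-rejection
#: rule in the outlier screen (the task is motor-related).
MOTOR_CHANNELS: tuple[str, ...] = (
    "C6", "C4", "C2", "C1", "C3", "C5",
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
)

CLASSES: tuple[int, ...] = (1, 2, 3, 4)


@dataclass
class ContinuousRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per row of ``data``.
    reference : str
        Label of the current reference scheme (e.g. ``"CPz"`` for the
        recording reference, ``"mastoids"`` after re-referencing).
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    reference: str = "CPz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, names: Sequence[str]) -> "ContinuousRecording":
        """Return a copy restricted to ``names`` (in the given order)."""
        idx = [self.channel_names.index(n) for n in names]
        return ContinuousRecording(
            self.data[idx].copy(), self.rate, list(names), self.reference
        )


@dataclass
class EpochSet:
    """Cue-locked trials, the universal unit of decoding.

    ``trials`` is a list because sleep trials have jittered lengths.  Time 0
    of every trial is cue onset; ``tmin`` is the time of the first stored
    sample relative to the cue (negative when a pre-cue baseline is kept).
    ``lengths_s`` records the post-cue duration of each trial.
    """

    trials: list[np.ndarray]
    labels: np.ndarray
    state: str  # "sleep" | "wake"
    rate: float
    channel_names: list[str]
    condition: np.ndarray | None = None
    tmin: float = 0.0
    lengths_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.trials) != len(self.labels):
            raise ValueError("labels must match trial count")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"labels must be in {CLASSES}, got extra {sorted(bad)}")
        if self.state not in ("sleep", "wake"):
            raise ValueError("state must be 'sleep' or 'wake'")
        if self.condition is None:
            self.condition = np.array(["cued"] * len(self.trials))
        else:
            self.condition = np.asarray(self.condition)
        if self.lengths_s is None:
            self.lengths_s = np.array(
                [t.shape[1] / self.rate + self.tmin for t in self.trials]
            )
        else:
            self.lengths_s = np.asarray(self.lengths_s, dtype=float)
        for t in self.trials:
            if t.shape[0] != len(self.channel_names):
                raise ValueError("trial channel dimension mismatch")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def times(self, i: int = 0) -> np.ndarray:
        """Sample times of trial ``i`` in seconds relative to cue onset."""
        n = self.trials[i].shape[1]
        return self.tmin + np.arange(n) / self.rate

    def to_array(self) -> np.ndarray:
        """Stack trials into (n_trials, n_channels, n_samples).

        Only valid when all trials share one length (wake sets).
        """
        lens = {t.shape[1] for t in self.trials}
        if len(lens) != 1:
            raise ValueError("trials have unequal lengths; cannot stack")
        return np.stack(self.trials)

    def subset(self, idx: Iterable[int]) -> "EpochSet":
        """Return a new EpochSet restricted to trial indices ``idx``."""
        idx = np.asarray(list(idx), dtype=int)
        meta = {
            k: (np.asarray(v)[idx] if np.ndim(v) >= 1 and len(v) == self.n_trials else v)
            for k, v in self.meta.items()
        }
        return EpochSet(
            trials=[self.trials[i].copy() for i in idx],
            labels=self.labels[idx],
            state=self.state,
            rate=self.rate,
            channel_names=list(self.channel_names),
            condition=self.condition[idx],
            tmin=self.tmin,
            lengths_s=self.lengths_s[idx],
            meta=meta,
        )

    def copy(self) -> "EpochSet":
        return self.subset(range(self.n_trials))


def channel_positions_2d(names: Sequence[str]) -> dict[str, np.ndarray]:
    """2-D scalp positions for standard 10-10 channel names.

    Uses the template electrode positions shipped with MNE and flattens them
    with an azimuthal-equidistant projection (the usual topographic-map
    convention), so Delaunay triangulation of the result gives sensible
    scalp neighborhoods.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across MNE releases
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos3d]
    if missing:
        raise KeyError(f"channels without template positions: {missing}")
    out = {}
    for n in names:
        x, y, z = pos3d[n]
        r = np.sqrt(x * x + y * y + z * z)
        theta = np.arccos(np.clip(z / r, -1, 1))
        phi = np.arctan2(y, x)
        out[n] = np.array([theta * np.cos(phi), theta * np.sin(phi)])
    return out


def delaunay_neighbors(positions: dict[str, np.ndarray]) -> dict[str, set[str]]:
    """Neighbor map from Delaunay triangulation of 2-D channel positions."""
    from scipy.spatial import Delaunay

    names = list(positions)
    pts = np.array([positions[n] for n in names])
    tri = Delaunay(pts)
    nb: dict[str, set[str]] = {n: set() for n in names}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    nb[names[a]].add(names[b])
    return nb
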