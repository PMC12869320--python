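"""Cross-state (sleep-to-wake) decoding of cued reactivation.

The core method: spatial principal components are fitted on sleep data
(channels x pooled timepoints), both states are projected through the same
components, a four-class LDA is trained with every post-cue sleep timepoint
as one observation (labelled by its trial's cue class), and the model is
applied to every wake timepoint, yielding a correct-classification-rate (CCR)
time course per participant.  Group inference against the 0.25 chance level
uses a cluster-based sign-flip permutation test over the whole 1.15 s wake
window.

Training on sleep and testing on wake (rather than the reverse) lets the
classifier weight features by their expression in sleep and absorb sleep
noise into the within-class covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .epochs import CLASSES, EpochSet
from .stats import ClusterResult, cluster_permutation_onesample

__all__ = [
    "PCAModel",
    "LDAModel",
    "CCRTimecourse",
    "fit_pca_on_sleep",
    "project",
    "train_sleep_lda",
    "ccr_wake_timecourse",
    "cluster_permutation_vs_chance",
    "decode_participant",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Spatial PCA fitted on pooled sleep timepoints.

    ``components`` are orthonormal spatial vectors (rows), sorted by
    explained variance; ``n_kept`` is the smallest count whose cumulative
    explained-variance ratio reaches 95% (or the configured fraction).
    """

    mean: np.ndarray  # (n_channels,)
    components: np.ndarray  # (n_components, n_channels)
    explained_ratio: np.ndarray
    n_kept: int
    explained_target: float = 0.95


def n_components_for_variance(explained_ratio: np.ndarray, target: float) -> int:
    """Smallest k with cumulative explained-variance ratio >= target."""
    cum = np.cumsum(explained_ratio)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def _pooled_timepoints(epochs: EpochSet) -> np.ndarray:
    """Concatenate all trials' timepoints into (n_obs, n_channels)."""
    return np.concatenate([t.T for t in epochs.trials], axis=0)


def fit_pca_on_sleep(
    sleep: EpochSet, explained: float = 0.95, _min_keep: int = 2
) -> PCAModel:
    """Fit spatial PCA on the pooled sleep timepoints.

    Components with non-positive eigenvalue (rank deficiency) are dropped;
    an error is raised if fewer than two remain.  Each component's
    largest-magnitude loading is made positive to remove sign indeterminacy.
    """
    X = _pooled_timepoints(sleep)
    n_obs, n_ch = X.shape
    if n_obs <= n_ch:
        raise ValueError("need more pooled timepoints than channels")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred observation matrix: right singular vectors are the
    # spatial components, singular values give the eigenvalue spectrum.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n_obs - 1)
    tol = eig[0] * max(n_obs, n_ch) * np.finfo(float).eps if eig.size else 0.0
    pos = eig > tol
    if pos.sum() < _min_keep:
        raise ValueError("rank-deficient input: fewer than 2 usable components")
    eig, vt = eig[pos], vt[pos]
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    ratio = eig / eig.sum()
    return PCAModel(
        mean=mean,
        components=vt,
        explained_ratio=ratio,
        n_kept=n_components_for_variance(ratio, explained),
        explained_target=explained,
    )


def project(pca: PCAModel, epochs: EpochSet) -> EpochSet:
    """Project every trial onto the kept components (n_kept x time).

    The same sleep-fitted model is applied to both states so features live
    in one shared space.
    """
    n_ch = pca.components.shape[1]
    if epochs.n_channels != n_ch:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels, model expects {n_ch}"
        )
    W = pca.components[: pca.n_kept]
    out = epochs.copy()
    out.trials = [W @ (t - pca.mean[:, None]) for t in epochs.trials]
    out.channel_names = [f"PC{i + 1}" for i in range(pca.n_kept)]
    return out


# ---------------------------------------------------------------------------
# LDA with analytic shrinkage
# ---------------------------------------------------------------------------

def _oas_shrinkage(S: np.ndarray, n_obs: int) -> float:
    """Oracle Approximating Shrinkage coefficient toward the scaled identity,
    computed from the pooled scatter matrix alone."""
    d = S.shape[0]
    mu = np.trace(S) / d
    alpha = float(np.mean(S * S))
    num = alpha + mu * mu
    den = (n_obs + 1.0) * (alpha - mu * mu / d)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


@dataclass
class LDAModel:
    """Four-class linear discriminant with shrinkage-regularized pooled
    within-class covariance and (by default) equal priors."""

    classes: np.ndarray
    class_means: np.ndarray  # (n_classes, n_features)
    covariance: np.ndarray  # shrunk pooled within-class covariance
    priors: np.ndarray
    shrinkage: float
    _chol: np.ndarray | None = None

    def _factor(self) -> np.ndarray:
        if self._chol is None:
            self._chol = sla.cho_factor(self.covariance, lower=True)[0]
        return self._chol

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores (log posterior up to a shared term)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        c = self._factor()
        A = sla.cho_solve((c, True), self.class_means.T)  # (d, K)
        const = -0.5 * np.sum(self.class_means.T * A, axis=0) + np.log(self.priors)
        return X @ A + const

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class prediction; ties break toward the lowest class id."""
        scores = self.decision_scores(X)
        return self.classes[np.argmax(scores, axis=1)]

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: np.ndarray | None = None,
    shrinkage: float | str = "oas",
) -> LDAModel:
    """Fit the shrinkage LDA on observations ``X`` with labels ``y``.

    The pooled within-class scatter is shrunk toward ``mu * I`` (``mu`` the
    mean eigenvalue) with an OAS coefficient unless a fixed value is given.
    For large feature dimensions the scatter product is accumulated in
    float32 (BLAS syrk), which is far below the shrinkage-induced bias.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    idx = np.searchsorted(classes, y)
    Xc = X - means[idx]
    if n * d * d > 2e9 or X.dtype == np.float32:
        Xc32 = np.ascontiguousarray(Xc, dtype=np.float32)
        from scipy.linalg.blas import ssyrk

        S = np.array(ssyrk(1.0 / n, Xc32.T), dtype=np.float64)
        S = S + np.triu(S, 1).T  # syrk fills one triangle
    else:
        S = (Xc.T @ Xc) / n
    if shrinkage == "oas":
        lam = _oas_shrinkage(S, n)
    elif shrinkage is None:
        lam = 0.0
    else:
        lam = float(shrinkage)
    mu = np.trace(S) / d
    cov = (1 - lam) * S + lam * mu * np.eye(d)
    cov = 0.5 * (cov + cov.T)
    if priors is None:
        priors = np.full(classes.size, 1.0 / classes.size)
    priors = np.asarray(priors, dtype=float)
    if priors.size != classes.size or abs(priors.sum() - 1) > 1e-9 or (priors < 0).any():
        raise ValueError("priors must be non-negative and sum to 1")
    return LDAModel(
        classes=classes,
        class_means=means.astype(float),
        covariance=cov,
        priors=priors,
        shrinkage=lam,
    )


def train_sleep_lda(
    sleep_pcs: EpochSet,
    priors: np.ndarray | None = None,
    shrinkage: float | str = "oas",
) -> LDAModel:
    """Timepoints-as-observations LDA on PC-space sleep trials.

    Every post-cue timepoint of every sleep trial is one observation whose
    feature vector is the PC activations at that instant and whose label is
    the trial's cue class.  Priors are equal by default (cues are balanced
    by design).
    """
    counts = {c: int(np.sum(sleep_pcs.labels == c)) for c in CLASSES}
    missing = [c for c, n in counts.items() if n < 2]
    if missing:
        raise ValueError(f"classes with fewer than 2 trials: {missing}")
    # Use only post-cue samples (t >= 0) if a baseline is attached.
    start = max(0, round(-sleep_pcs.tmin * sleep_pcs.rate))
    X = np.concatenate([t[:, start:].T for t in sleep_pcs.trials], axis=0)
    y = np.concatenate(
        [
            np.full(t.shape[1] - start, lab)
            for t, lab in zip(sleep_pcs.trials, sleep_pcs.labels)
        ]
    )
    return fit_lda(X, y, priors=priors, shrinkage=shrinkage)


# ---------------------------------------------------------------------------
# Wake CCR time course and group statistics
# ---------------------------------------------------------------------------

@dataclass
class CCRTimecourse:
    """Per-timepoint correct classification rate on wake trials."""

    participant_id: int | None
    times: np.ndarray  # seconds after the wake cue
    ccr: np.ndarray
    chance: float = 0.25

    @property
    def max_ccr(self) -> float:
        return float(self.ccr.max())


def ccr_wake_timecourse(
    model: LDAModel, wake_pcs: EpochSet, participant_id: int | None = None
) -> CCRTimecourse:
    """Classify every wake trial at every post-cue timepoint.

    Both cued and uncued wake trials are included, so above-chance decoding
    cannot stem from cue-sound responses alone.
    """
    arr = wake_pcs.to_array()  # (n_trials, d, T)
    n_trials, d, T = arr.shape
    if d != model.class_means.shape[1]:
        raise ValueError("wake feature dimensionality does not match the model")
    start = max(0, round(-wake_pcs.tmin * wake_pcs.rate))
    arr = arr[:, :, start:]
    T = arr.shape[2]
    X = np.transpose(arr, (0, 2, 1)).reshape(n_trials * T, d)
    pred = model.predict(X).reshape(n_trials, T)
    ccr = (pred == wake_pcs.labels[:, None]).mean(axis=0)
    times = np.arange(T) / wake_pcs.rate
    return CCRTimecourse(participant_id, times, ccr)


def cluster_permutation_vs_chance(
    timecourses: list[CCRTimecourse],
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.05,
    n_permutations: int = 100_000,
    seed: int | None = 0,
) -> ClusterResult:
    """Group cluster-permutation test of CCR time courses against chance.

    One-tailed (decoding above chance is the hypothesis); the correction
    window is the whole wake trial.
    """
    if len(timecourses) < 5:
        raise ValueError("need at least 5 participants")
    T = timecourses[0].times.size
    if any(tc.times.size != T for tc in timecourses):
        raise ValueError("time axes differ across participants")
    devs = np.array([tc.ccr - tc.chance for tc in timecourses])
    if not np.all(np.isfinite(devs)):
        raise ValueError("non-finite CCR values")
    return cluster_permutation_onesample(
        devs,
        alpha_sample=alpha_sample,
        alpha_cluster=alpha_cluster,
        n_permutations=n_permutations,
        seed=seed,
        tail="greater",
    )


def decode_participant(
    sleep: EpochSet,
    wake: EpochSet,
    explained: float = 0.95,
    smooth_ms: float | None = 100.0,
    participant_id: int | None = None,
) -> CCRTimecourse:
    """Full single-participant pipeline: smooth, PCA on sleep, sleep-trained
    LDA, wake CCR time course."""
    from .preprocessing import moving_average_smooth

    if smooth_ms:
        sleep = moving_average_smooth(sleep, smooth_ms)
        wake = moving_average_smooth(wake, smooth_ms)
    pca = fit_pca_on_sleep(sleep, explained=explained)
    model = train_sleep_lda(project(pca, sleep))
    return ccr_wake_timecourse(model, project(pca, wake), participant_id)
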