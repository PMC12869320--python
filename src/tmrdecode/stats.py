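"""Rank and permutation statistics used across the pipeline.

Implements the three statistical primitives the analysis relies on:

* Wilcoxon signed-rank test against a fixed value, with an exact null for
  small samples (distribution of the positive-rank sum over all 2^n sign
  assignments, computed by dynamic programming) and a normal approximation
  with continuity and tie correction for larger samples.
* One-sample cluster-based permutation test over a time axis: pointwise
  t statistics are thresholded, contiguous suprathreshold runs form clusters
  scored by their summed t (cluster mass), and the null is built from random
  sign flips of each participant's whole deviation vector.
* Spearman correlation and a rank-based partial correlation (residualize the
  ranks of both variables on the ranks of a control variable, correlate the
  residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class SignedRankResult:
    """Outcome of a one-sample signed-rank test."""

    statistic: float  # W+ : sum of ranks of positive differences
    z: float  # normal-approximation z (positive = differences > 0)
    p_value: float
    n_used: int  # non-zero differences entering the test
    alternative: str
    mode: str  # "exact" | "approx"


def _exact_wplus_pmf(double_ranks: np.ndarray) -> np.ndarray:
    """PMF of W+ over all sign assignments, indexed by 2*W+ (integer grid).

    Ranks are doubled so tied (midrank) values stay on an integer lattice.
    Returns probabilities; index k corresponds to W+ = k / 2.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts / counts.sum()


def signed_rank_test(
    diffs: np.ndarray,
    alternative: str = "two-sided",
    mode: str = "auto",
    exact_max_n: int = 25,
) -> SignedRankResult:
    """Wilcoxon signed-rank test of ``diffs`` against zero.

    Zero differences are discarded (Wilcoxon's convention); if none remain
    the test is degenerate and ``p = 1``.  ``mode='auto'`` uses the exact
    sign-enumeration null for ``n <= exact_max_n`` and the normal
    approximation with continuity correction above, mirroring standard
    practice for group sizes in the tens.

    The reported ``z`` is always the (tie-corrected) normal approximation
    with the convention that positive ``z`` means the differences are
    predominantly positive.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided/greater/less")
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be 1-D")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 0.0, 1.0, 0, alternative, "degenerate")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    # normal approximation pieces (also reported alongside exact p)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    sigma = np.sqrt(sigma2) if sigma2 > 0 else np.nan
    if sigma2 > 0:
        # continuity correction toward the mean
        cc = 0.5 if w_plus != mu else 0.0
        z = (w_plus - mu - np.sign(w_plus - mu) * cc) / sigma
    else:
        z = 0.0

    use_exact = mode == "exact" or (mode == "auto" and n <= exact_max_n)
    if use_exact:
        pmf = _exact_wplus_pmf(np.round(2 * ranks).astype(int))
        k = int(round(2 * w_plus))
        p_ge = float(pmf[k:].sum())
        p_le = float(pmf[: k + 1].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2 * min(p_ge, p_le))
        used = "exact"
    else:
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        used = "approx"
    return SignedRankResult(w_plus, float(z), min(1.0, p), n, alternative, used)


# ---------------------------------------------------------------------------
# Cluster-based permutation
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters of contiguous suprathreshold timepoints with permutation p."""

    clusters: list[tuple[int, int]]  # half-open index ranges, sorted
    masses: np.ndarray  # summed t per cluster
    p_values: np.ndarray
    n_permutations: int
    alpha_sample: float
    alpha_cluster: float
    t_obs: np.ndarray = field(default_factory=lambda: np.array([]))
    t_threshold: float = np.nan

    @property
    def significant(self) -> list[tuple[int, int]]:
        return [c for c, p in zip(self.clusters, self.p_values) if p < self.alpha_cluster]

    @property
    def min_p(self) -> float:
        return float(self.p_values.min()) if self.p_values.size else 1.0


def _contiguous_clusters(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a 1-D mask."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _one_sample_t(devs: np.ndarray) -> np.ndarray:
    """t statistic per column of an (n, T) deviation matrix."""
    n = devs.shape[0]
    m = devs.mean(axis=0)
    sd = devs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def cluster_permutation_onesample(
    deviations: np.ndarray,
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.05,
    n_permutations: int = 100_000,
    seed: int | np.random.Generator | None = 0,
    tail: str = "greater",
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of a group of time courses.

    ``deviations`` is (n_participants, n_times): each row a participant's
    deviation from the null value (e.g. CCR - 0.25).  Pointwise one-sample
    t statistics exceeding the ``alpha_sample`` one-tailed t quantile form
    contiguous clusters scored by summed t.  The null distribution records
    the maximum cluster mass under random sign flips of whole rows; each
    observed cluster gets ``p = (1 + #{null >= mass}) / (1 + n_perm)``.

    The test is one-tailed (``tail='greater'``) by default: the hypothesis
    throughout this pipeline is above-chance decoding.
    """
    devs = np.asarray(deviations, dtype=float)
    if devs.ndim != 2:
        raise ValueError("deviations must be (participants x times)")
    if not np.all(np.isfinite(devs)):
        raise ValueError("non-finite deviations")
    n, T = devs.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    if tail == "less":
        devs = -devs

    t_thresh = float(sps.t.ppf(1 - alpha_sample, df=n - 1))
    t_obs = _one_sample_t(devs)
    clusters = _contiguous_clusters(t_obs > t_thresh)
    masses = np.array([t_obs[a:b].sum() for a, b in clusters])

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # Precompute pieces shared across permutations: sign flips leave the
    # per-column sum of squares unchanged.
    ss = np.sum(devs**2, axis=0)  # (T,)
    null_max = np.zeros(n_permutations)
    chunk = max(1, min(n_permutations, int(2e7) // max(T, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
        mean_p = (signs @ devs) / n  # (m, T)
        var_p = (ss / n - mean_p**2) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / np.sqrt(var_p / n)
        t_p = np.where(var_p > 0, t_p, 0.0)
        sup = np.where(t_p > t_thresh, t_p, 0.0)
        run = np.zeros(m)
        best = np.zeros(m)
        for j in range(T):
            col = sup[:, j]
            run = np.where(col > 0, run + col, 0.0)
            np.maximum(best, run, out=best)
        null_max[done : done + m] = best
        done += m

    p_values = np.array(
        [(1 + np.sum(null_max >= mass)) / (1 + n_permutations) for mass in masses]
    )
    return ClusterResult(
        clusters=clusters,
        masses=masses,
        p_values=p_values,
        n_permutations=n_permutations,
        alpha_sample=alpha_sample,
        alpha_cluster=alpha_cluster,
        t_obs=t_obs if tail == "greater" else -t_obs,
        t_threshold=t_thresh,
    )


# ---------------------------------------------------------------------------
# Spearman and rank-based partial correlation
# ---------------------------------------------------------------------------

def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, control: np.ndarray
) -> tuple[float, float]:
    """Spearman partial correlation of x and y controlling for one covariate.

    Rank-transform all three variables, residualize the ranks of x and y on
    the ranks of the control by least squares, and Pearson-correlate the
    residuals.  A constant control contributes nothing and the result equals
    the plain Spearman correlation.  p from the t distribution with n - 3
    degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(control, float)
    if not (x.size == y.size == c.size):
        raise ValueError("inputs must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    if not np.all(np.isfinite(c)):
        raise ValueError("control values must be finite")
    n = x.size
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rc = sps.rankdata(c)

    def resid(v: np.ndarray) -> np.ndarray:
        if np.ptp(rc) == 0:
            return v - v.mean()
        A = np.column_stack([np.ones(n), rc])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    ex, ey = resid(rx), resid(ry)
    # a variable fully explained by the control leaves numerically-zero
    # residuals; report exactly zero partial correlation there
    scale = np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom**2 <= 1e-16 * scale:
        return 0.0, 1.0
    r = float(np.sum(ex * ey) / denom)
    df = n - 3
    r_cl = min(max(r, -0.999999999), 0.999999999)
    tstat = r_cl * np.sqrt(df / (1 - r_cl**2))
    p = float(2 * sps.t.sf(abs(tstat), df))
    return r, p
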