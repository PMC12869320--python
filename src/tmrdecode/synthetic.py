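"""Synthetic multi-participant EEG cohorts with planted ground truth.

This module generates wake imagery sessions, cued slow-wave-sleep sessions and
behavioral reaction-time tables that carry the statistical structure the
decoding pipeline assumes, so that every downstream analysis can be validated
by parameter recovery:

* Four class templates (one per finger/image).  Finger representations
  overlap heavily at scalp resolution, so each class topography is a common
  smooth map plus a smaller class-specific component; class identity is
  carried mostly temporally, by a phase-locked slow (1-3 Hz) cue-locked
  waveform of one wake-trial length (1.15 s) with a class-specific frequency
  and an ordered net deflection.
* Wake trials are template (scaled by the participant's representation
  strength) + state-specific background noise including slow baseline drift;
  sleep trials have jittered lengths (2.5-3.5 s post-cue) and contain, with
  some probability, several repetitions of the class template compressed in
  time by the planted factor, over a 1/f + slow-oscillation background.
* Embedded motifs can be coupled to sigma-band (11-16 Hz) bursts at Cz,
  emulating the spindle/reactivation association.
* Per-participant reaction-time tables in which the cued sequence gains a
  benefit proportional to the participant's reactivation SNR.

Everything is deterministic given the seeds recorded in
:class:`ParticipantTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import CLASSES, DEFAULT_CHANNELS, EpochSet, channel_positions_2d

__all__ = [
    "ClassTemplate",
    "ReactivationSpec",
    "ParticipantTruth",
    "CohortConfig",
    "ParticipantRecord",
    "generate_class_templates",
    "generate_wake_session",
    "generate_sleep_session",
    "generate_behavior",
    "generate_cohort",
]

SESSIONS = ("pre", "24h", "10d", "6-8w")
POST_SESSIONS = ("24h", "10d", "6-8w")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ClassTemplate:
    """Spatiotemporal pattern of one of the four classes.

    ``spatial_weights`` is a unit-norm scalp map; ``waveform`` a cue-locked
    time course of one wake-trial length (unit RMS, arbitrary units).
    """

    class_id: int
    spatial_weights: np.ndarray
    waveform: np.ndarray

    @property
    def pattern(self) -> np.ndarray:
        """Rank-one channels x time pattern (outer product)."""
        return np.outer(self.spatial_weights, self.waveform)


@dataclass
class ReactivationSpec:
    """How reactivation motifs are planted in sleep trials.

    compression_factor ``c > 1`` means the sleep motif replays ``c`` times
    faster than the wake template (motif duration = wake length / c).
    ``spindle_coupling`` is P(sigma burst | motif embedded);
    ``baseline_burst_rate`` is P(sigma burst | no motif), so setting the two
    equal makes bursts independent of reactivation (a null condition).
    """

    compression_factor: float = 1.0
    embed_probability: float = 1.0
    snr: float = 1.0
    latency_window: tuple[float, float] = (0.2, 1.2)
    spindle_coupling: float = 1.0
    baseline_burst_rate: float = 0.0
    #: reactivation is repetitive: an embedded trial carries up to this many
    #: non-overlapping motif occurrences (first onset inside latency_window,
    #: later ones anywhere after it), as many as fit in the trial
    n_repeats: int = 9
    #: expected number of spontaneous motifs of the *other* classes per trial
    #: (Poisson): uncued memories also reactivate, which keeps cue-specific
    #: decoding from reducing to mere topography matching
    distractor_rate: float = 0.0

    def validate(self, wake_len_s: float = 1.15, min_trial_s: float = 2.5) -> None:
        if not 0 <= self.embed_probability <= 1:
            raise ValueError("embed_probability must be in [0, 1]")
        if not 0 <= self.spindle_coupling <= 1:
            raise ValueError("spindle_coupling must be in [0, 1]")
        if not 0 <= self.baseline_burst_rate <= 1:
            raise ValueError("baseline_burst_rate must be in [0, 1]")
        if not (1 / 2.2 <= self.compression_factor <= 20):
            raise ValueError("compression_factor must lie in [1/2.2, 20]")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        lo, hi = self.latency_window
        if not 0 <= lo <= hi:
            raise ValueError("latency_window must be ordered and non-negative")
        motif_s = wake_len_s / self.compression_factor
        if lo + motif_s > min_trial_s:
            raise ValueError(
                f"motif of {motif_s:.3f}s starting at {lo:.2f}s does not fit "
                f"inside the shortest sleep trial ({min_trial_s}s)"
            )

    @property
    def motif_duration_s(self) -> float:
        return 1.15 / self.compression_factor


@dataclass
class ParticipantTruth:
    """Everything needed to regenerate one participant bit-for-bit."""

    participant_id: int
    templates: list[ClassTemplate]
    reactivation: ReactivationSpec
    behavior_slope_ms: float
    seed: int


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    The defaults mirror the recorded experiment's structure: 58 scalp
    channels at 200 Hz, 1.15 s wake imagery trials, sleep cue trials jittered
    2.5-3.5 s, 24 behavioral blocks per sequence and session, and a pre-sleep
    median reaction time around 420 ms.
    """

    n_channels: int = 58
    rate: float = 200.0
    wake_len_s: float = 1.15
    n_sleep_trials: int = 60
    n_wake_trials_per_class: int = 30
    wake_noise_sd: float = 1.0
    wake_drift_amp: float = 2.5
    wake_own_background: bool = True
    # reactivation spec fields (per-participant snr drawn from snr_range)
    compression_factor: float = 1.0
    embed_probability: float = 1.0
    spindle_coupling: float = 1.0
    baseline_burst_rate: float = 0.0
    snr_range: tuple[float, float] = (1.0, 1.0)
    latency_window: tuple[float, float] = (0.2, 1.2)
    n_repeats: int = 9
    distractor_rate: float = 0.0
    # behavior
    n_blocks: int = 24
    pre_mean_ms: float = 420.0
    rt_sd_ms: float = 8.0
    slope_ms: float = 40.0
    base_gain_ms: float = 20.0
    # background composition (sleep)
    n_background_sources: int = 12
    source_gain: float = 1.0
    so_amp: float = 0.9
    white_amp: float = 0.06
    burst_amp: float = 2.5
    burst_dur_s: float = 0.8
    waveform_dc: float = 0.15
    waveform_freq_range: tuple[float, float] = (1.2, 2.8)
    spatial_distinctness: float = 0.5

    def reactivation_spec(self, snr: float) -> ReactivationSpec:
        spec = ReactivationSpec(
            compression_factor=self.compression_factor,
            embed_probability=self.embed_probability,
            snr=snr,
            latency_window=self.latency_window,
            spindle_coupling=self.spindle_coupling,
            baseline_burst_rate=self.baseline_burst_rate,
            n_repeats=self.n_repeats,
            distractor_rate=self.distractor_rate,
        )
        spec.validate(self.wake_len_s)
        return spec


@dataclass
class ParticipantRecord:
    """One participant's generated data bundle."""

    truth: ParticipantTruth
    sleep: EpochSet
    wake: EpochSet
    behavior: pd.DataFrame


# ---------------------------------------------------------------------------
# Low-level synthesis helpers
# ---------------------------------------------------------------------------

def _positions_array(n_channels: int) -> np.ndarray:
    """2-D channel positions: the template montage when the standard 58-channel
    set is used, otherwise a synthetic spiral layout."""
    if n_channels == len(DEFAULT_CHANNELS):
        pos = channel_positions_2d(DEFAULT_CHANNELS)
        return np.array([pos[n] for n in DEFAULT_CHANNELS])
    # synthetic layout: sunflower spiral on a disc of radius ~1.3 rad
    k = np.arange(n_channels) + 0.5
    r = 1.3 * np.sqrt(k / n_channels)
    th = k * (np.pi * (3 - np.sqrt(5)))
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _smooth_maps(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_maps: int,
    width: tuple[float, float] = (0.45, 0.9),
) -> np.ndarray:
    """Unit-norm Gaussian-bump scalp maps centred on random channels.

    Returns shape (n_channels, n_maps).
    """
    n_ch = positions.shape[0]
    maps = np.empty((n_ch, n_maps))
    for j in range(n_maps):
        c = positions[rng.integers(n_ch)] + 0.08 * rng.standard_normal(2)
        w = rng.uniform(*width)
        d2 = np.sum((positions - c) ** 2, axis=1)
        m = np.exp(-d2 / (2 * w * w))
        maps[:, j] = m / np.linalg.norm(m)
    return maps


def _pink_series(
    rng: np.random.Generator,
    n_series: int,
    n_samples: int,
    rate: float,
    f_floor: float = 0.75,
) -> np.ndarray:
    """Unit-RMS 1/f (power ~ 1/f) noise series, flat below ``f_floor``."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1 / rate)
    amp = 1.0 / np.sqrt(np.maximum(f, f_floor))
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _resample_linear(x: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation of a 1-D series onto ``n_out`` points covering the
    same span (endpoints map to endpoints)."""
    n_in = x.shape[-1]
    if n_in == n_out:
        return x.copy()
    src = np.linspace(0.0, n_in - 1.0, n_out)
    return np.interp(src, np.arange(n_in), x)


class _ParticipantSynth:
    """Deterministic per-participant synthesis state (mixing maps etc.)."""

    def __init__(self, truth: ParticipantTruth, cfg: CohortConfig):
        self.truth = truth
        self.cfg = cfg
        self.positions = _positions_array(cfg.n_channels)
        rng = np.random.default_rng([truth.seed, 0xB16])
        self.mixing = _smooth_maps(rng, self.positions, cfg.n_background_sources)
        # wake background has its own spatial structure: the waking brain is
        # in a different state, so its ongoing activity is not a noise-matched
        # copy of the slow-wave-sleep background
        self.wake_mixing = _smooth_maps(rng, self.positions, cfg.n_background_sources)
        self.source_gains = cfg.source_gain / np.sqrt(
            np.arange(1, cfg.n_background_sources + 1)
        )
        self.so_map = _smooth_maps(rng, self.positions, 1, width=(0.9, 1.2))[:, 0]
        # sigma bursts are focal around Cz (peak amplitude 1 at Cz)
        if cfg.n_channels == len(DEFAULT_CHANNELS):
            cz = DEFAULT_CHANNELS.index("Cz")
        else:
            cz = int(np.argmin(np.sum(self.positions**2, axis=1)))
        self.cz_index = cz
        d2 = np.sum((self.positions - self.positions[cz]) ** 2, axis=1)
        self.burst_map = np.exp(-d2 / (2 * 0.35**2))

    def background(self, rng: np.random.Generator, n_samples: int) -> np.ndarray:
        """One trial of sleep background: 1/f sources through smooth scalp
        maps, a 0.75 Hz slow oscillation with random phase and depth, and a
        little sensor white noise; normalized to overall unit RMS."""
        cfg = self.cfg
        src = _pink_series(rng, cfg.n_background_sources, n_samples, cfg.rate)
        bg = self.mixing @ (self.source_gains[:, None] * src)
        t = np.arange(n_samples) / cfg.rate
        amp = cfg.so_amp * rng.uniform(0.6, 1.4)
        phase = rng.uniform(0, 2 * np.pi)
        bg += np.outer(self.so_map, amp * np.sin(2 * np.pi * 0.75 * t + phase))
        bg += cfg.white_amp * rng.standard_normal(bg.shape)
        return bg / np.sqrt(np.mean(bg**2))

    def wake_noise(self, rng: np.random.Generator, n_samples: int) -> np.ndarray:
        """Wake-state background: spatially smooth 1/f plus sensor noise and
        slow baseline drift; unit overall RMS.

        The drift term (a random offset plus a sub-Hz wander on a random
        smooth topography) mimics electrode baseline wander, which dominates
        trial-averaged wake activity without obscuring instantaneous
        structure."""
        cfg = self.cfg
        src = _pink_series(rng, cfg.n_background_sources, n_samples, cfg.rate)
        mixing = self.wake_mixing if cfg.wake_own_background else self.mixing
        bg = mixing @ (self.source_gains[:, None] * src)
        bg += cfg.white_amp * rng.standard_normal(bg.shape)
        if cfg.wake_drift_amp > 0:
            t = np.arange(n_samples) / cfg.rate
            f_d = rng.uniform(0.15, 0.5)
            course = rng.standard_normal() + rng.standard_normal() * np.sin(
                2 * np.pi * f_d * t + rng.uniform(0, 2 * np.pi)
            )
            dmap = _smooth_maps(rng, self.positions, 1, width=(0.6, 1.1))[:, 0]
            drift = np.outer(dmap, course)
            drift *= (
                cfg.wake_drift_amp
                * np.sqrt(np.mean(bg**2))
                / max(np.sqrt(np.mean(drift**2)), 1e-12)
            )
            bg = bg + drift
        return bg / np.sqrt(np.mean(bg**2))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def generate_class_templates(
    n_channels: int,
    rate: float,
    wake_len_s: float,
    seed: int,
    waveform_dc: float = 0.15,
    freq_range: tuple[float, float] = (1.2, 2.8),
    spatial_distinctness: float = 0.5,
    max_cosine: float = 0.95,
    max_attempts: int = 100,
) -> list[ClassTemplate]:
    """Draw four pairwise non-collinear class templates.

    Spatial maps are smooth scalp bumps orthogonalized pairwise (QR), which
    guarantees separability for a linear classifier; waveforms are slow
    (1.5-3 Hz) one-to-two-cycle oscillations under a Hann envelope with a
    positive DC component of relative size ``waveform_dc``, normalized to
    unit RMS.  Redraws until the maximum absolute cosine similarity between
    flattened spatiotemporal patterns is below ``max_cosine``.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_t = round(wake_len_s * rate)
    positions = _positions_array(n_channels)
    rng = np.random.default_rng([seed, 0x7E4])
    t = np.arange(n_t) / rate
    env = np.hanning(n_t)
    # The four fingers' sensorimotor representations overlap heavily at scalp
    # resolution: each class map is one common topography plus a smaller
    # class-specific component (mixing weight ``spatial_distinctness``).
    # Class identity is otherwise temporal: a signed net deflection ("mass",
    # ordered across classes -- what an instantaneous decoder keys on) and a
    # phase-locked slow oscillation at a class-specific frequency.
    mass = waveform_dc * np.linspace(-1.0, 1.0, 4)
    f_grid = np.linspace(freq_range[0], freq_range[1], 4)
    beta = spatial_distinctness
    for _ in range(max_attempts):
        raw = _smooth_maps(rng, positions, 5)
        q, r = np.linalg.qr(raw)
        q = q * np.sign(np.diag(r))
        common, distinct = q[:, 0], q[:, 1:]
        if common[np.argmax(np.abs(common))] < 0:
            common = -common
        templates = []
        for k, cid in enumerate(CLASSES):
            s = np.sqrt(1 - beta**2) * common + beta * distinct[:, k]
            if s[np.argmax(np.abs(s))] < 0:
                s = -s
            f = float(f_grid[k] + 0.05 * (f_grid[1] - f_grid[0]) * rng.standard_normal())
            # cue-locked responses are phase-locked: every waveform starts
            # with a rising deflection (small phase jitter only), so
            # above-chance decoding occupies a common post-cue window across
            # classes and participants
            phase = rng.uniform(-0.3, 0.3)
            osc = env * np.sin(2 * np.pi * f * t + phase)
            osc = osc - osc.mean()  # oscillatory part carries no net mass
            # the envelope term sets the waveform's time-integral exactly:
            # it is what survives time-averaging
            w = osc + mass[k] * env
            w = w / np.sqrt(np.mean(w**2))
            templates.append(ClassTemplate(cid, s, w))
        flat = np.array([tp.pattern.ravel() for tp in templates])
        flat = flat / np.linalg.norm(flat, axis=1, keepdims=True)
        cos = np.abs(flat @ flat.T)
        np.fill_diagonal(cos, 0.0)
        if cos.max() < max_cosine:
            return templates
    raise RuntimeError(
        f"could not draw 4 distinguishable templates in {max_attempts} attempts"
    )


def generate_wake_session(
    truth: ParticipantTruth,
    n_trials_per_class: int,
    noise_sd: float,
    cfg: CohortConfig | None = None,
) -> EpochSet:
    """Balanced wake imagery session: each trial is its class template scaled
    by the participant's representation strength (the reactivation SNR; 1 by
    default) plus ``noise_sd`` times unit-RMS background noise (exactly the
    template when ``noise_sd=0`` at unit strength).  Half the trials of each
    class are tagged ``cued`` and half ``uncued``, mirroring that both
    sequences appear in the imagery task.

    Tying wake pattern expression to the same per-participant strength that
    scales sleep motifs models a participant-level representation quality;
    it is what makes decoding strength informative about the participant.
    """
    if n_trials_per_class < 1:
        raise ValueError("need at least 1 trial per class")
    cfg = cfg or CohortConfig()
    synth = _ParticipantSynth(truth, cfg)
    rng = np.random.default_rng([truth.seed, 0xA3E])
    n_t = round(cfg.wake_len_s * cfg.rate)

    labels = np.repeat(CLASSES, n_trials_per_class)
    order = rng.permutation(labels.size)
    labels = labels[order]
    # condition balanced within class
    cond_by_class = {
        c: np.array(["cued", "uncued"])[
            rng.permutation(np.arange(n_trials_per_class) % 2)
        ]
        for c in CLASSES
    }
    counters = {c: 0 for c in CLASSES}
    trials, conds = [], []
    gain = truth.reactivation.snr
    for lab in labels:
        tpl = truth.templates[lab - 1]
        trial = gain * tpl.pattern
        if noise_sd > 0:
            trial = trial + noise_sd * synth.wake_noise(rng, n_t)
        trials.append(trial)
        conds.append(cond_by_class[lab][counters[lab]])
        counters[lab] += 1
    names = (
        list(DEFAULT_CHANNELS)
        if cfg.n_channels == len(DEFAULT_CHANNELS)
        else [f"CH{i:02d}" for i in range(cfg.n_channels)]
    )
    return EpochSet(
        trials=trials,
        labels=labels,
        state="wake",
        rate=cfg.rate,
        channel_names=names,
        condition=np.array(conds),
    )


def generate_sleep_session(
    truth: ParticipantTruth,
    n_trials: int,
    noise_model: CohortConfig | None = None,
    pre_s: float = 0.0,
) -> EpochSet:
    """Cued N3 sleep session with planted reactivation motifs.

    Trial lengths are drawn uniformly from [2.5, 3.5] s after the cue.  With
    probability ``embed_probability`` a trial contains its label's waveform,
    linearly resampled to ``wake_len / c`` seconds, at a latency drawn from
    the spec's latency window, scaled so the motif RMS over its support is
    ``snr`` times the background RMS there.  Sigma bursts (12-15 Hz, Hann
    envelope) are added at Cz with probability ``spindle_coupling`` for
    embedded motifs (centred on the motif) and ``baseline_burst_rate``
    otherwise (random centre).  Ground-truth embed/burst flags, latencies and
    burst centres are returned in ``meta``.

    ``pre_s`` seconds of pre-cue background can be prepended (``tmin`` is set
    accordingly); lengths and embedding latencies always refer to the
    post-cue axis.
    """
    if n_trials < 4:
        raise ValueError("need at least 4 sleep trials")
    cfg = noise_model or CohortConfig()
    spec = truth.reactivation
    spec.validate(cfg.wake_len_s)
    synth = _ParticipantSynth(truth, cfg)
    rng = np.random.default_rng([truth.seed, 0x51E])
    rate = cfg.rate
    n_pre = round(pre_s * rate)

    motif_len = round(spec.motif_duration_s * rate)
    if motif_len < 2:
        raise ValueError("compressed motif shorter than 2 samples")

    labels = np.repeat(CLASSES, math.ceil(n_trials / 4))[:n_trials]
    labels = labels[rng.permutation(n_trials)]

    trials, lengths = [], []
    embed = np.zeros(n_trials, dtype=bool)
    burst = np.zeros(n_trials, dtype=bool)
    latency = np.full(n_trials, np.nan)
    burst_center = np.full(n_trials, np.nan)
    for i, lab in enumerate(labels):
        L = rng.uniform(2.5, 3.5)
        n_post = round(L * rate)
        if motif_len > n_post:
            raise ValueError("motif longer than the shortest sleep trial")
        x = synth.background(rng, n_pre + n_post)
        do_embed = rng.random() < spec.embed_probability
        onsets: list[int] = []
        if do_embed:
            lo, hi = spec.latency_window
            hi = min(hi, n_post / rate - spec.motif_duration_s)
            lat = rng.uniform(lo, hi) if hi > lo else lo
            onsets = [round(lat * rate)]
            # additional repeats: non-overlapping, anywhere after the cue
            last = n_post - motif_len
            for _ in range(max(0, spec.n_repeats - 1) * 10):
                if len(onsets) >= spec.n_repeats:
                    break
                cand = rng.integers(round(lo * rate), last + 1)
                if all(abs(cand - o) >= motif_len for o in onsets):
                    onsets.append(int(cand))
            tpl = truth.templates[lab - 1]
            wav = _resample_linear(tpl.waveform, motif_len)
            motif = np.outer(tpl.spatial_weights, wav)
            motif_rms = np.sqrt(np.mean(motif**2))
            for on0 in onsets:
                on = n_pre + on0
                seg = x[:, on : on + motif_len]
                scale = spec.snr * np.sqrt(np.mean(seg**2)) / motif_rms
                x[:, on : on + motif_len] += scale * motif
            embed[i], latency[i] = True, lat
        if spec.distractor_rate > 0:
            taken = list(onsets)
            n_dist = rng.poisson(spec.distractor_rate)
            others = [c for c in CLASSES if c != lab]
            last = n_post - motif_len
            for _ in range(n_dist):
                placed = None
                for _try in range(10):
                    cand = int(rng.integers(0, last + 1))
                    if all(abs(cand - o) >= motif_len for o in taken):
                        placed = cand
                        break
                if placed is None:
                    continue
                taken.append(placed)
                d_lab = others[rng.integers(3)]
                d_tpl = truth.templates[d_lab - 1]
                d_wav = _resample_linear(d_tpl.waveform, motif_len)
                d_motif = np.outer(d_tpl.spatial_weights, d_wav)
                on = n_pre + placed
                seg = x[:, on : on + motif_len]
                scale = (
                    spec.snr
                    * np.sqrt(np.mean(seg**2))
                    / np.sqrt(np.mean(d_motif**2))
                )
                x[:, on : on + motif_len] += scale * d_motif
        p_burst = spec.spindle_coupling if do_embed else spec.baseline_burst_rate
        if rng.random() < p_burst:
            half = cfg.burst_dur_s / 2
            if do_embed:
                center = latency[i] + spec.motif_duration_s / 2
            else:
                center = rng.uniform(0.5, 2.0)
            center = float(np.clip(center, half + 0.05, n_post / rate - half - 0.05))
            c0 = n_pre + round((center - half) * rate)
            n_b = round(cfg.burst_dur_s * rate)
            tb = np.arange(n_b) / rate
            f_b = rng.uniform(12.0, 15.0)
            osc = np.hanning(n_b) * np.sin(2 * np.pi * f_b * tb + rng.uniform(0, 2 * np.pi))
            cz = synth.cz_index
            amp = cfg.burst_amp * np.sqrt(np.mean(x[cz, c0 : c0 + n_b] ** 2))
            x[:, c0 : c0 + n_b] += np.outer(synth.burst_map, amp * osc)
            burst[i], burst_center[i] = True, center
        trials.append(x)
        lengths.append(n_post / rate)

    names = (
        list(DEFAULT_CHANNELS)
        if cfg.n_channels == len(DEFAULT_CHANNELS)
        else [f"CH{i:02d}" for i in range(cfg.n_channels)]
    )
    return EpochSet(
        trials=trials,
        labels=labels,
        state="sleep",
        rate=rate,
        channel_names=names,
        condition=np.array(["cued"] * n_trials),
        tmin=-pre_s,
        lengths_s=np.array(lengths),
        meta={
            "embedded": embed,
            "latency_s": latency,
            "sigma_burst": burst,
            "burst_center_s": burst_center,
            "compression_factor": spec.compression_factor,
            "snr": spec.snr,
        },
    )


def generate_behavior(
    truth: ParticipantTruth,
    n_blocks: int = 24,
    pre_mean_ms: float = 420.0,
    sd_ms: float = 8.0,
    base_gain_ms: float = 20.0,
) -> pd.DataFrame:
    """Block-level reaction times for both sequences across four sessions.

    All blocks are Gaussian around a session/sequence mean: the pre-sleep
    mean for both sequences, and post-sleep means lowered by a general
    consolidation gain plus -- for the cued sequence only -- the planted
    cueing benefit ``behavior_slope_ms * snr``.  With ``sd_ms = 0`` the
    post-sleep cued-minus-uncued difference is therefore exactly the planted
    benefit.
    """
    if n_blocks < 20:
        raise ValueError("need at least 20 blocks per session and sequence")
    benefit = truth.behavior_slope_ms * truth.reactivation.snr
    means = {
        ("pre", "cued"): pre_mean_ms,
        ("pre", "uncued"): pre_mean_ms,
    }
    for s in POST_SESSIONS:
        means[(s, "uncued")] = pre_mean_ms - base_gain_ms
        means[(s, "cued")] = pre_mean_ms - base_gain_ms - benefit
    if min(means.values()) - 6 * sd_ms <= 0:
        raise ValueError("parameters imply non-positive reaction times")
    rng = np.random.default_rng([truth.seed, 0xBE4])
    rows = []
    for session in SESSIONS:
        for sequence in ("cued", "uncued"):
            mu = means[(session, sequence)]
            rts = mu + sd_ms * rng.standard_normal(n_blocks)
            for b, rt in enumerate(rts):
                rows.append(
                    {
                        "participant": truth.participant_id,
                        "session": session,
                        "sequence": sequence,
                        "block": b,
                        "rt_ms": float(rt),
                    }
                )
    table = pd.DataFrame(rows)
    if (table["rt_ms"] <= 0).any():
        raise ValueError("generated non-positive reaction times")
    return table


def make_participant_truth(
    cfg: CohortConfig, participant_id: int, seed: int, snr: float
) -> ParticipantTruth:
    """Build one participant's ground truth (templates + reactivation spec)."""
    templates = generate_class_templates(
        cfg.n_channels, cfg.rate, cfg.wake_len_s, seed,
        waveform_dc=cfg.waveform_dc, freq_range=cfg.waveform_freq_range,
        spatial_distinctness=cfg.spatial_distinctness,
    )
    return ParticipantTruth(
        participant_id=participant_id,
        templates=templates,
        reactivation=cfg.reactivation_spec(snr),
        behavior_slope_ms=cfg.slope_ms,
        seed=seed,
    )


def generate_participant(
    cfg: CohortConfig, participant_id: int, seed: int, snr: float | None = None
) -> ParticipantRecord:
    """Generate one participant's full bundle (sleep, wake, behavior)."""
    if snr is None:
        snr = float(np.mean(cfg.snr_range))
    truth = make_participant_truth(cfg, participant_id, seed, snr)
    sleep = generate_sleep_session(truth, cfg.n_sleep_trials, cfg)
    wake = generate_wake_session(
        truth, cfg.n_wake_trials_per_class, cfg.wake_noise_sd, cfg
    )
    behavior = generate_behavior(
        truth, cfg.n_blocks, cfg.pre_mean_ms, cfg.rt_sd_ms, cfg.base_gain_ms
    )
    return ParticipantRecord(truth, sleep, wake, behavior)


def generate_cohort(
    cfg: CohortConfig, n_participants: int, master_seed: int
) -> list[ParticipantRecord]:
    """Generate a cohort with per-participant seeds derived from one master
    seed and reactivation SNR drawn uniformly from ``cfg.snr_range`` (so the
    reactivation-behavior correlation is recoverable when the range is wide).
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n_participants)]
    rng = np.random.default_rng([master_seed, 0xC0])
    snrs = rng.uniform(*cfg.snr_range, size=n_participants)
    return [
        generate_participant(cfg, pid, seeds[pid], float(snrs[pid]))
        for pid in range(n_participants)
    ]
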