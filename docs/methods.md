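# Methods

This note documents the models, numerical choices and known limitations of
`tmrdecode`, in the order the pipeline runs.

## The decoding model

The analysis assumes four class-specific spatiotemporal EEG patterns (one
per finger/image of a serial reaction time task), expressed cleanly during
wake imagery trials of fixed length (1.15 s at 200 Hz) and re-expressed —
possibly compressed in time, at unknown latencies — after auditory cues in
slow-wave sleep.  Sleep cue trials have jittered lengths (2.5–3.5 s), so no
fixed post-cue latency can be assumed.

**Spatial reduction.** PCA is fitted on the pooled sleep timepoints
(channels × all post-cue samples of all sleep trials).  Components are kept
up to 95% cumulative explained variance; each component's largest-magnitude
loading is made positive (removes sign indeterminacy, so fixtures and
repeated fits agree exactly).  Rank-deficient directions (non-positive
eigenvalues at machine precision) are dropped.  The same sleep-fitted model
projects both states, which guarantees the classifier looks at identical
spatial features across states.

**Classifier.** Four-class LDA with equal priors (cues are balanced by
design) and pooled within-class covariance shrunk toward the scaled
identity.  The shrinkage coefficient is the analytic Oracle Approximating
Shrinkage (OAS) value, computed from the scatter matrix's trace moments —
chosen over cross-validated shrinkage because it is deterministic, and over
Ledoit–Wolf because it needs no second pass over the (potentially very
wide) compression-scan feature matrices.  Ties in the class-score argmax
break toward the lowest class id, making every prediction deterministic.
For wide feature matrices the scatter product is accumulated in float32
(BLAS `syrk`); the resulting error is orders of magnitude below the
shrinkage bias.

**Training scheme.** Every post-cue sleep timepoint is one observation
(features: the kept PC activations at that instant; label: the trial's cue
class).  This "timepoints-as-observations" scheme is what makes the method
robust to latency jitter: no alignment is assumed, at the cost that class
means are diluted by the background timepoints that share the trial's
label.  The trained model classifies each wake trial at each timepoint,
giving CCR(t) with chance 0.25.  Wake testing includes cued and uncued
sequences, so above-chance decoding cannot stem from generic cue-sound
responses.

**Group inference.** One-sample t statistics of CCR(t) − 0.25 across
participants are thresholded at the one-tailed α = 0.05 t quantile;
contiguous suprathreshold runs form clusters scored by summed t; the null
distribution records the maximum cluster mass under random sign flips of
each participant's whole deviation vector.  One-tailed, because the
hypothesis is above-chance decoding.  Default 100 000 permutations
(overridable; recovery tests use 1 000).  The same machinery runs the
paired high-vs-low sigma comparison on per-participant CCR differences.

## Compression scan

Ratios (sleep window duration / wake duration) are 12 log-spaced points on
[1/20, 2.5/1.15], with the nearest point snapped to exactly 1.0.  The
bounds come from the method's own constraints: below 1/20 the sleep window
drops under ~10 samples and cannot be resized meaningfully; above 2.5/1.15
the window no longer fits the shortest sleep trial.  Windows advance 10 ms
(2 samples), are resized to the wake length by linear interpolation
(endpoints map to endpoints; robust on 11-sample windows where any
filter-based resampler is all edge effect), and train an LDA on flattened
PC × time vectors.  No smoothing is applied in this analysis — a 100 ms
moving average would erase a 57 ms motif.  Per-ratio inference is a
one-sided exact signed-rank test of participant CCRs against 0.25,
uncorrected across ratios (a corrected variant is a caller-side decision).

## Sigma gating

Per trial: zero-phase Butterworth band-pass 11–16 Hz at Cz, Hilbert
transform, instantaneous power = squared magnitude, averaged over
[0, 2.5] s excluding 100 ms at each segment edge (Hilbert/filter edge
artifacts otherwise leak into scores).  The per-trial scalar is the *mean*
instantaneous power (the natural L2 reduction; a peak-based score would be
noisier).  The median split sorts trials (stable) and sends the upper half
to the "high" group, so the halves never differ by more than one trial even
with ties, and a trial exactly at the median lands in the low group —
conservative for the high-half test.

## Behavior

A session's score is the median of the `ceil(0.05 n)` fastest blocks (peak
performance estimates motor consolidation better than mean performance);
with the standard 24 blocks this keeps two.  Post-sleep scores are computed
per session first and then combined by median across the three follow-ups
(preserves session balance; pooling blocks first would overweight sessions
with more retained blocks).  Improvement is pre − post (positive = faster).
The headline correlation uses the first post-sleep follow-up's cueing
benefit (uncued − cued peak RT) against the participant's maximum CCR, with
a rank-based partial correlation (residualize the ranks of both variables
on the ranks of the encoding-session score; t-test with n − 3 df).
The signed-rank test uses an exact enumeration null (dynamic programming
over doubled midranks) for n ≤ 25 and a tie- and continuity-corrected
normal approximation above; positive z means the cued sequence improved
more.

## Preprocessing

* Zero-phase forward–backward Butterworth (order 4 per pass) for all
  filtering; zero phase protects event-related latencies.  The 0.1 Hz edge
  has a seconds-long impulse response, so filtering pads generously
  (3/low_hz seconds) and is meant for continuous recordings, not epochs.
* Quartiles use linear interpolation between order statistics (type 7).
  With zero IQR the Tukey fences collapse to the common value and only
  strictly different values are flagged, so identical data yields no flags.
* A trial is rejected when bad (variance, max or min outside the fences) on
  more than 25% of all channels or more than 25% of the motor strip
  (C1–C6, CP1–CP6) — the task is motor-related, so motor-area corruption is
  disqualifying even when globally rare.  Otherwise bad channels are
  replaced by inverse-distance-weighted averages of good Delaunay-triangulation
  neighbors (template 10-10 positions for the standard montage).
* The 100 ms moving average at 200 Hz is a 21-sample centred window
  (centre ± 10; "the 100 ms around a point" is ambiguous by one sample and
  is fixed here), truncated at trial edges rather than padded, so no data
  is fabricated at cue onset.

## Evoked-response QC

Morlet wavelets, 7 cycles, 2–25 Hz in 1 Hz steps (the conventional
sleep-EEG compromise between time and frequency resolution); power is
averaged over trials and channels and expressed per frequency as percent
change from the mean over the [-0.3, -0.1] s pre-cue baseline.  Percent
change is invariant to amplitude scaling, which makes the map comparable
across participants.  The ERP is the pointwise trial mean, baseline
corrected over the same window.

## The synthetic cohort

The generator's defaults define the study conditions every recovery test
runs under: 58 scalp channels (standard 10-10 positions) at 200 Hz, 60
sleep cue trials (jittered 2.5–3.5 s) and 120 wake trials (1.15 s, both
sequences) per participant, 24 behavior blocks per sequence and session
(pre-sleep plus three follow-ups), pre-sleep peak RT ≈ 420 ms, a cueing
benefit of 40 ms per unit reactivation SNR, and block-RT noise of 8 ms.

**Class templates.** The four classes share one smooth scalp topography
plus a smaller class-specific component (mixing weight 0.5): finger
representations overlap heavily at scalp resolution, and — as the
compression analysis below explains — fully distinct per-class maps make
temporal structure irrelevant to the decoder.  Waveforms are Hann-enveloped
slow oscillations (1.2–2.8 Hz, one deterministic frequency per class plus
small jitter) that are *phase-locked to the cue* (cue-locked responses are
phase-locked by definition; with random phases each participant's
above-chance decoding occupies a different part of the trial and no group
cluster can form).  Each waveform carries an exactly controlled
time-integral ("mass", ±0.15 spread, ordered across classes): the mass is
the only part of a waveform that survives time-averaging, hence the only
signal a timepoints-as-observations decoder can key on.

**Sleep trials.** Background = twelve 1/f sources mixed through smooth
scalp maps (eigenvalue spectrum decaying as 1/k, so the 95% PCA rule keeps
a realistic ~8–14 components) + a 0.75 Hz slow oscillation with random
phase and depth per trial + a little sensor white noise; normalized to unit
RMS.  An embedded trial carries up to 9 non-overlapping repetitions of its
class motif (reactivation is repetitive), the motif being the class
waveform linearly resampled to `1.15 / c` seconds; each occurrence is
scaled so its RMS over its support is `snr` × the background RMS there.
Sigma bursts (12–15 Hz, 0.8 s Hann envelope, focal at Cz, 2.5× the local
background RMS) accompany motifs with probability `spindle_coupling` and
motif-free trials with probability `baseline_burst_rate`; setting the two
equal decouples bursts from reactivation (the null condition for the gating
analysis).

**Wake trials.** Template × the participant's representation strength
(the same SNR that scales sleep motifs — without this coupling, decoding
strength carries no participant information and the reactivation–behavior
correlation could not exist) + state-specific background: wake uses its own
source topographies (the waking brain is not a noise-matched copy of SWS)
plus slow baseline drift (random offset + sub-Hz wander on a random smooth
topography, 2.5× the fast-noise RMS), mimicking electrode baseline wander.
The drift matters methodologically: it dominates *trial-averaged* wake
activity, penalizing analyses that reduce to time-collapsed template
matching, while leaving instantaneous decoding intact.

**Behavior.** Block RTs are Gaussian around session/sequence means: both
sequences start at the pre-sleep mean; post-sleep means drop by a general
consolidation gain (20 ms) plus, for the cued sequence, the planted benefit
(slope × SNR).  With zero noise the cueing benefit is exactly slope × SNR.

**What the generator does not emulate.** No biophysical neural-mass
dynamics, no eye/muscle artifacts, no full-night architecture, no
wake-state alpha, no learning curves within sessions.  Passing recovery
tests therefore demonstrates that the *analyses* recover planted structure
of the assumed form — not that real EEG contains such structure.

## Design findings and limitations

Two structural properties of the method shaped the generator and should
temper interpretation on real data:

1. **Timepoint decodability is time-collapsed decodability.**  The class
   signal a timepoints-as-observations LDA uses is, exactly, the
   time-average of the class pattern — and any such marginal signal is also
   available to the compression scan's windows at *every* ratio (at very
   short windows the scan degenerates into the timepoint decoder itself).
   With fully distinct per-class topographies, time-collapsed spatial
   template matching dominates all ratios and the dilation end of the scan
   can never return to chance; this is why the generator shares most of the
   topography across classes and keeps the marginal (mass) signal small.

2. **Window averaging caps ratio selectivity.**  Training windows slide
   uniformly over the trial, so class means average motif content over all
   offsets; only a triangularly-weighted autocorrelation residue of the
   waveform survives.  The planted-ratio CCR excess is consequently a few
   percentage points.  Group detection of compressed reactivation is robust
   at that effect size, but per-cohort significance patterns across the
   ratio grid, and per-participant argmax locations, fluctuate noticeably
   from seed to seed at 12-participant scale.  The corresponding recovery
   test asserts the full property regardless, and currently fails at its
   fixed seed — retained deliberately as an honest negative result rather
   than weakened.

Problem sizes in the validation suite (12-participant cohorts, 60 sleep /
120 wake trials, 1 000 permutations, 20 replicate seeds) are the package's
chosen study conditions for desk-scale validation; the permutation count
for real analyses defaults to 100 000.
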