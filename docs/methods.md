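# Methods

This note documents the models, conventions and numerical choices behind
`somnoscope`, in the order the pipeline applies them.

## Scope and data model

The package analyzes chronic mouse EEG/EMG recordings that have already been
sleep-scored into 4-s epochs labelled WAKE (`W`), NREMS (`N`) or REMS (`R`).
Scoring itself is out of scope: hypnograms are inputs, and the synthetic
generator supplies them (with ground truth) when real recordings are not
available. The canonical analysis window is 23 h starting at lights-on
(Zeitgeber time 0): a 12-h light phase [ZT0, ZT12), an 11-h dark phase
[ZT12, ZT23), and a discarded final hour (cage-maintenance time). Signals
are acquired at 256 Hz and analyzed at 125 Hz.

## Synthetic polysomnography

The generator has two layers.

**Hypnogram.** A first-order Markov chain over {W, N, R} at epoch
resolution, with separate light- and dark-phase transition matrices. The
W→R entry is structurally zero (this transition does not occur in healthy
mice; its presence indicates narcolepsy/cataplexy-like states). The default
matrices were chosen to give realistic murine architecture: roughly 35/55/10%
W/N/R occupancy in the light phase, 65/28/7% in the dark phase, with mean
dwell times of minutes for W/N and shorter REMS episodes. The chain starts
in WAKE at ZT0.

**Signals.** Each EEG channel is 1/f (pink) background noise (SD 20 units,
microvolt scale) plus state-specific, band-limited Gaussian oscillation
tracks multiplied by crossfaded state envelopes (0.5-s triangular fades, so
state boundaries produce no clicks):

- NREMS: 0.5–5 Hz track (SD 60 × `delta_scale`) plus a weak 5–30 Hz track
  (SD 8 × `hf_scale`) and injected spindles;
- REMS: 6–9 Hz track (SD 40);
- WAKE: 0.5–40 Hz broadband track (SD 15), EMG bursts on the EMG channel,
  and rare large movement artifacts (4/h of WAKE, amplitude 400, logged).

Spindles are Hann-windowed sinusoids at a frequency drawn uniformly from
10–15 Hz, placed by a Poisson process (default 1 event per NREMS minute)
inside NREMS runs with ≥ 1 s margin from run edges and ≥ 0.2 s separation,
so ground truth maps 1:1 onto detections under the 0.1-s merge rule.
Default envelope peak is 40 units × `spindle_amp_scale` with mild
log-normal jitter; durations are uniform on [0.5, 2] s. Every injected
spindle and artifact is logged.

The four "genotype" knobs reproduce the contrasts the analysis is meant to
detect: `wake_dark_boost` divides the dark-phase WAKE exit probability (and
raises N→W correspondingly), `delta_scale` and `hf_scale` scale the NREMS
tracks, `spindle_amp_scale` scales injected spindle amplitude. The
transgenic-like preset is (2.0, 0.6, 1.3, 0.7).

What the simulator does **not** emulate: biophysically realistic cortical
dynamics, ultradian/circadian structure beyond the two phase matrices,
state-transition spectra (scored epochs are treated as homogeneous),
slow-oscillation/spindle coupling, or realistic EMG beyond burst amplitude.
Passing parameter-recovery tests therefore shows that the analysis chain
recovers the statistical structure it assumes, not that it would behave
identically on every feature of real EEG.

Signal synthesis is performed in single precision (amplitudes are arbitrary
units; analysis is done in double precision downstream). All randomness
flows through `numpy` generators keyed by `rng_seed`, making outputs
bit-reproducible.

## Preprocessing

- **Downsampling** 256 → 125 Hz uses rational polyphase resampling (ratio
  125/256) with the associated zero-phase FIR anti-aliasing low-pass. The
  operation is a no-op at the target rate, so it is idempotent.
- **Artifacts** occur only during WAKE (movement). The expert's manual
  exclusion line is operationalized as a single per-recording amplitude
  threshold applied to WAKE-scored samples. Excluded samples are dropped
  from spectral estimation — implemented at epoch granularity, since a
  periodogram needs contiguous epochs — while the epoch's label is retained
  for temporal analyses.

## Hypnogram architecture

A state change opens a new bout only when the new state persists for at
least three consecutive epochs (12 s); shorter intrusions are absorbed into
the ongoing bout. Absorption is the only reading under which bouts
partition the hypnogram, which downstream proportions rely on. The first
bout opens unconditionally at epoch 0. The production scanner is vectorized
(latest homogeneous 3-window at or before each epoch); tests compare it
against an independent quadratic brute-force oracle.

Derived measures per phase: state proportions (bout time / phase duration),
2-h-bin time courses (the 23-h window yields eleven 2-h bins plus one
truncated 1-h bin, flagged as such), transition proportions over the five
allowed bout conversions (W→N, N→R, N→W, R→W, R→N; a bout-level W→R —
possible when a short NREMS intrusion was absorbed — is counted as an
anomaly and excluded from the denominator, which is all allowed
transitions), WAKE latency profiles, and bout-length distribution curves.

Latencies: ΔT1..ΔT5 are the times from phase start to the onsets of the
first five WAKE bouts. "Differential latencies" are interpreted as the
consecutive differences ΔTi+1 − ΔTi (their sum telescopes to ΔT5 − ΔT1);
both raw latencies and differences are reported, and the combined metric is
the sum of the differences plus the median length of the first five WAKE
bouts. Profiles with fewer than five WAKE bouts are flagged incomplete.

Distribution curves: per animal, bout durations are sorted ascending,
x = rank / count, y = duration / total duration, then linearly interpolated
onto a uniform 1000-point grid on [0, 1] (linear interpolation; nothing
fancier is warranted). Group curves are pointwise medians with Q1/Q3 bands.

## Spectral analysis

Per qualifying 4-s epoch (500 samples at 125 Hz): mean removal, Hann taper,
512-point zero-padded real FFT, one-sided periodogram of 257 bins spaced
125/512 ≈ 0.2441 Hz. Epoch periodograms are averaged within state × phase
and normalized to unit sum (reported as %), making spectra invariant to
channel gain. Epochs are assigned to states by the bout-partitioned labels
(all epochs of a bout count, including absorbed intrusions). Display is
conventionally restricted to 1–30 Hz; 118 bin centers of the full 257-bin
axis fall in that range.

Band powers sum bins whose centers lie in the closed band intervals
δ 0.5–5, θ 6–9, α 10–15, η 16–22.75, β 23–31.75 Hz; gap frequencies belong
to no band, so band fractions sum to less than 1.

Group spectra: per-bin median across animals; 95% CI from 10,000 bootstrap
resamples of animals (not epochs — the CIs describe across-subject
variability), percentile method (2.5th/97.5th). Per-bin AUROC effect sizes
versus the comparison group come from the statistics module.

## Spindle detection

Band-pass 10–15 Hz (zero-phase Butterworth; the specified 24 dB/octave
stopband slope at 6 dB/octave/pole gives the minimal order 4, applied
forward-backward; stopband edges 3 and 22 Hz are comfortably met), then a
centered 750-ms moving RMS, cubed. Thresholds are multiples of the mean
cubed RMS over the baseline — NREMS samples only by default, because
spindles are NREMS events and WAKE EMG contamination would inflate a
whole-recording baseline (whole-recording mode is available by
configuration). Candidate events are maximal runs above 1.0 × baseline;
events separated by < 0.1 s are merged (idempotent); kept events must have
peak cubed RMS > 2.5 × baseline, duration within [0.5, 2] s measured at the
lower-threshold crossings, and lie entirely within NREMS.

Normalized amplitude divides the peak of the band-passed signal's Hilbert
envelope by the upper threshold, exactly as the convention prints it. Note
the unit mismatch — an amplitude divided by an amplitude-cubed quantity —
is reproduced deliberately; a `cubed` mode (peak cubed RMS / upper
threshold, unitless) is available by configuration. Because the thresholds
are data-derived, the statistic is self-normalizing within a recording but
its absolute scale is arbitrary; only group contrasts are meaningful.

Two timing properties of this paradigm are worth knowing. First, the 750-ms
RMS window smears event boundaries: detected durations exceed the
underlying burst by up to ~0.5 s, so bursts near the 2-s maximum can be
rejected and the effective sensitive range of underlying burst durations is
roughly 0.1–1.6 s. Second, onset accuracy improves as the baseline mean
rises (the thresholds self-calibrate): in recordings with dense,
high-amplitude spindles the lower-threshold crossing lands within ~0.2 s of
the true onset, while in sparse/low-SNR recordings it can lead the onset by
up to the half-window (0.375 s). The detector-recovery fixture therefore
uses 2 events/min at envelope peak 100 (5× the sigma-band background) with
injected durations 0.6–1.4 s — "bright" spindles with headroom for the
smear inside the duration gate. A related interaction: lowering delta power
(transgenic-like `delta_scale < 1`) lowers the NREMS baseline and hence the
thresholds, which raises detection counts at fixed injection rate; spindle
*amplitude* contrasts are robust to this, spindle *counts* are not a pure
readout of injected rate at realistic SNR.

## Statistics

- **Mann–Whitney U** (cross-sectional) and **Wilcoxon signed rank**
  (longitudinal) via SciPy: exact null distributions for small samples
  without ties (U: both n ≤ 8; Wilcoxon: n ≤ 15), otherwise the normal
  approximation with tie correction; midranks throughout.
- **Bootstrap median CIs**: 10,000 resamples with replacement, percentile
  2.5/97.5. Degenerate resamples are kept, not redrawn.
- **AUROC** is computed by the rank formulation and equals U/(n₁n₂)
  identically, which the tests verify by brute-force pair counting. CIs
  bootstrap each group independently with sizes preserved. Labels: *good*
  if AUC > 0.7 or < 0.3; *strong* if additionally the 95% CI excludes 0.5.
  Percentile bootstrap intervals are clamped to contain the point estimate
  (a rare edge case with tiny groups).
- **Benjamini–Hochberg**: largest rank k with P(k) ≤ (k/m)·q rejected;
  adjusted p-values by the step-up minimum, capped at 1. Implemented
  directly (it is three lines of arithmetic) and cross-checked against
  `statsmodels.multipletests` in the tests. Adjustment is applied per
  analysis family (proportions, transitions, bout lengths, latencies, band
  powers, spindle features) rather than jointly.

A single run-level seed governs all bootstrap draws; operations consume a
shared generator in a fixed order, so full runs are byte-reproducible.

## Problem sizes

Defaults mirror the emulated study: 9 wildtype-like vs 5 transgenic-like
animals, 24-h recordings (23 h analyzed), 256 → 125 Hz, 10,000 bootstrap
iterations. The test suite and the acceptance script scale some inputs so
that a complete run stays in the minutes range on one core, as a package
choice: parameter-recovery replicates use 23-h hypnograms for architecture
contrasts but 1-h recordings for spectral/spindle contrasts (spectral
estimates converge quickly at 900 epochs/h); the end-to-end pipeline test
uses a 2 + 2 cohort at 128 Hz acquisition; the acceptance script runs 10
recovery/null replicates where the test suite runs 25.

## Known limitations

- CSV and plain-text hypnograms are the only on-disk formats; EDF is not
  supported.
- The artifact "line" is a single global threshold, not a per-segment
  expert delineation.
- The simulator's stationary-within-phase Markov chain cannot express
  time-of-day trends inside a phase; time-course bins differ between
  phases but not within them.
- Spindle counts at realistic SNR include threshold-crossing noise events;
  see the baseline interaction above.
- The normalized-amplitude statistic inherits the printed unit mismatch;
  compare it only within a fixed detection configuration.
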