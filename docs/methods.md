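# Methods

This note documents the models, parameter choices and known limitations of
the package, in the order data flows through it.

## Synthetic data model

The generator (`spatiodyn.synth`) produces parcellated BOLD-like series
with a planted, fully known quasi-periodic pattern so that every downstream
stage has a recovery target.

**Parcellation.** 246 ROIs in contiguous blocks over eight networks —
SCN 39, LIM 26, SMN 33, VIS 34, VAN 22, DAN 30, FPN 26, DMN 36 — plus the
derived task-positive union TPN = DAN ∪ FPN (56 ROIs). Seven counts follow
the canonical atlas grouping; the limbic count of 26 is the remainder that
brings the total to 246 and is an assumption, not an atlas fact.

**Template.** Each ROI row is one period of a Hann-windowed cosine,
`hann(m) · cos(2π m / W − θ_β)`, mean-removed. The per-ROI phase θ_β folds
together two things:

* *propagation*: network phases are spaced `max_phase_lag / 8` along the
  ordering FPN → DAN → VAN → SMN → VIS → DMN → SCN → LIM (task-positive
  regions lead, the DMN trails, subcortical/limbic regions anchor the late
  phase). The spacing makes the DMN–DAN propagation lag exactly half the
  maximal lag. `standing` mode sets all propagation phases to zero.
* *polarity*: the anti-correlation of the DMN-aligned group (DMN, SCN, LIM)
  with the task-positive/sensory group (FPN, DAN, VAN, SMN, VIS) is a π
  phase offset, not a multiplicative sign. Folding polarity into the phase
  keeps every row a positively-enveloped cosine, so the planted
  `phase_of_roi` is directly comparable with a phase-delay map
  (`arg U ≈ −phase_of_roi`); with a sign flip, peak positions and phases
  would decouple.

Phases are referenced to the DMN so the DMN-mean row has its trough exactly
at the window centre — the display convention the QPP literature uses and
the anchor the detection stage aligns to. Defaults: W = 24 s at the
configured TR, `max_phase_lag = π/2`, traveling.

**Events.** Quasi-periodic, not periodic: a regular grid at the mean
inter-event interval (default 45 s, inside the 30–60 s occurrence range
typical of these patterns) with uniform jitter bounded so that spacing never
drops below one window. Occurrences are added into a zero background over
half-open windows `[t, t + W)`.

**Noise.** Independent per-ROI AR(1) with coefficient 0.3 and stationary
SD set by the SNR, defined as (template RMS over its support) / noise SD;
default SNR 1. The generator does **not** model cross-ROI noise
correlation, physiological (cardiac/respiratory) rhythms, scanner drift, or
spatial smoothness. Consequently, passing recovery tests show the
algorithms are correct and seed-stable under autocorrelated noise at
realistic SNR; they do not show robustness to structured artefacts in real
acquisitions.

**Determinism.** Everything derives from `(config, seed)` through
`numpy.random.default_rng`; the noise stream uses a child seed so planting
and noise are separately reproducible.

## Preprocessing

Decimation (every k-th sample, no anti-alias filter — deliberately, since
it emulates *acquiring* at a longer TR) is applied to raw series before any
filtering, so filters are designed at the new rate. Band-limiting is a
2nd-order Butterworth applied forward–backward (zero phase, so event and
lag estimates are not biased); supported bands are Slow-5 (0.01–0.027 Hz),
Slow-4 (0.027–0.073 Hz), Infraslow (0.01–0.10 Hz) and Infraslow+
(0.01–0.15 Hz). A band whose upper edge reaches Nyquist at the current TR
is an error, never silently clipped. A filtfilt'd 2nd-order Butterworth has
gain 0.25 at the band edges; gain contracts (≥ 0.9 passband, ≤ 0.1
stopband) therefore refer to interior band frequencies, measured on the
interior 80 % of long sinusoids to avoid filter transients. Global signal
regression residualises each row on `[1, g]` with `g` the across-ROI mean;
z-scoring uses population SD. Network aggregation emits rows in the fixed
order SCN, LIM, SMN, VIS, VAN, DAN, FPN, (TPN,) DMN.

## QPP detection

`detect_qpp` runs the iterative matching from `n_starts = 20` seeded random
start windows and keeps the solution with the largest summed correlation
over its matched maxima. Numerical choices:

* **Thresholds** 0.1 (iterations 1–3) / 0.2 (after), the convention of the
  sliding-template literature; both config-exposed.
* **Convergence** when successive correlation time courses correlate
  ≥ 0.9999, max 20 iterations.
* **Extrema separation**: within each event list, peaks closer than one
  full window W are thinned greedily, keeping the larger |c|. Two
  non-overlapping occurrences of a W-long pattern cannot start closer than
  W apart; a smaller radius (e.g. W/2) admits duplicate events from windows
  that straddle the tail of one occurrence and the head of the next —
  empirically these straddling windows correlate 0.3–0.5 with the template
  even on noiseless data.
* **Phase anchoring.** The iteration's fixed points are translations of
  the pattern: starting off-phase converges to a consistently offset event
  set and a truncated template. The winner is therefore re-anchored by
  shifting its events by the offset of the DMN-mean row's trough from the
  window centre and rebuilding the template from the data windows there.
  Anchoring in data space keeps the template a true window mean; a circular
  roll would match no contiguous window of the data and demonstrably
  degrades the correlation time course.
* Zero-variance windows get c(t) = 0 (logged); sliding correlation is
  FFT-based and clipped into [−1, 1] against rounding.
* Window-length expansion and secondary (regressed-out) patterns are out of
  scope: only the dominant pattern is detected.

## cPCA

Analytic signals are computed on mean-removed rows; rows are normalised to
unit RMS before the complex correlation (flag `normalize`, default on) so R
has unit diagonal and results are amplitude-scale-free. R is symmetrised to
exact Hermitian form before the SVD. The SVD's arbitrary per-component
phase is gauged by rotating each component so its largest-modulus entry is
real-positive, making runs reproducible. Both phase outputs are exposed:
the spatial phase-delay map `arg U` (used for all spatial comparisons) and
the temporal `φ_n(t) = arg A_n(t)`. Phase-based assertions exclude the
first/last 10 % of samples, where the analytic signal's edge effects live.
Component-to-template reconstruction renders one cycle,
`σ_k · Re(U e^{i 2π m / W})`; it is a single-harmonic rendering, so its
correlation with a windowed (multi-harmonic) template tops out near 0.89
even for perfect phase recovery.

## Comparison metrics

Event matching in the MJI-with-cushion and the precursor analysis is the
sorted two-pointer greedy sweep, which attains the maximum one-to-one
matching under an interval tolerance on sorted 1-D sets; the test suite
verifies this exhaustively against brute force. Matching is within event
type only (maxima to maxima, minima to minima). Two empty sets score
MJI = 1; a precursor analysis with no matched pairs returns an undefined
marker rather than 0. Defaults: cushion ±8 timepoints with a ±16
sensitivity setting. The precursor sign convention is (b − a) with a the
reference condition.

Templates detected at different TRs are compared after periodic linear
resampling onto the finer cycle grid, maximising Pearson correlation over
circular shifts.

Stability curves GSR + z-score each scan before concatenation (so scan
boundaries introduce no steps), truncate to `floor(duration / TR)` samples
per level, and report the mean and across-group SD of the DMN profile;
durations shorter than two windows are skipped with a warning. Windows
crossing scan boundaries are permitted.

## Statistics

Mid-ranks everywhere; Wilcoxon drops zero differences. Exact p-values below
the switchover sizes (Wilcoxon n ≤ 12; Mann–Whitney min(n) ≤ 8 on tie-free
data), asymptotic above. Kruskal–Wallis on all-identical data returns
H = 0, p = 1 by convention. Dunn's z-tests use pooled mid-ranks with tie
correction and report both the raw and the Bonferroni-adjusted p
(m = k(k−1)/2); calibration checks of the nominal level use the raw p,
since the adjusted p is conservative by construction. Accounting
conversions to hours use exact decimal arithmetic rounded half-up to two
decimals, matching tabular presentation.

## Sweeps and problem sizes

Each sweep level × replicate regenerates an independent cohort (distinct
seed), mirroring designs with non-overlapping subject groups; the window
length is held at 24 s across TR levels and reconverted to points per
level. Infeasible levels (band ≥ Nyquist at the level's TR) are recorded
in the report with a reason string. GSR defaults off in the sweeps: the
planted pattern already carries the anti-correlated structure GSR is meant
to expose, and leaving the generator's output untouched keeps recovery
metrics interpretable against the known truth.

Default experiment sizes — 246 ROIs × 1200 timepoints per scan, 5 seeds for
recovery, 5 cohorts × 5 groups × 3 scans for stability, decimation factors
1–5 — were chosen so each recovery quantity is estimated from ≈ 20 planted
events per scan and the full suite runs comfortably on a laptop. The
scan-length stability check in `scripts/acceptance.py` runs the cPCA path
(the trend being measured is method-agnostic and cPCA is the cheaper
estimator); the analysis driver reports both methods.

## Known limitations

* Synthetic noise is spatially independent; real BOLD noise is not.
* Only the dominant pattern is modelled and detected; real data carry
  secondary patterns and global events.
* The cPCA reconstruction is single-harmonic (see above), bounding
  attainable cross-method template correlations below 1 by construction.
* The stability SD on synthetic cohorts is far smaller than on real
  subject groups, because between-group variability here is only noise and
  event-placement jitter, not subject physiology.
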