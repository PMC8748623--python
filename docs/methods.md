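# Methods

This note documents the models, estimators and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Experiment model

A dataset is an ordered list of daily sessions, each labeled with a
training phase (`pre`, `I`–`IV`). Every session contains a passive
fixation block (all nine 3×3-grid stimulus locations, 1.5 s delays, no
choice targets) followed — from phase I on — by an active
match/nonmatch block. Active phases I–II present the cue only at the
right location with the nonmatch sample at the left; phase III
generalizes to all nine locations with diametric nonmatch samples;
phase IV draws both delays per trial uniformly from 0.25–1.5 s, in
tandem. Event times are stored in seconds from trial start; all
aligned analyses place cue onset at *t* = 0. Spike times are ragged
per-trial arrays (float64); LFP traces are float32 at ≥ 500 Hz.
Binned counts always use half-open windows `[t, t+Δ)`.

Timing defaults: 1.0 s fixation, 0.5 s cue and sample (stimulus
durations are not constrained by the design itself, so they are
declared configuration, not inference), 0.25 s delays in active phases
I–III, and a 0.5 s recorded tail after the last delay.

## Synthetic generator

Spiking is an inhomogeneous Poisson process, sampled by thinning a
homogeneous process at the per-trial peak intensity:

    λ(t) = g · [ b · m(t) + ramp(t) ]

* `b` — baseline rate (spikes/s).
* `m(t)` — epoch multiplier: `1 + cue_gain·w` during the cue,
  `1 + delay_gain·w` during the first delay, and a match/nonmatch
  multiplier during and after the second stimulus. The tuning weight
  `w = exp(κ(cos(θ_loc − θ_pref) − 1))` is a von-Mises kernel over the
  eight peripheral location angles; the center location is untuned,
  mirroring its exclusion from decoding. Only units drawn "responsive"
  for that task (per-phase responsive fraction) are tuned.
* `ramp(t)` — a linear climb of the scheduled slope from cue offset to
  choice-target onset, present in active phases I–III and zero in
  phase IV, where randomized delays abolish anticipatory ramping.
* `g` — a per-trial, per-unit shared multiplicative gain:
  `log g ~ N(−σ²/2, Σ)` with `Σ_ij = σ² exp(−d_ij / L)` over
  inter-electrode distances, giving unit-mean gains whose correlation
  decays exponentially with distance. This one mechanism produces both
  the level of spike-count noise correlation (via σ, scheduled per
  phase and task) and its distance dependence (via `L`, default 1 mm).
  A multiplicative shared gain was chosen over common-input spiking
  because it parameterizes the Pearson-correlation target directly.

Match information is planted only in the active task: a unit with
match preference `s = ±1` multiplies its rate after second-stimulus
onset by `1 + strength·(1 + s·m)/2`, `m = ±1` for match/nonmatch.

LFP is a 1/f-amplitude Gaussian background plus band-limited
oscillations (alpha 8–14, beta 20–45, gamma 46–70 Hz) whose amplitude
during the cue epoch is raised by the scheduled per-band factor, plus
an optional 60 Hz line term for exercising line removal.

The default effect schedule encodes the study conditions the pipeline
must recover: responsive fraction and epoch gains rising over active
phases (≈ 0.35 → 0.50), delay ramping in phases I–III only, shared-gain
σ dropping in phases III–IV (0.35 → 0.20 active) with passive values
slightly higher than active, beta cue-amplitude declining
(1.0 → 0.35) while alpha rises, and match information present only in
the active task. Where the training design itself fixes no number
(e.g. baseline rates of ~5–8 spikes/s, 85% behavioral accuracy), the
defaults are ordinary values for prefrontal multi-unit recordings and
are configurable.

What the generator does **not** emulate: refractoriness and spike-sorting
artifacts (irrelevant to rate-based analyses), eye movements, error-trial
structure beyond the correct/incorrect label, slow nonstationarities
within a session, and spike–field coupling. Passing tests therefore
demonstrate that the estimators recover effects of the planted form and
magnitude, not that real recordings satisfy those forms.

Determinism: a master seed spawns per-session seed sequences, which
spawn independent streams for trials, unit parameters, shared gains,
per-unit spiking and per-electrode LFP, so identical configurations
regenerate byte-identical datasets (HDF5 written without timestamps).

## Responsiveness screening

Multi-location blocks: one-way ANOVA of epoch rate across cue
locations, run separately on the cue and first-delay epochs;
responsive iff either p < α (default 0.05). Single-location blocks
(early active training): paired t-test of cue (and delay1) rate
against the fixation rate; the rate must be elevated, and multi-unit
records must additionally show ≥ 10% increase during the stimulus
presentation — single units are exempt. The 10% gate is applied to the
cue epoch only, a literal reading of the stated rule; whether it also
gated the delay path in the original analysis is unknowable from the
text, so the choice is isolated in one operation. Zero-variance
(degenerate) rate vectors yield p = 1 rather than an error; units with
too few trials are "unevaluable", distinct from "unresponsive". The
two-epoch OR-rule implies a null flag rate near `1 − (1−α)² ≈ 0.0975`,
which the suite verifies by simulation.

## Noise correlation

Counts are taken exclusively from the 1 s fixation epoch, which is
identical across tasks and phases, so no per-condition z-scoring is
needed. Pairs require ≥ 20 trials (the minimum is configurable; the
procedure's source leaves it unstated) and a non-constant count vector
— undefined correlations exclude the pair rather than contributing
r = 0. Phase comparison: OLS ANCOVA `r ~ C(phase) + distance_mm` with
the F-test on the phase factor, distance entering untransformed;
same-electrode pairs additionally get a 2-way phase × task factorial.
Display binning groups distances as {0, 0.75, 1.06–1.5, > 1.5} mm;
statistics always use continuous distance.

## Signals

MUA events are negative crossings of −3.5 × RMS of the 500 Hz–8 kHz
zero-phase-filtered broadband trace, with a 1 ms dead time. The
crossing rate on pure noise is validated against the Rice level-crossing
rate computed from the filter's spectral moments (with the dead time
disabled for that comparison, since Rice's formula counts re-crossings
within a single ringing excursion, and at high sampling so brief
excursions are not lost to the sample grid).

LFP preprocessing: zero-phase Butterworth bandpass 0.5–200 Hz and a
60 Hz notch (Q = 30). Channel quality control is a robust z-score on
log channel variance (median/MAD, |z| > 3 excluded, both tails — dead
channels are low-side outliers); the underlying published procedure
names only "a generalized linear model", so this concrete rule is a
declared implementation isolated behind one operation. Note that with
30–60 channels a 3σ rule still false-flags *some* channel in roughly
10–25% of null sessions; the tests assert the honest calibration (mean
flagged fraction ≪ α, planted outliers flagged exactly) rather than a
near-zero family-wise rate no threshold rule can deliver.

Spectral estimation: sliding-window multitaper with DPSS tapers
(window 0.5 s, step 0.05 s, NW = 3, 5 tapers — declared defaults, the
source names a toolbox but no parameters), scaled so the PSD integral
matches signal variance (checked against a Parseval identity and an
averaged-periodogram oracle). Band time courses subtract the mean
fixation-baseline power at each frequency (additive subtraction, not a
dB ratio; a ratio mode would be a one-line change) and then average
within the band; session values average across kept electrodes and
trials, and phases are compared by one-way ANOVA treating one session
as one observation. Trials of unequal duration are averaged over their
common window grid.

## Decoding

Pseudo-populations draw, per unit and condition, k trials without
replacement and permute them independently per unit, which is exactly
the "random matching" that discards cross-unit simultaneity. Units
short of k trials in any condition are excluded before sampling; if
fewer eligible units remain than requested, sampling is with
replacement. Per 500 ms bin (50 ms steps), accuracy comes from
stratified 10-fold cross-validation repeated 5 times; features are
z-scored with training-fold statistics only, and features with zero
training variance are dropped per fold. The whole procedure repeats
over fresh pseudo-populations, giving `repeats × resamples` accuracy
samples per comparison (500 at the reference setting of 5 × 100). The
classifier is the maximum-correlation-coefficient rule — nearest class
centroid under Pearson correlation — the conventional default of
pseudo-population decoding toolboxes; it is isolated behind one
function so a regularized discriminant can be swapped in. Shuffle
nulls permute labels once per resample before the identical procedure;
significance flags bins whose mean actual accuracy leaves the null
2.5–97.5 percentile band, with a two-sample z-test p alongside.

Two calibration facts discovered while testing are worth recording.
First, z-scoring with full-data (label-blind) statistics does *not*
bias shuffled-label accuracy for this classifier — normalization that
ignores labels cannot move chance — so the suite's leakage negative
control instead normalizes each class with statistics computed from
all of that class's data (a genuine label leak), which destroys
calibration dramatically. Second, with few pseudo-trials the
between-resample spread of shuffled accuracy is large (s.d. up to
~0.19 for binary labels at 20 trials), so chance-calibration checks
use enough resamples and trials per condition to push the Monte-Carlo
standard error well below the ±1-percentage-point tolerance being
asserted; this is an estimator-precision choice, not an effect-size
one.

## dPCA

The trial-averaged tensor (units × 8 stimuli × 2 decisions × time) is
centered per unit and split additively into time, stimulus × time,
decision × time and interaction marginalizations, which sum exactly to
the centered tensor and are mutually orthogonal for balanced designs.
For each marginalization, the decoder/encoder pair solves a
ridge-penalized reduced-rank regression of that marginalization onto
the full centered data: `W = X_φ Xᵀ (X Xᵀ + λI)⁻¹`, rank-reduced by the
SVD of `W X`, encoder orthonormal. λ defaults to 10⁻⁶ × total variance
(the source reports none); with a single nonzero marginalization and
λ = 0 the components reduce to PCA of that marginalization, which the
suite verifies to machine precision. Explained-variance shares are
reported per component against total centered variance; the passive
task's decision factor is fit from the match/nonmatch label even
though no behavioral decision occurs, so "decision components are
virtually absent in passive" is a recoverable statement.

## Sliding three-way ANOVA

Per unit and 200 ms / 50 ms bin, binned rates are fit by a linear
model with main effects of cue location, sample location and decision
(match/nonmatch); each factor is tested by a drop-one-factor F test
(Type II). Interactions are omitted deliberately: the match label is a
deterministic function of the two locations, so a fully crossed model
is aliased. In the diametric design even the main-effects model is
*partially* aliased — cue and sample each contribute only 4 effective
degrees of freedom beyond the other factors — so degrees of freedom
are derived from numerical ranks (SVD with rank truncation; an
unpivoted-QR implementation was found to project onto too large a
subspace and inflate F). With rank-derived dfs the null flag rate per
factor is calibrated at α in both full-rank and partially aliased
designs, verified against a statsmodels Type-II oracle on full-rank
designs and by simulation on aliased ones. A factor with a single
observed level is dropped for that unit (NaN p-values) rather than
discarding the unit.

The selective fraction per bin is compared to the 5% chance level by
an exact two-sided binomial test in the "minlike" convention — the
p-value sums the probabilities of all outcomes no more likely than the
observed count — verified against direct pmf enumeration.

## Pipeline, problem sizes and limitations

`run_pipeline` executes, per phase × task: screening and responsive
fractions, baseline-subtracted population PSTHs at each unit's best
location, daily location-rate maps, location and match decoding with
shuffle-null bands, the noise-correlation table with ANCOVA and the
same-electrode factorial, band-power session series with phase ANOVAs,
and dPCA variance tables. Every figure-level result is a CSV/JSON
table so numerics are testable without image comparison; reports are a
pure function of (dataset, config) and byte-identical across re-runs
with the same seed.

The shipped demo and test configurations run at reduced scale — tens
of units, a handful of sessions per phase, 10–150 decoding resamples —
chosen so the full suite and demo complete in about a minute on one
CPU while every planted contrast remains statistically recoverable;
all sizes scale up through configuration alone. Known limitations:
responsiveness screening power (and hence detected fractions) depends
on trials per condition, so small demos under-detect the planted
responsive fraction; shuffle-null percentile bands are coarse below
~20 resamples (a warning is emitted); and the dPCA fit assumes
balanced condition averages — unbalanced cells must be dropped or
imputed upstream.
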