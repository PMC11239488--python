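# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data do and
do not establish about real recordings.

## Photometry model and correction

The recorded channels are modeled as

    control(t) = S(t) + ε_c(t),          S(t) = bleach(t) · (1 + m(t))
    signal(t)  = F₀(t) · (1 + T(t)) + ε_s(t),   F₀(t) = β₁·S(t) + β₀

with a single shared exponential bleach `bleach(t) = c₀ + a·e^(−t/τ)`
(defaults c₀ = 100, a = 30, τ = 600 s in arbitrary fluorescence units), a
shared slow multiplicative motion term m(t) (Gaussian noise smoothed at
0.5 s, s.d. 0.005), independent sensor noise per channel (s.d. 0.3), and a
transient term T(t) in ΔF/F units. This is the simplest structure that
makes isosbestic regression non-trivial (bleach and motion must actually be
regressed out) while keeping the noise-free signal exactly affine in the
noise-free control — which requires the two channels to share one bleach
time constant; the per-channel amplitudes live in the affine map (β₁ = 1.8,
β₀ = 10 by default). Channels bleaching at genuinely different rates are
not exactly affine and are outside the generator's scope.

Transients are difference-of-exponentials kernels
`(1 − e^(−t/rise)) · e^(−t/decay)`, peak-normalized **on the sampling
grid** so an injected amplitude equals the maximum sampled ΔF/F exactly
(continuous-time normalization would undershoot the peak by up to ~10⁻³ at
20 Hz). Defaults: rise 0.2 s for all events; decay 1.0 / 1.5 / 3.0 s and
amplitude 0.03 / 0.08 / 0.09 ΔF/F for 20-Hz stimulation, 50-Hz stimulation
and food — chosen once to reproduce the qualitative ordering of evoked
release (20 Hz < 50 Hz ≤ food, food most prolonged) at a realistic ~3–9%
ΔF/F scale. Sessions default to 40 min, five events per type, ITIs jittered
±25% around 2 min, events ordered so no type repeats more than twice in a
row.

Correction regresses the signal on the control (OLS) after discarding the
first 60 s and uses the fitted trace as F₀; ΔF/F = (signal − F₀)/F₀.
Dividing by the fitted control is the standard convention that makes ΔF/F
dimensionless; dividing by a session median is a reasonable alternative the
package deliberately does not implement. One numerical caveat is inherent
to the method: the transients themselves sit in the regression, so the
fitted F₀ absorbs a small fraction of them (measured ≈ 2·10⁻³ relative
error on a realistic noise-free session — harmless next to sensor noise,
but not exact). `correct_trace(..., exclude_windows=...)` can mask known
event spans out of the fit (the ΔF/F is still computed everywhere); the
exact-recovery tests use this masked fit, and analyses needing
machine-precision amplitude recovery should too. The default remains the
plain full-trace fit.

Trial extraction z-scores each trial on the half-open baseline [−5, 0) s
(the event sample is never baseline; masks are computed on the integer
sample grid so float rounding cannot shift the window). Trials without full
[−pre, +post] support are excluded, logged, and listed in
`TrialMatrix.dropped` — never silently. A zero-s.d. baseline raises an
error naming the trial. AUC is the trapezoid rule on the native 20-Hz grid
over [0, 3] s; no resampling or smoothing anywhere.

The AUC comparison fits `auc ~ event + (1 | rat)` by maximum likelihood
(statsmodels MixedLM; lbfgs with fallbacks, default convergence tolerances).
With all-equal responses the model is singular and the effect is reported
as exactly 0 with p = 1; with a single subject the random intercept is
unidentifiable and an explicit `allow_single_subject=True` switches to OLS.

## Resampling statistics

Bootstrap: trials resampled with replacement (B = 1000 by default — chosen
to mirror the permutation count; the CI is percentile, not BCa, matching
the simplicity of the waveform-analysis tradition). Significance mask: the
(1 − α) CI excludes zero. Permutation: trial labels shuffled across the
pooled trials (n_perm = 1000), two-sided add-one p =
(1 + #{|null| ≥ |obs|})/(n_perm + 1), so p is floored at 1/(n_perm+1) and
never 0. An exact mode enumerates all C(n_a+n_b, n_a) relabelings (identity
included, so no correction is needed); a stratified option shuffles only
within each subject's trials and is off by default, since the canonical
procedure shuffles the pooled data.

Window rule: run duration is run_length × dt, so at 20 Hz 0.2 s ↔ 4
samples. "More than 0.2 s" (bootstrap) means strictly greater — ≥ 5
samples; "at least 0.2 s" (permutation) means ≥ 4 samples. Both thresholds
and both conventions are arguments of `find_windows` and of the two
procedures. Under a pure-noise null the consecutive rule suppresses the
pointwise 5% error rate to a measured family-wise any-window rate of ≲ 2%
(the tests bound it at 15%). No cluster-mass or max-T correction is
applied beyond this rule.

## Spike metrics

Response windows are half-open [onset, onset + 15 ms); a spike is credited
to at most one pulse (the earliest containing window — at 20/50 Hz windows
are disjoint, so this only matters for pathological inputs). Fidelity is
the mean of the per-pulse responses by definition, and the first/last-five
split requires ≥ 10 pulses. The train rate counts all spikes in [0, 1 s)
regardless of pulse locking; spontaneous spikes are not excluded from rate
or latency computations (only fidelity uses windowed detection). Latency to
the 10th spike is the 10th observed latency, or, with fewer than 10 spikes,
the OLS prediction of latency at ordinal 10 from all observed
(ordinal, latency) pairs — the simplest regression consistent with
"expected latency", and exact on linear spike sequences. All latencies are
measured from the first pulse onset.

The evoked-spike generator gives pulse k (0-based) a response probability
p₀·decay^k with truncated-normal latencies (mean 6 ms, s.d. 2 ms) inside
the 15-ms window, plus a 2-Hz homogeneous Poisson background (a typical
tonic dopamine rate; purely a fixture choice). Frequency presets
p₀ = 0.95, decay = 0.99 (20 Hz) and p₀ = 0.90, decay = 0.95 (50 Hz) were
chosen once so that the generated data reproduce the qualitative
electrophysiology: higher per-pulse fidelity at 20 Hz, a fidelity gap that
widens toward the end of the train, a similar *total* number of spikes per
1-s train (~17 evoked at 20 Hz vs ~16 at 50 Hz), and a shorter latency to
the 10th spike at 50 Hz (~0.33 s vs ~0.45 s).

## Behavioral simulation and scoring

Schedules are i.i.d. Bernoulli per press — CRF/FR1 p = 1, RR5 p = 0.2,
RR10 p = 0.1 — the defining probabilities, not drawn ratios. An
instrumental session is four blocks alternating levers (L, R, L, R; two
10-min blocks per lever) separated by 2.5-min time-outs; a lever retracts
immediately at its 20th press of a block. Under continuous reinforcement a
saturating agent therefore earns exactly 20 rewards per block = 40 per
lever per session, which the acceptance script recomputes. The transfer
test is 8 min of extinction followed by the fixed seven-cue sequence
clicker–noise–noise–clicker–noise–clicker–clicker (2-min cues, fixed 3-min
ITIs, both levers out, no rewards); the order is a structural invariant,
never shuffled. Pavlovian sessions deliver four presentations of each 2-min
cue with four rewards at random times within the cue and ITIs jittered
around 5 min. Agents press as Poisson processes per lever (optionally
multiplied during cues) or deterministically at a fixed cadence
("saturating", default 2 s — any cadence that fits 20 presses in 10 min
yields the same reward count); port entries are alternating in/out pairs
with exponential dwell times.

Scoring: the transfer-test baseline is the 2 min immediately before each
cue onset (matching the cue duration; configurable). Aggregation across the
three test sessions supports both all-trials pooling (default) and
session-means-first; neither is asserted as canonical. The elevation ratio
is (X − baseline)/(X + baseline) with 0/0 defined as 0. The
self-stimulation/unblocking correlation is Pearson's r between
log(x + 1)-transformed presses (first 5 min) and the ratio, one-tailed for
the declared directional hypothesis; directional tests always require an
explicit direction argument — there is no default tail anywhere.

The mixed-design RM-ANOVA is computed from first-principles sums of
squares: between effect against subjects-within-groups, within effect and
interaction against the within × subject residual. The within design must
be balanced (hard error otherwise); unequal group sizes use weighted-means
sums of squares, which agrees with pingouin's `mixed_anova` to machine
precision on the designs tested (pingouin serves as an independent
cross-check in the tests, never as the implementation). Constant data
yield F = 0, p = 1 rather than 0/0. Simple effects re-test one factor at a
fixed level of the other (one-way RM or one-way between ANOVA as
appropriate), with no multiplicity correction — they are treated as
planned and orthogonal.

Post hoc power converts partial η² to Cohen's f = √(η²/(1 − η²)) and
evaluates the noncentral-F tail with λ = f²·N, df₁ = k − 1,
df₂ = N − k. This is the generic convention; nonsphericity corrections of
dedicated power calculators are not reproduced — at f = 2 (η² = 0.8) the
power saturates (> 0.999 at N = 11, two groups) regardless.

## Files, configs, provenance

All on-disk times are seconds, 0-based from session start, half-open
intervals throughout; CSV everywhere (desk-scale data, inspectability
preferred). Readers validate the header, report malformed rows by line
number, re-sort out-of-order timestamps with a warning, and reject
duplicate trial rows. Writers can prepend `# key=value` provenance
comments; pipeline outputs always embed the config hash (over the
analysis-relevant fields, excluding the output directory) and the seed.
Configs are strict YAML: unknown keys are rejected and a seed is mandatory.
CLI exit codes: 0 success, 2 config error, 3 data error.

## Problem sizes in the test suite

Simulation-based tests use: 500 replicate datasets for the resampling
calibrations (n = 10 trials per group; 161 timepoints for the bootstrap
family-wise check, 20 for the pointwise permutation check with
n_perm = 199), 200 replicates for mixed-model recovery (3 rats × 10 trials
per event), 500 replicates for the ANOVA power check and the label-permuted
type-I check, 2,000 replicates for the correlation calibration (n = 9
pairs), and 40 seeded default sessions for the release-ordering check. The
full suite runs in under a minute on one CPU.

## What the synthetic data do not show

The generators match the *statistical structure* the analyses assume —
shared bleach/motion, event-locked kernels, decaying per-pulse fidelity,
Bernoulli schedules, Poisson pressing. They do not emulate hemodynamic or
pH artifacts, sensor saturation, non-exponential bleaching, electrical
artifact contamination of spike sorting, satiety or within-session learning
dynamics, or any biophysical model of dopamine release. Passing tests
therefore certify the pipeline's arithmetic and calibration, not the
validity of those assumptions for any particular recording. Real data with
channels bleaching at different rates, or with motion that is not shared
multiplicatively, will leave residual artifacts that isosbestic regression
cannot remove.
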