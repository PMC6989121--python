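# Methods

## Scope and data model

The pipeline consumes three delimited-text streams from a dual-site
miniscope session: per-cell fluorescence traces (cells × frames, 30
frames/s nominal), a 3-axis accelerometer log (104 Hz nominal, ±2 g range
at 0.061 mg per count), and an optional stimulation log. All times are in
seconds from session start; intervals are half-open `[t0, t1)` so an
event at a boundary belongs to exactly one interval. Streams sampled at
different rates are aligned by nearest-neighbour timestamp matching with
a 15 ms tolerance (about half a frame at 30 Hz, matching the per-frame
IMU FIFO read-out).

## Event-onset detection

Calcium-event onsets are recovered at sub-frame resolution by matched
filtering: the median-subtracted trace is cross-correlated with a
unit-energy transient template (double exponential, rise τ ≈ 30 ms,
configurable decay). Because the correlation at lag *k* is maximal when a
transient starts at sample *k*, local maxima of the correlation that
exceed `threshold_sigma` (default 3) times the noise SD are events; the
sub-frame onset comes from a parabola through the three samples around
each maximum. The noise SD is estimated as 1.4826·MAD of the
first-differenced trace divided by √2, which is insensitive to the
transients themselves. Each candidate must also have *prominence* above
the same threshold — without this, noise ripples riding on a transient's
long correlation tail produce spurious local maxima that pass the
absolute threshold. Events closer than `refractory_s` (default 0.2 s) to
the previously kept event are discarded, keeping the earlier one.

The detector is scale-invariant (both the threshold and the statistic
scale linearly with the trace) and deterministic. Known limits, measured
on synthetic sessions at 5 % noise: at resolvable event rates (≤ 0.3 Hz)
sensitivity and precision are both ≥ 0.9 within ±2 frames of ground
truth; at the ~0.6 Hz rate typical of Purkinje dendrites, transient
overlap plus the refractory rule cap sensitivity near 0.85 while
precision stays ≈ 1. Events inside the refractory shadow of a previous
event are unreportable by construction.

## Transient kinetics

Per-event half-decay time: the peak is the maximum within 0.5 s of
onset, the baseline is the median of the 0.3 s pre-onset, and t½ is the
first post-peak time the trace falls to baseline + (peak − baseline)/2,
linearly interpolated between samples. Only events isolated by ≥ 1 s on
both sides are used; events that never fall to half are counted as
censored rather than contributing a value.

The generator's transient kernel is
`k(t) = (1 − e^(−t/τ_r)) · e^(−λt)`, normalized to unit peak. The decay
constant λ is calibrated (scalar root-find) so that the *peak-to-half*
time of the kernel equals the configured t½. This matters: reported
half-decay times are measured from the transient peak, and with a finite
rise the naive choice λ = ln2/t½ makes the measured half-decay overshoot
the configured value by ~13 % at t½ = 0.217 s. With the calibrated
kernel, the estimator recovers configured kinetics within 1 % on
noiseless transients and within 5 % (median) on low-noise sessions at
both 0.217 s and 0.488 s. The first-crossing rule is slightly biased
early under noise, more so for slow decays (shallow slope at the half
level), which is why the session-level recovery band is 5 % rather
than 1 %.

## Kernel-sum synchrony

Onsets of all cells are convolved with a unit-peak Epanechnikov kernel
`k(t) = 1 − (t/h)²` on `|t| ≤ h` and summed. The half-width defaults to
h = 0.1 s — ±3 frames at 30 Hz, i.e. "synchronous" at frame resolution —
and is exposed as a parameter since the width of such a kernel is the
only time-like quantity in it. The sum is evaluated on a uniform grid
(dt = 10 ms, enforced ≤ h/4). The significance threshold is mean + 2 SD
of the sum over the *entire* grid, supra-threshold stretches included; a
median/MAD alternative exists but is off by default. Maximal
supra-threshold runs become synchronous events `[first_t, last_t + dt)`;
adjacent runs separated by even one sub-threshold grid point stay
distinct (no merging rule is applied).

Pair counting: a cell participates in an event if it has ≥ 1 onset inside
the interval; multiple onsets still count once. `co_count(a, b)` is the
number of events containing both cells, and pairs with `co_count ≥ 5` are
synchronous pairs. The kernel sum is computed globally over both regions
(a per-region option exists). Properties verified against brute-force
oracles: exact equality of the kernel sum, the interval scan and the pair
counts on small problems; invariance of co-counts under time shifts;
monotonicity in the `min_co` threshold.

A structural caveat: the ≥ 5 rule is an absolute count, so at fixed
baseline rates the number of *chance* co-firing events grows linearly
with session length while a planted ensemble's count is set by its firing
rate. On 60 s validation sessions the false-pair rate is ~1 %; by 80 s it
exceeds 5 %. Real use at multi-minute durations implicitly relies on the
mean+2σ threshold rising with population size; for planted-ensemble
validation we therefore fix 60 s sessions with ~9 ensemble firings.

## Behavioral acceleration

The compound signal is the per-sample Euclidean norm of (x, y, z). For
each SP, a ±2 s snippet is thresholded at mean + 2σ of its *baseline*,
defined as the outer 25 % of the pre-window (the part farthest from the
SP, least contaminated by the movement itself). The four-way
classification implements "where the largest mean signal occurred": among
the three bands — pre `[−2, −0.15)` s, post `(0.15, 2]` s, central
±150 ms — the band with the largest mean over its supra-threshold samples
sets the category (`pre` / `post` / `around`); nothing crossing means
`no_change`; ties between sides resolve to `post`. A strict
"sides-first" ordering was rejected because any noise crossing on a side
would pre-empt `around` entirely. SPs within 2 s of a recording edge are
excluded and counted separately, so the categories exactly partition the
classified SPs.

The random-trigger control draws uniform trigger times (edge-excluded)
and compares the fraction of snippets whose **post-window mean** exceeds
the baseline threshold, for random vs SP triggers, with a χ² test on the
2×2 hit table (no continuity correction; a table with an empty hit or
miss column gives p = 1). The mean — not the maximum — is used as the
indicator because the max over ~200 post-window samples crosses a
mean+2σ threshold almost surely under noise alone, saturating both
fractions at 1. Calibration measured over 200 uncoupled sessions:
rejection rate 0.035 at α = 0.05; on fully coupled sessions the
SP-triggered fraction exceeds the random fraction in 100 % of seeds.

Rearing is detected on the low-pass-filtered (2 Hz, 4th-order
zero-phase Butterworth) median-subtracted y channel with a hysteresis
rule: an epoch starts when the signal rises through θ_off = 0.05 g on its
way past θ_on = 0.1 g and ends when it falls below θ_off; durations
outside [0.5, 10] s are discarded. Turns are signed supra-threshold runs
of the filtered x channel (|x| > 0.1 g) with a 0.5 s refractory;
the sign convention (positive = left) is configurable. These thresholds
are tuned to the synthetic templates; the original workflow scored
rearing semi-manually from video, so fully automatic thresholding on real
data is an extension and should be re-tuned per rig.

Peri-event averages interpolate each signal onto a common lag grid,
report mean ± SEM (zero SEM for a single trigger, by convention), and
take the peak latency as the argmax of the mean in `[0, win]`.

## Stimulus-response analyses

Trials are cut from the traces around each stimulus (edge-overlapping
trials dropped and counted), aligned to onset or offset. The responder
rule takes the **max of the trial-averaged trace** in a post-stimulus
window (default: offset to offset + 1.5 s) against mean + 2σ of the
pre-stimulus baseline. The baseline statistics default to the *pooled*
per-trial pre-stimulus samples rather than the trial-averaged trace:
with spontaneous activity at realistic rates, the averaged-trace σ is so
small that the max-over-window rule marks ~50 % of truly unchanged cells
as responders (a liberality consistent with the ~50 % responder fractions
reported for this criterion in vivo); pooled σ includes trial-to-trial
variability and recovers planted classes with sensitivity and specificity
≥ 0.95. The averaged-trace mode remains available
(`baseline_stats="averaged"`).

Onset latency fits `f(t) = b + A/(1 + e^{−(t−t0)/s})` by least squares
(initialized at b = baseline mean, A = peak − b, t0 = half-rise sample,
s = 0.1 s); the onset is the first grid time with f above baseline
mean + 1σ. Fit failure falls back to the first raw-sample crossing and is
flagged. On noiseless logistics the onset matches the closed-form
crossing within one grid step.

Three-way modulation: per cell, trial means of fluorescence pre-stimulus
vs during stimulation are compared by a paired t-test; p < α (0.05)
splits by sign into decreased/increased, otherwise unchanged. A
zero-variance difference is defined as p = 1. No multiple-testing
correction is applied, matching the per-cell p < 0.05 convention of the
original analysis; a Benjamini–Hochberg option could be layered on the
returned p-values. Per-cluster event rates are computed from event trains
restricted to the stimulation windows. Type-I error measured on null
sessions: 0.053 (modulation) and 0.065 (action-window test) at α = 0.05.

## Synthetic sessions

The generator emulates the statistics the pipeline is meant to recover,
not raw imaging physics. Defaults are the reported conditions of the
preparation:

| parameter | default | meaning |
|---|---|---|
| baseline rates | 0.62 / 0.22 Hz | cerebellar / cortical event rates |
| t½ | 0.217 / 0.488 s | region decay kinetics (peak-to-half) |
| rise τ | 30 ms | transient rise time |
| noise SD | 0.05 | trace noise, fraction of unit transient peak |
| frame / accel rate | 30 / 104 Hz | acquisition rates |
| SP rate | 0.1 Hz | planted synchronous-event rate |
| ensemble fraction | 0.3 per region | cells in the planted ensemble |
| SP jitter SD | 10 ms | member-onset jitter around the SP time |
| p(move \| SP) | 0.31 | matches the reported 31 % post-SP fraction |
| bout latency | ~80 ms (lognormal) | reported stimulus-reflex latency scale |
| spontaneous bouts | 0.05 Hz | movement unrelated to SPs |
| rearing | 1.47/min, 2.2 s | reported rate and duration |
| responder latency | 220 ms | onset after stimulus offset |
| increased-cell extra rate | 1.4 Hz | during-stimulation excess events |

Movement bouts are half-sine envelopes on a random 3-D direction;
rearing is a rise–plateau–fall template on y (z co-moves at 0.6 gain);
turns are signed half-sine pulses on x. "Increased" cells fire extra
Poisson events during the stimulation window *and* an offset-locked
large transient — covering both the long-stimulation (during-window) and
short-pulse (offset-locked) paradigms; "decreased" cells have 80 % of
their baseline events suppressed during stimulation. Spontaneous bouts
exist because a null with no movement at all makes the random-trigger
control degenerate (nothing ever crosses, p ≡ 1).

A single seed feeds a `SeedSequence` that spawns six independent child
streams (events, trace noise, movement, rearing/turns, accelerometer
noise, stimulation), so each component is separately reproducible and
identical configs are bit-identical.

What the generator does **not** model — and hence what a green test does
not establish: photon/shot noise and motion artifacts, source-extraction
crosstalk between neighbouring cells, slow fluorescence drift and
bleaching, gravity offset and orientation changes in the accelerometer,
autocorrelated IMU noise, and any behavior beyond the planted templates.
Threshold defaults for rearing/turn detection are meaningful only
relative to the template amplitudes.

## Pipeline and determinism

`run_pipeline` validates its config against the full default schema
before any computation (unknown keys are errors), echoes every parameter
into the report, and writes all artifacts as CSV/GraphML plus a JSON
report. Reports are byte-identical across reruns of the same config and
seed. Graph export round-trips nodes, regions, co-counts and SP flags
losslessly through both GraphML and edge-list CSV; the arc layout is a
pure function of the graph with lexicographic tie-breaking.
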