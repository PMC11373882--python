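# Methods

## Problem and model

In a memory-guided gaze task, target position T and final gaze position G
are dissociated by the animal's endpoint errors and, in the cue-conflict
variant simulated here, by a partial attraction of gaze toward a shifted
visual landmark. A unit's response field is its firing rate as a function
of 2D position; the analysis asks in which candidate coordinate system
that field is best organized. Candidates are built per trial from the
behavioral geometry under a 2D additive frame convention
(`gaze_space = head_space + eye_in_head`; a position "in" frame F is
`x_space − F_origin_space`): target and future gaze in space/head/eye
frames (Ts, Th, Te, Gs, Gh, Ge), final effector positions (Eh, Hs), and
effector displacements (dE, dH). Gaze displacement is excluded because it
is numerically indistinguishable from Ge in this paradigm. All "in eye"
coordinates are relative to the initial (pre-saccade) gaze direction,
which is the response-field origin; Hs and Eh use final (post-saccade)
effector orientations.

The 2D additive composition replaces true 3D rotational kinematics. It
preserves exactly the degrees of freedom the model fits exploit (what
dissociates the ten candidates is the trial-to-trial variability of
fixation, head contribution, and gaze error, all of which survive the
approximation) while avoiding rotation arithmetic that the fits never
see. Torsion and non-commutativity effects of real 3D rotations are
therefore absent.

## Fitting and model selection

Response fields are fit by Nadaraya–Watson regression with an isotropic
Gaussian kernel, bandwidth h on a 2–25° grid in 1° steps. Fit quality is
the mean squared leave-one-out (PRESS) residual, computed exactly: the
kernel weight matrix has its diagonal zeroed so each trial's prediction
sums only over the other trials (this also avoids cancellation against
the unit self-weight; the vectorized computation matches a brute-force
per-trial refit to ~1e-12 relative). If all weights at a held-out point
underflow to zero, the prediction falls back to the unweighted mean of
its 3 nearest neighbors. Squared (not absolute) residuals define PRESS;
group comparisons use the residuals themselves via the Brown–Forsythe
(median-centered Levene) test at the best model's bandwidth, with p = 1
by convention when neither group has spread about its median. Exact ties
in model selection resolve deterministically: smallest bandwidth;
continuum step nearest 0, then the smaller (target-side) α.

The T–G continuum evaluates x(α) = Te + α(Ge − Te) on a grid from −0.2 to
1.2 in 0.1 steps — two steps beyond each anchor, keeping the extrapolated
flanks short while still letting estimates at the anchors err outward.
If Te = Ge on every trial the profile is flat and the fit is flagged
indeterminate. Epoch rates use half-open windows: visual 80–180 ms after
target onset, motor −50 to +50 ms around saccade onset, baseline the
100 ms ending at target onset.

## Spatial tuning test

The null hypothesis is exchangeability of rates across positions: rates
are permuted without replacement 100 times and the mean PRESS of each
shuffled field collected. Because bandwidth selection is part of the
fitting procedure, each shuffled field undergoes the same per-field
bandwidth search as the observed data, making observed and null PRESS
exactly exchangeable; when the test is run at an externally fixed
bandwidth, both sides use that bandwidth. The decision is one-sided —
only an improbably *low* PRESS indicates tuning — with rank p-value
p = (1 + #{null ≤ observed})/(n_shuffles + 1) and threshold 1 − ci_level
(default 0.05). With 100 shuffles the realized false-positive rate is
5/101 ≈ 4.95%, so ~95% of untuned units are retained as not-tuned; the
acceptance script recomputes this calibration. The null interval is
empirical (rank-based), not a normality-based mean ± 2 SD. The coherence
index CI = 1 − PRESS_best/PRESS_random uses the null mean; it is
undefined (NaN, with a warning) when the null PRESS is numerically zero,
as for constant rates.

## Time normalization

The interval from 80 ms after target onset to saccade onset is divided
into n = 14 equal, half-overlapping bins per trial. With span S and
overlap o, the width is w = S/(1 + (n−1)(1−o)) — w = 2S/(n+1) at o = 0.5
— and the step w(1−o), so the bins tile the span exactly (for the
simulated delay range this puts w at roughly 110–180 ms). The final
bin's sampling window additionally extends 50 ms past saccade onset so
the motor burst contributes to the last step. Per unit and bin, rates
are refit along the continuum and shuffle-tested; the population track
reports mean ± SEM of tuned units' α̂. Bins where the across-unit
coherence distribution does not exceed the baseline-window coherence
(one-sided Mann–Whitney, p < 0.05) are masked and carry no α estimate —
without demonstrable tuning a best-fit α is noise.

## Synthetic sessions

The generator emulates the paradigm's statistical structure, not its
visual appearance. Defaults: 4×4 target grid at 8° spacing; fixation
jittered uniformly in a 10° window; landmark 11° from the target in one
of four oblique directions; on 90% of trials the landmark shifts 8° in
one of eight radial directions; second memory delay uniform 200–600 ms.
The gaze endpoint is G = T + ω(L′−L) + ε with shift attraction ω = 0.4
and isotropic error SD 4.5°/axis. These two free parameters were set by
calibrating the simulated target-vs-gaze correlation to the task's
empirical regime (R ≈ 0.87 per axis with this grid); the generous reward
window of the paradigm (8–12° radius) is what permits errors of this
size. Head motion contributes a 0.3 fraction of each gaze displacement
plus 1° Gaussian jitter, dissociating head- from eye-frame models.

Units fire as inhomogeneous Poisson processes (1 ms resolution; the
noise model is a package choice): baseline (default 4–12 sp/s) plus a
visual burst (Gaussian in time, peaking ~125–145 ms after target onset
with 45 ms SD so the 80–180 ms window captures its core; gain 100–200
sp/s), a sustained delay/planning plateau from 200 ms after target onset
until saccade onset (10–30 sp/s), and a perisaccadic burst (30 ms SD,
100–200 sp/s). Each component's spatial factor is a closed (Gaussian,
σ 5–9°) or open (rectified-linear gradient) field evaluated at the
unit's coded continuum point; RF centers are drawn within ±8° because
experimenters position the target array over the response field. The
coded α may be constant, epoch-specific, or ramp linearly across the
trial. Waveform templates are built per class (regular-spiking
trough-to-peak > 250 µs, fast-spiking ≤ 250 µs, triphasic with an
initial positive phase at 0.6 of the post-trough peak; the triphasic
criterion for classification is ≥ 0.3, configurable, since no standard
threshold exists). Raw traces are white Gaussian noise with templates
inserted trough-aligned, default 8× the noise SD.

Determinism: all randomness derives from one session seed through named
substreams keyed by (seed, role, index); adding units never perturbs
existing units' spikes, and a fixed seed reproduces a session
bit-identically.

What the generator does *not* emulate — saccade kinematics
(main-sequence dynamics), microsaccades, torsion, rate adaptation,
correlated noise across units, non-Poisson spiking statistics, drift,
or allocentric (landmark-anchored) coding. Passing tests therefore show
that the analysis chain recovers known codes under realistic Poisson
variability and behavioral geometry; they do not certify performance
under correlated or non-stationary noise.

## Signal processing choices

Spike detection thresholds the absolute deviation from the trace median
at 3.5 robust SDs (1.4826·MAD, so inserted spikes do not inflate the
noise estimate); both polarities trigger; crossings merge within a 1 ms
dead time and stamp at the extremum. Saccade onset/offset use 50°/s and
30°/s velocity thresholds (head offset 15°/s). The endpoint-exclusion
primitive removes trials farther than a threshold from the per-target
mean gaze endpoint in a single pass (the mean includes prospective
outliers); its default radius is 2°, but the pipeline default is 12°
(~2.4 SDs of the simulated endpoint scatter) because a 2° radius would
discard most trials under the calibrated behavioral noise — with real
data the threshold should be set to the session's scatter.

## Population statistics

Signed-rank tests are exact for n ≤ 25 without ties, otherwise normal
approximation with continuity correction; degenerate all-zero
differences give p = 1. Group comparisons use the two-sided
Mann–Whitney U and a two-sided variance-ratio F test. The
visual-to-motor shift analysis reports the signed-rank p on motor −
visual, marginal medians, and the least-squares slope; between-group
slope and elevation comparisons are nested-model F tests
(analysis-of-covariance style: interaction term, then group intercept
given a common slope). Bimodality is summarized by a two-component 1D
Gaussian mixture fit by EM with 10 random restarts (tolerance 1e-8, max
500 iterations; components reported sorted by mean; all-equal input
collapses both components with SDs floored at 1e-3). No
multiple-comparison correction is applied beyond the per-test α = 0.05.

## Problem sizes

Validation suites use 4×4 grids with 9–10 trials per target (144–160
trials), 6–10 units per simulated session, 30 units per recovery
condition, 500 units for tuning-test calibration, and 100 random
datasets (n ≤ 20) for the leave-one-out oracle; these sizes give stable
statistics for every check while keeping the default test run fast.
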