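# Methods

This note records the models, numerical choices, and known limitations of
the package, in the order data flows through it.

## Task model and the synthetic session generator

The simulated operant task reproduces the trial logic of a head-fixed
wheel-turning design.  Each trial draws two delay parameters independently
and uniformly on a discrete grid (defaults: ITI 4–7 s, quiescence 0.5–2 s,
both in 100 ms increments).  The ITI runs from the previous trial's outcome;
the quiescence timer then starts and restarts with any wheel movement; the
stimulus appears when it completes.  After onset the stimulus is
positionally yoked to the wheel: a counterclockwise cumulative displacement
of 90° (configurable) from onset triggers reward, 90° clockwise triggers
punishment, and a trial with neither within a 60 s timeout ends with no
outcome.  The wheel-to-stimulus positional gain and the exact displacement
thresholds are not fixed by the experimental description we model, so they
are configurable with these defaults; only their ratio to the generated
bout amplitude (120°) matters for the simulated statistics.

Wheel behavior is a superposition of half-sine velocity bouts
(default duration 0.3 s, displacement 120°, 85% counterclockwise),
sampled at 1 kHz.  Movement is defined as wheel speed exceeding a
configurable floor (10 units/s) for at least one sample.  Two regimes:

* **null** — bouts form a homogeneous Poisson process (default
  0.25 bouts/s), independent of stimulus timing.  This is the chance
  behavior of an animal that turns often but has not learned the
  association.
* **associated** — additionally, each stimulus is answered with
  probability 0.9 by a counterclockwise bout at a latency drawn from a
  shifted log-normal (shift 50 ms, σ = 0.35, mode 150 ms).  The shifted
  log-normal was chosen for its strictly positive support and directly
  controllable mode; the 150 ms default places the latency bulk in the
  100–200 ms band characteristic of trained animals.

The generator renders the background process into the trace first, then
walks the trials against the *rendered* trace, splicing each response bout
in as it is produced.  Every recorded quantity — stimulus onset, first
movement, outcome — is therefore computed from the exact trace the session
record ships with, and `SessionRecord.verify_replay()` confirms that
replaying each trial's delay parameters reproduces its recorded onset to
machine precision.  This exactness is not cosmetic: the conditional
randomization test replays delays against the trace, and any inconsistency
between record and trace would corrupt its acceptance sets.  An earlier
design that planned bouts analytically and rendered afterwards was
abandoned because overlapping opposite-sign bouts cancel in the rendered
trace, silently desynchronizing planned and actual outcome times.

What the generator does *not* emulate: within-session satiety and
engagement drifts, idiosyncratic per-mouse kinematics, wheel slippage, and
any coupling between movement vigor and trial history.  Passing tests
therefore demonstrate correctness of the analysis logic under the stated
stochastic model, not robustness to every behavioral pattern of real mice.

## Conditional-randomization reaction-time test

Let X be the wheel trace plus the per-trial delay parameters D_i, V_i the
stimulus onsets, M_i the first movement after V_i, and S(X) the trace
together with the M_i.  Under the null hypothesis that movements are
unrelated to stimulus timing, the conditional law of D_i given S(X) is
uniform on each trial's *acceptance set*: the delay combinations whose
replayed onset V′_i is still followed first by the observed M_i.  Given the
trace and the outcome times, each trial's delays influence only its own
onset, so the conditional distribution factorizes over trials.

Two constructions of the null are provided and cross-checked:

* `conditional_null` — per trial and resample, delay pairs are proposed
  uniformly on the grid and replayed against the trace; after 1000 proposal
  rounds, unresolved resamples fall back to the trial's enumerated
  acceptance set.  This matches the resampling description directly while
  keeping runtime bounded for low-acceptance trials, without approximation.
* `exact_conditional_null` — every grid combination (≤ ~500 for the
  default grid) is replayed once per trial; null medians are drawn from the
  exact per-trial conditional supports.  A guard refuses grids above 10⁴
  combinations.

The test statistic is the median across trials of M_i − V_i, excluding
reaction times below a 100 ms floor (the same exclusion is applied inside
every resample).  The p-value is lower-tailed ("faster than chance") with
the add-one correction, p = (1 + #{T′ ≤ T}) / (1 + R); ties and resamples
whose median is undefined (all reaction times floored) count toward the
null tail, keeping the test conservative.  Trials whose stimulus was never
followed by a movement are excluded from both the observed statistic and
the null.  A session with fewer than 10 floor-surviving reaction times
reports no p-value.  A two-sided variant exists but is off by default.

Quiescence replay is exact and fast: movement bouts are reduced to sorted
intervals; for each quiescence duration q a "resolver" array (first
following inter-bout gap ≥ q) is precomputed in O(n), after which each
replay is O(log n).  This is what makes exact enumeration over 500
combinations × 60 trials × 500 sessions affordable in the calibration
sweep (about half a minute in total).

The association day is the first day with p below α = 0.05; days are taken
in the order given, without interpolating skipped days, and the delay grid
is read from each session's own record (training-early sessions with
shorter ranges are handled by the same code path).  The task performance
index (chance − observed)/(chance + observed) lies in (−1, 1) and is 0 at
chance.  `split_thirds` partitions trials into contiguous thirds with
earlier groups taking the remainder (10 → 4/3/3).

## Widefield processing

**Compression.**  Movies are factored as F = U S Vᵀ with a dense SVD and
truncated (default k = 2000, matching full-session practice; simulations
use far fewer).  All temporal operations act on S·V; the test suite checks
that every temporal operator commutes with reconstruction through U.

**Hemodynamic correction.**  The violet (calcium-invariant) channel is
sub-sample shifted onto the blue time grid by linear interpolation — the
simplest phase-accurate choice for 35 Hz interleaved channels.  For
fitting, both channels are spatially downsampled 3× (block mean) and
band-passed 5–15 Hz with a zero-phase (forward–backward) 3rd-order
Butterworth; a per-pixel scaling from violet to blue is then regressed by
ordinary least squares without intercept.  The correction subtracts the
*unfiltered*, mean-removed, scaled violet signal from the blue signal:
regressing on the filtered band but applying to the broadband signal
follows the stated order of operations of the protocol we model, and
subtracting the mean-removed violet preserves the blue baseline that F₀
normalization needs.  On stacks with a planted in-band artifact the
correction removes > 99% of 5–15 Hz power while preserving planted slow
signals to within a few percent, and a second pass changes the output by
well under 1% RMS.

**ΔF/F₀.**  Linear detrend, 0.01 Hz zero-phase high-pass (2nd-order
Butterworth), then (F − F₀)/(F₀ + c) with F₀ the per-pixel session mean of
the raw input and c the median of F₀ across pixels.  The softening is
additive regularization of the denominator — one reading of "softened by
the median"; it keeps dim pixels bounded and maps all-zero input to zero
output with a warning.

**Deconvolution.**  The indicator kernel is consumed as an asset (kernel
fitting is out of scope), resampled to the trace rate by linear
interpolation, and inverted in the frequency domain with Tikhonov
regularization, X = Y K* / (|K|² + λ max|K|²), λ = 10⁻³ by default
(λ = 0 gives exact inverse filtering when the kernel is invertible).

**Recasting and alignment.**  Cross-recording recasting is the linear map
SV_recast = U_masterᵀ U_exp SV_exp; when the experiment's column space is
contained in the master basis this is lossless, otherwise the residual is
exactly the orthogonal-complement projection (tested against an explicit
projector).  Within-animal day-to-day alignment computes vasculature edge
maps (image minus its Gaussian blur, σ = 4 px), searches rotation on a
coarse-then-fine grid (±5° by 0.5°, refined at 0.1°) with translation per
angle from upsampled phase cross-correlation, scores by edge-map
correlation, and breaks ties toward the smallest displacement.  Recovery
on a vasculature-like phantom is within 0.5 px and 0.5°.  Across-animal
affine alignment and atlas registration are out of scope (they require
external atlas assets).

**Hemisphere-weighted subtraction.**  Modeling region fluorescence as
F_L = v_L V + m_L M and F_R = v_R V + m_R M with V unilateral-visual and M
bilateral-motor, the movement gain ratio m_L/m_R is fitted by least squares
between epoch-averaged left and right traces around stimulus-free
delay-period movements that would have been rewarded (counterclockwise
threshold reached, clockwise not), averaged within then across days.  The
weighted difference F_L − (m_L/m_R) F_R cancels M exactly when the ratio
is exact and leaves (v_L − m_L v_R/m_R) V; with the planted gains
v_L = 1, v_R = 0.2, m_L = 0.8, m_R = 1 the output coefficient is 0.84 and
movement leakage is below 1% at zero noise.

**Visual field sign.**  Input is the per-presentation response of every
pixel to sparse-noise squares, already averaged in the 0.3–0.5 s window
after square onset (where the indicator response peaks).  Per bootstrap
(default 10; the resampling unit is the square presentation), per-square
mean responses are Gaussian-smoothed (σ = 2 px), each pixel's azimuth and
elevation preferences are computed as response-weighted centers of mass
(responses clipped at zero — negative weights have no meaning for a
center of mass), and the sign is the sine of the angle between the
elevation- and azimuth-gradient directions; bootstraps are averaged.
Orientation convention: with azimuth increasing along image columns and
elevation along image rows, a non-mirror area yields +1 and its mirror
image −1; because image rows grow downward, this fixes the otherwise
ambiguous sign of the "azimuth minus elevation" angle difference.  The
sign map is invariant to rotating the cortical coordinates, and a planted
two-area phantom localizes the mirror border to within the smoothing
radius.

## Electrophysiology

**Quality criteria.**  Waveform shape uses `scipy.signal.find_peaks` with
a prominence threshold of 10% of the trough amplitude (a threshold the
criterion itself leaves open): exactly one trough, at most two peaks,
trough before and larger than the main peak, trough-to-peak duration in
(100, 800) µs, and baseline (first 20% of samples) below 30% of the
maximum amplitude.  The spatial-decay slope is a linear fit of per-channel
maximum template amplitude against distance from the peak channel measured
in channel spacings, with the conventional floor of −20; the units of that
floor are not standardized, so both the distance normalization and the
floor are configurable, and this criterion is documented as the one
quantity not invariant to amplitude rescaling.

**Missing spikes.**  A Gaussian truncated at the detection floor (default:
the smallest observed amplitude) is fitted to spike amplitudes by maximum
likelihood (Nelder–Mead on (µ, log σ)); the missing fraction is the fitted
mass below the floor.  MLE on the raw amplitudes avoids the binning
choices a histogram fit would add.  Error shrinks with sample size and is
within 3 percentage points of closed-form truncation values at realistic
counts.

**Contamination.**  Violations r are spike pairs (all ordered pairs by
default; consecutive-pair counting available) with inter-spike interval in
(τ_C, τ_R] = (0.1, 2] ms.  F_p solves
r = 2(τ_R − τ_C) N² (1 − F_p) F_p / T, smaller root; a negative
discriminant (more violations than the formula's maximum) reports F_p = 1.
The synthetic contaminated unit is the superposition of two independent
refractory-respecting Poisson processes — the unit and a contaminating
neuron — so cross-source pairs occur at exactly the rate the formula
models and recovery is unbiased; a memoryless (non-refractory) contaminant
would add contaminant–contaminant violations the formula does not model
and bias recovery upward at high F_p.

**Responsiveness.**  The statistic is the mean over trials of the firing
rate difference between the response window (0–200 ms after stimulus,
±100 ms around movement) and the baseline window (−500 to −300 ms).  The
null swaps the two windows independently within each trial with
probability ½, 1000 shuffles; the p-value is two-sided (both elevated and
suppressed responders are of interest) with the add-one correction, so the
false-positive rate is bounded by α = 0.01 in expectation.

**Surface detection.**  Channels above the brain share ambient signal;
the boundary maximizing within-block minus cross-block mean LFP
correlation, searched from the probe top, marks the first in-brain
channel.  A minimum contrast of 0.1 guards against declaring a boundary in
a featureless matrix.

## Calibration sweeps and problem sizes

`visuomotor.calibration` measures empirical false-positive rates:
500 null-mode sessions of 60 trials (enumeration-backed null, 2000 medians
per session) for the reaction-time test, and 2000 stationary Poisson units
(50 trials, 5 Hz, 200 ms windows, 1000 shuffles) for the responsiveness
test.  These sizes give binomial standard errors of about 1% and 0.2% on
the nominal 5% and 1% levels while keeping each sweep under a minute on a
single core; `scripts/acceptance.py` runs both.  The contamination
recovery check averages 30 simulated one-hour units per contamination
level so that its Monte Carlo error (< 0.01) is well inside the ±0.02
recovery tolerance being asserted.

## Known limitations

* The conditional test's exactness rests on the session record replaying
  against its wheel trace; records assembled from real rigs must pass
  `verify_replay` (movement-threshold mismatches are the usual culprit).
* Enumeration cost grows with the delay grid; grids beyond ~10⁴
  combinations must use the rejection-sampling path.
* The hemodynamic model is a single per-pixel scaling; wavelength- or
  depth-dependent effects beyond the two-wavelength regression are out of
  scope.
* The field-sign map assumes responses dense enough in visual space for a
  meaningful center of mass; very sparse square grids degrade gracefully
  but are not flagged.
* Deconvolution is linear; indicator nonlinearity and saturation are not
  modeled.
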