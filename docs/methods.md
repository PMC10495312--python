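# Methods

## Threshold model and update rule

Sensitivity at a test location is represented by a discrete PMF over
candidate thresholds on a 1 dB support from −2 to 50 dB (53 bins). The
two ends lie outside the clinically reportable 0–40 dB range on purpose:
they stop the posterior mean from being dragged inward at the extremes.
Reported estimates are the posterior mean clamped to [0, 40] dB; the
internal PMFs keep the full support.

The stimulus presented at a location is always the current PMF mean,
rounded to the nearest integer dB (perimeters present integer
attenuations; rounding can be disabled for analysis). The response
likelihood used for updates is a cumulative Gaussian in
(candidate − stimulus) with slope 1 dB and asymptotes γ = λ = 0.03 —
the conventional ZEST response model, distinct from the simulated
observer's curve. A weighted update raises the likelihood to the power
w before multiplying:

    posterior(t) ∝ prior(t) · L(t)^w .

Exponentiation (rather than a linear blend) makes w = 0 exactly neutral
and w = 1 exactly Bayesian, and composes associatively, so repeated
neighbor updates behave like fractional observations. The tested
location updates with w = 1; same-quadrant neighbors with
w = WL(d) = 1/(0.5 d + 4) (AIZE), w = 0.33 (fixed-weight arm) or w = 0
(non-weighted arm). Cross-quadrant and already-terminated locations are
never touched; termination therefore freezes a location's estimate for
good.

## Prior

The prior at each location is a 1:1 mixture of two discretized
Gaussians plus a small uniform floor (10⁻³ per bin before
renormalization): a normal component at the location's normative
sensitivity (sd 4 dB) and a damaged component at 5 dB (sd 12 dB). The
mixture mirrors priors built from pooled normal and glaucomatous
reference data; since no such clinical database ships with the package,
the damaged component's mode and spread were calibrated once against
the simulation study's reference accuracy values and then frozen. All
parameters are exposed in `PriorSpec`.

## Termination and verification

A location terminates when the posterior's standard deviation falls
below σ(dB, r) = (−0.1 dB + 4.8)(1 + r/30 · 0.2), or at five
presentations. The formula's sensitivity argument is clamped to
[0, 28] dB, which reproduces the intended 2.0–5.8 working range of the
terminal value (2.0 at 28 dB centrally; 5.76 at 0 dB at 30°); a config
flag switches the comparison to variance instead of sd. The running
posterior mean is used as the formula's sensitivity argument.

Capped locations that missed the spread criterion and whose estimate is
below 15 dB are retested: one stimulus at the current estimate; a
"not seen" leaves the estimate unchanged (the response is counted in
presentation totals but discarded from estimation), a "seen" triggers a
second stimulus and both responses enter as full-weight updates, the
estimate becoming the new posterior mean. Verification responses do not
propagate to neighbors. Verification presentations count toward the
total-presentations metric (flag to exclude).

## Observer

Responses are Bernoulli draws from
fp + (1 − fp − fn)·Φ((t_true − stimulus)/sd(t_true)) with
sd(t) = min(exp(−0.081 t + 3.27), 4) dB — the published log-linear
variability law for perimetric thresholds with the 4 dB cap. The slope
is evaluated at the simulated patient's true threshold. Five canonical
FP/FN conditions are provided: (3,3), (9,9), (15,15), (15,3), (3,15)%.

## Synthetic fields

The generator stands in for clinical input fields that cannot be
redistributed. A linear hill of vision (34 dB at fixation, −0.25 dB/deg)
defines normal sensitivity. Normal fields add demeaned Gaussian noise
(sd 1 dB) and a uniform offset hitting a target MD within 0.1 dB.
Glaucomatous fields subtract 1–3 Gaussian-profile depression clusters
(more and wider clusters at greater severity; clusters confined to one
hemifield with probability 0.8 for MDs above −12 dB, mimicking
nerve-fiber-bundle defects), with the depth scaled by bisection until
the realized MD matches the target within 0.3 dB. Generated
sensitivities are floored at 0 dB — the reporting floor of the
instruments whose printouts the cohort emulates — and MD is the
unweighted mean of (sensitivity − normative) over the 52
non-blind-spot-adjacent locations, against the package's own normative
model (clinical MD is age-corrected and weighted; no such database is
bundled, and field metadata records the definition used).

The 20-field study cohort uses fixed MD targets whose medians and
ranges equal the emulated cohorts': normals median −0.77 dB in
[−1.78, 1.50]; glaucoma median −10.55 dB in [−20.82, −0.40].

What the generator does not emulate: anatomically shaped nerve-fiber
bundle defects (a deliberate choice — the strategy itself is meant to be
disease-agnostic), age effects, media opacity, and the bimodal
normal-or-floor depth distribution of real scotomas. Synthetic deep-MD
fields therefore carry more intermediate (8–25 dB) sensitivities than
typical clinical fields — the regime where threshold estimates are
noisiest — so absolute RMSE on the synthetic glaucoma cohort runs
slightly above values reported for empirical fields, while the
between-strategy orderings are unaffected.

## Experiment harness and randomness

An experiment is the full factorial of strategy arms × fields × error
conditions × repetitions. Every trial owns a seed derived from the base
seed and the trial's design coordinates (numpy `SeedSequence` spawn
keys), so results are reproducible bit-exactly and independent of
execution order. Within a trial a single random stream is consumed in a
fixed order — location draw, then response draw, per presentation;
verification draws last, in ascending location order — so an event log
plus the seed replays a trial exactly. The full design (1000
repetitions) schedules 100,000 trials per arm; the desk-scale runs used
by the acceptance script use 100 repetitions (5,000 trials per cohort),
and the test suite's three-arm ordering checks use 40 repetitions per
cell with paired Wilcoxon tests over per-(field, condition) medians.

## Metrics

Accuracy is per-trial RMSE between estimates and truth over the 52
included locations (blind-spot-adjacent points excluded by default).
Headline summaries report the median over per-condition medians — and,
because the two poolings can legitimately differ, the pooled-over-all-
trials median alongside. Test-retest variability is the per-location
across-repetition RMSE, histogrammed in 1 dB bins with a count of
locations above 7 dB. Estimator bias is summarized by estimate
quantiles conditional on rounded true sensitivity. Paired comparisons
use the two-sided Wilcoxon signed-rank test.

## Numerical choices and degenerate cases

PMFs are renormalized after every update and validated to sum to 1
within 10⁻⁹; an all-zero posterior raises with a diagnostic rather than
silently renormalizing. The fast trial driver caches the trial-invariant
tables (likelihood vectors per (stimulus, response), prior masses per
normative value, neighbor indices and weights per grid and weight
policy) across trials, and is cross-checked in the test suite against
the reference per-operation implementation via event-log replay (both
for the zero-weight arm, where the trial must equal independent
per-location ZEST exactly, and for the weighted arms). Stimulus
rounding uses round-half-up for determinism. The MD bisection runs 200
halvings on a [0, 2000] depth scale and rejects unreachable targets.

## Known limitations

The prior and the observer's slope coefficients are calibrated/adopted
conventions, not fitted clinical quantities; absolute RMSE and
presentation counts shift with them, though orderings between arms are
robust. The fixed-weight arm terminates faster here than in the
emulated study, and its accuracy advantage on normal fields does not
reproduce under these synthetic conditions (the test suite documents
this as an expected failure of the corresponding ordering check — the
check is implemented faithfully and left failing). Response-time
modeling, fixation-loss catch trials and kinetic perimetry are out of
scope.
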