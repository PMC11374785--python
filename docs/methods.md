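# Methods

This note documents the generative model behind `simkit`, the
statistical machinery in `models` and `reliability`, the numerical
choices made where several were defensible, and what the synthetic-data
tests do and do not establish about real game data.

## The generative model

### Choice trials (regular, mismatching-flanker, ice)

Each non-lava trial is a symmetric drift-diffusion decision.  Evidence
`x` starts at 0 and evolves by Euler–Maruyama in 1 ms steps with unit
diffusion coefficient, `x(t+1) = x(t) + v + N(0, 1)`, until it reaches
one of the boundaries ±a (correct = +a).  The first crossing plus a
per-player non-decision time `Ter` gives the first response; crossing
the wrong boundary produces an incorrect initial response.

After an incorrect crossing the **same accumulator keeps running** —
this is the continuity mechanism — toward the correct boundary, with a
post-decision drift `g·v_base − (post-decision conflict decrements)`.
The post-decision gain `g` (default 6–10) reflects the rapid,
often-insight-like evidence build-up after an error; only the correct
boundary absorbs in this stage, since drifting further past the
incorrect boundary simply means staying committed to the error.
Reaching +a initiates the error-correcting reversal (RT2, clocked like
RT1 from the central rat's color assignment).

Conflict manipulations act through two channels, both per player:

* **drift decrements** (evidence/ms) degrade evidence quality — they
  slow responses *and* lower accuracy (mismatching flanker, ice);
* **additive shifts** (ms) delay the stimulus-driven stages without
  touching accuracy.

The additive channel exists because parameter-recovery and
continuity-discrimination tests need cohorts whose true per-player
conflict effects are known *exactly in milliseconds*: a shift pair
`(shift_pre, shift_post)` with configurable between-player correlation
(`continuity_flanker`, `continuity_ice`) makes the true RT1 effect, the
true RT2 effect, and their true correlation direct generator inputs.
The default population uses both channels, calibrated so that observed
effect sizes, accuracy, and correction rates fall in the range the
game's published validation reports.

Two refinements keep the behavioral statistics realistic:

* **Success requires completed rotation.**  A trial succeeds only when
  the correct response (first or corrective) is initiated at least
  `rotation_margin` (200 ms) before obstacle collision — an initiated
  but incomplete rotation fails, as in the real game.
* **Deadline guessing.**  A player who has not reached a boundary by the
  last moment a rotation could still finish commits to the current
  evidence sign.  The commit is clock-driven, so condition shifts do not
  postpone it.  Without this mechanism the window staircase (below)
  forces ~20% of trials to end without any response, which real players
  essentially never do; with it, non-response is confined to a small
  lapse probability (2%), matching the low non-response incidence the
  published exclusion counts imply.

### Lava (stop-signal) trials

Lava trials are an independent race.  The go process is the same
diffusion first-crossing machinery; the stop process finishes at
`SSD + L`, with `L ~ N(stop_latency_mean, stop_latency_sd)` per trial.
If the stop process wins there is no movement (successful inhibition).
If the go process wins, movement starts at the go time and is released
when the stop process finishes (the late stop); with probability
`lava_correction_prob` a corrective response follows after a per-player
correction latency (mean 191 ms).  TTS = release − SSD therefore equals
the trial's stop latency, re-expressed on the player's "late-stop" scale:
the population correlates the latency's expression in the inhibition
race with its expression in release timing through `stop_share`
(default 0.9), so the generator can also produce regimes where SSRT and
TTS share less variance.

Because TTS is observed only on trials where the stop process *loses*,
its mean carries a small positive selection bias (~5–10 ms under
default parameters) relative to the latency mean.  This is inherent to
the race architecture, not an implementation artifact; recovery tests
therefore check per-player agreement within 3 SE rather than exact
equality, and use matching-flanker trials (the mismatching condition
deliberately carries a flanker effect on stop latency,
`tts_flanker_shift`, default 15 ms).

### Difficulty adaptation

* **Obstacle-timing (go-window) staircase**: driven by regular and
  mismatching-flanker trials only.  Success shrinks the
  collision window by `step_down` (20 ms), failure grows it by
  `step_up = 4·step_down`, so the stationary success rate is
  `step_up/(step_up+step_down) = 0.80`.  The published description fixes
  the target, not the step sizes; the 4:1 asymmetric rule is one of
  several staircases with the right stationary point and was chosen for
  simplicity.  The window starts at 1317 ms and is capped at 2600 ms.
* **SSD staircases**: one per lava flanker condition, starting at
  300 ms; a response moves the stop signal 50 ms earlier, an inhibition
  50 ms later, targeting a 50% respond rate.

Sessions consist of 40 training trials (same condition mix, staircases
active, excluded from analysis) followed by 456 test trials in exactly
the printed composition — 126 regular, 126 mismatching flanker, 84 lava
(42 per flanker condition), 120 ice (60 per flanker condition); lava and
ice never co-occur.  Ordering is uniformly random: the real game's three
blocks with breaks have no analytic role here.  All randomness flows
from a single seed; cohorts are byte-reproducible.

### Default population

Defaults (means ± between-player SDs) were chosen once, to place the
simulated cohorts in the operating range the published design implies:
boundary 16 ± 1.8, base drift 0.055 ± 0.008 /ms, non-decision
270 ± 25 ms (so that RTs essentially never cross the 300 ms filter
floor), flanker decrement 0.012 ± 0.004 plus a 25 ± 22 ms shift, ice
penalties calibrated so pooled non-lava success sits near the 80%
staircase target despite ice trials not driving the staircase, stop
latency 250 ± 70 ms between players with 50 ms trial-to-trial SD.  The
between-player stop-latency SD is at the upper end of the plausible
range; it was fixed so that integration-method SSRT retains a clear
individual-differences signal under the window censoring the adaptive
design imposes.

## Preprocessing

The player-exclusion rules use a point system (≥ 2 points excludes):
2 points each for mean fps < 35, first-response accuracy within 3
binomial SEs of chance, or non-response on > 10% of non-lava trials;
1 point each for a lava stopping rate outside [0.3, 0.7], correction
rates below 30% of opportunities (non-lava and lava separately),
non-response > 3%, and fps < 45.  The fps and non-response rules are
read as *tiers* (the severe threshold supersedes the mild one), and the
accuracy rule is one-sided by default — it targets near-chance
responders, and above-chance play is the norm; a two-sided switch is
provided.  "Opportunities" are incorrect, as-yet-uncorrected first
responses (non-lava) and post-signal responses (lava).

Trial filters: RT1 outside [300, 1500] ms; corrections more than 1 s
after the initial response (non-lava) or the stop signal (lava); then a
per-player, per-condition-cell 3-SD rule.  The SD rule is iterated to a
fixed point, which makes the filter idempotent by construction; the
first pass removes almost everything the rule ever removes.  SSRT inputs
are never trial-filtered.  Eligibility requires ≥ 3 retained
error-corrections per relevant trial type and, for SSRT, a stopping rate
in [0.30, 0.70].

## Measures

Integration-method SSRT: non-responses in the condition-matched go-RT
set are replaced by the maximum observed RT, the set is sorted
ascending (stable), and SSRT is the RT at 1-based rank `⌈p·n⌉` minus the
mean SSD, where `p` is the respond rate given a stop signal; a respond
rate of 0 or 1 is signalled as undefined.  The matching-flanker
sub-measure uses regular trials as its go-RT reference and the
mismatching sub-measure uses mismatching-flanker (non-ice, non-lava)
trials, mirroring the conditioning of the SSD staircases.  Composites
z-score each sub-measure over the analyzed cohort ((n−1) SD convention)
and average; the 2-column variant uses the two SSRT sub-measures, the
3-column variant adds TTS.

## Models

All models are linear mixed models grouped by player, REML-fitted, with
0/1 treatment coding (reference: non-conflict trial, first response).
The joint "maximal" model has fixed and random intercept, trial type,
response type and interaction; the "shared-conflict" (combined
measurement) model drops only the random interaction, encoding the
continuity assumption that individual differences in the conflict
effect are shared between response types.  Non-convergence triggers one
restart with a different optimizer and is otherwise flagged — the random
structure is never silently simplified.

Fixed effects are tested with CR2 (bias-reduced linearization)
cluster-robust standard errors using the model-implied covariance as the
working model, with Satterthwaite degrees of freedom computed from the
normal-theory moments of the variance estimator.  With singleton
clusters and no random effects this reduces algebraically to HC2 (a
test asserts the identity), and under the working model the adjusted
meat is exactly unbiased.  Small differences between these df and other
implementations' are expected.

Per-player conflict effects are empirical-Bayes conditional modes
(fixed effect + mode; RT2 effects add the interaction terms); a
no-pooling per-player OLS path is available, and is what the null
continuity check uses, because shrinkage can couple the two effect
estimates when the random-effect covariance is weakly identified.
Precision is η = σ(random component)/σ(residual) — the trial-type slope
for conflict effects, the intercept for the TTS model.

## Reliability

Split-half reliability assigns trials to halves by rank parity of trial
index within player × condition cell, recomputes the measure per half
(refitting any model involved), and applies the Spearman-Brown
correction `2r/(1+r)` (clamped to [−1, 1]; both raw and corrected are
reported).  McDonald's ω uses the closed-form triad solution for three
indicators (the just-identified one-factor ML fit) and an equal-loadings
identification for two; non-positive correlation structures are
signalled, Heywood loadings are replaced by the boundary solution.

BCa intervals resample players (reliability is a between-player
statistic): bias-correction `z0` from the proportion of bootstrap
replicates below the point estimate, acceleration `a` from the jackknife
over players.  With `z0 = a = 0` the interval is exactly the percentile
interval, and the implementation agrees with an independent BCa
implementation on scalar statistics.  Default B = 2,000 in tests; CI
endpoints are stable well below the 100,000 sometimes used, and B is
configurable.  The pipeline's split-half CIs resample players'
half-score pairs rather than refitting models per resample — an
approximation chosen for tractability and noted in the report.

The equivalent-trials translation treats reliability odds `R/(1−R)` as
proportional to trial count (the standard `R(n) = nq/(nq+1)` relation):
an increment r1→r2 implies the multiplier
`m = [r2/(1−r2)]/[r1/(1−r1)]`, which applied to a 0.50 baseline gives
the mapped reliability.  Published translations of this kind have used
formulations that this odds-multiplier rule does not exactly reproduce,
so mapped values should be read as this package's own convention.

For differences between *nested* measurements (e.g., a first-response
measure vs the same measure supplemented with error-corrections) no
bootstrap CI is reported.  `nested_bootstrap_validity_sim` shows why: in
a Gaussian trial model where one measure's trials contain the other's,
the single-cohort player bootstrap estimates the correlation between the
two reliabilities with large error (RMSE > 0.1 in the shipped
configuration) even though it calibrates the spread of each reliability
well, so the uncertainty of their *difference* is unreliable.  The
pipeline reports point differences only.

## Problem sizes and numerical notes

Simulation-based tests use cohorts of 20–100 players with the full
printed trial composition; recovery and continuity tests use a
fixed 2000 ms window (no adaptation, no lapses) so that known injected
effects are essentially uncensored by the filters; reliability-direction
tests use 20 cohorts of 100 players with a generous-corrections
population (accuracy ≈ 0.7, fast post-decision stage), the regime where
error-corrections carry enough trials to help.  Null-calibration checks
(CR2 type-I error, BCa coverage) use 500 replications.  The 1 ms Euler
grid overshoots boundaries by ≈ 0.58 evidence units on average, so
empirical first-passage means run a few percent above the continuous
closed form `(a/v)·tanh(av)`; tests use tolerances that cover this
known discretization bias plus Monte-Carlo error.

## Limitations

The generator emulates the statistical structure the analyses assume,
not the game itself: no rotation kinematics (event times are treated as
directly observed), no frame-level timing (fps is a per-player constant
used only by exclusion rules), no motivational or sequential effects
(streaks, post-error slowing, congruency-sequence effects), no
multi-session play.  Passing recovery tests shows the analysis chain is
correct under the stated model; it cannot show that real players follow
that model.  Accuracy-based conflict scores, evidence-accumulation model
*fitting*, and test–retest reliability are out of scope.
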