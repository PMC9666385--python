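# Methods

## The pitch-shift reflex and what is being modelled

When the pitch of a speaker's auditory feedback is shifted unexpectedly
mid-vowel, the speaker reflexively steers their fundamental frequency
(f_o) against the shift, typically cancelling only part of it.
`pitchreflex` models this reflex as a discrete-time feedback-control
loop and provides everything needed to study it quantitatively: a
registry of candidate controllers, a swarm-based fitting procedure, an
information-criterion comparison framework, a cross-validated
subject-identification analysis, and a synthetic-experiment generator
with known ground truth.

## The control loop

Time advances in steps of dt = 5 ms.  The plant (vocal apparatus) is a
pure accumulator:

    f[n+1] = f[n] + f_C[n]

where f is the produced f_o in units of the speaker's target (f_T = 1)
and f_C is the controller's corrective command.  The controller sees
two delayed copies of the output: an auditory channel
f_A(t) = f(t−τ_A)·(1+P(t−τ_A)), where P is the externally applied
fractional pitch shift, and a somatosensory channel f_S(t) = f(t−τ_S),
which is *not* perturbed.  Four controller laws are implemented:

* **pid** — f_C = α_P·e_A + α_I·Σe_A − α_D·Δf_A, with e_A = f_T − f_A
  the auditory error; the integral accumulates from perturbation onset.
* **diva** — f_C = α_A·e_A + α_S·e_S: auditory and somatosensory
  position errors.  With τ_S = 0 this is algebraically the one-state
  state-space law f_C = A·(f − f_T) + B·e_A with A = −α_S, B = α_A, and
  with α_A = α_S it is a first-order low-pass filter ("leaky
  integrator") of the delayed auditory error with time constant
  dt/α_S.  These equivalences are enforced by tests against separate
  implementations of the state-space and low-pass forms.
* **diva_velocity** — adds velocity-error terms −α_Av·Δf_A(t−τ_Av) and
  −α_Sv·Δf_S(t−τ_Sv) with differential delays.
* **diva_twostage** — adds a second, slower pair of position-error
  terms at differential delays τ_As, τ_Ss, capturing fast automatic
  plus slow (possibly volitional) response components.

Nineteen named configurations (P, PI, PD, PID, D1..D15) select an
equation and a free-parameter subset (2–8 parameters); everything else
is pinned at zero.

### Numerical conventions

* **Units.**  Gains are per-step increments; delays are seconds,
  rounded to the nearest whole step (the 5-ms grid is finer than any
  plausible delay precision).  Traces are fractional deviations from
  baseline, so data from downward- and upward-shift experiments share
  one representation.
* **Baseline silence.**  The controller output is forced to zero
  throughout the pre-onset baseline window, so simulated traces are
  exactly zero there, and the baseline is excluded from all RMSE.
* **Pre-history.**  Delayed signals reaching before the grid evaluate
  to the unperturbed target (f = f_T, P = 0).
* **Velocity terms.**  Derivatives are backward per-step differences of
  the plant signal scaled by the concurrent perturbation factor; the
  perturbation profile's own jump at onset is excluded (the controller
  resists perceived pitch drift, not the externally imposed
  discontinuity).  The step interval dt is absorbed into the velocity
  gain: an explicit 1/dt factor would make gains of order one — the
  documented and empirically occupied part of the range — violently
  unstable.
* **Causality.**  The differential velocity delays may be negative
  (velocity response faster than position response); the total delay
  τ_A + τ_Av is floored at zero steps so the controller can never read
  future samples.
* **Two-timescale law.**  The slow somatosensory term reads the
  somatosensory channel (f_S), keeping the law consistent with
  configurations that optimize τ_S; for configurations without a free
  τ_S the channel reduces to the plant output and nothing changes.

## Fitting

Free parameters are fit by minimizing the RMSE between the simulated
and observed trace over the post-onset window only.  The optimizer is a
recombination swarm: a population (default 10,000 particles; a 1,000
particle configuration is provided for batch work) is initialized
uniformly inside the bounds, and each iteration the worst 50% are
replaced by random linear combinations w·a + (1−w)·b of two members of
the top 10%, with w drawn uniformly from [−0.5, 1.5], plus uniform
jitter of 30% of the elite's current per-dimension spread.  Weights
outside [0, 1] extrapolate beyond the parents, which is essential for
tracking the strongly correlated valley between the auditory and
somatosensory gains; tying the jitter to the shrinking elite rather
than to the fixed bound range keeps exploration broad early while
allowing full refinement of the optimum late.  The search stops when every member's objective lies
within 1% of the incumbent best, after 100 consecutive iterations
without meaningful improvement (an absolute floor of 1e−12 prevents
denormal-scale "improvements" from deferring the stop), or at a hard
iteration cap.  Each fit repeats the search from independent seeds
(default 10) and keeps the minimum-RMSE solution; the repeat spread is
reported, and Pearson's r of the chosen solution summarizes fit
quality.  Optimized parameters are flagged if they lie on a bound.

Default bounds: gains −0.1..1.1 (negative gains express "following"
responses; 1 is immediate full compensation), the integral gain
±0.001, delays 0–500 ms, differential velocity delays −100..500 ms.

The delay parameter produces a plateaued, locally non-convex error
surface (delays act in whole steps), and individual swarm runs
occasionally settle one or two steps away with compensating gains;
this is precisely what the repeat protocol absorbs.

## Model comparison

Because trace residuals are strongly autocorrelated, sample counts
overstate the information in a fit.  Writing the Gaussian
log-likelihood with an effective degrees-of-freedom N, the
per-degree-of-freedom Akaike criterion is

    cAIC = 2k/N + ln(MSE) + 1 + ln(2π),

comparable across datasets of different lengths.  N is estimated by a
Satterthwaite–Welch argument: the autocorrelation ρ_k of the
pre-perturbation baseline (pooled across the analysis unit's segments,
tapered to zero from the first lag below the 2/√n significance bound)
defines a Toeplitz correlation matrix R over the scored window, and
N = (tr R)²/tr(R²), clipped to [1, n].  For exact AR(1) correlation
ρ = 0.5 over 100 samples this gives N ≈ 60.  A cAIC advantage larger
than 2·ln(20)/N marks a model as superior at 20:1 relative likelihood
(the conventional 95% support level); the relative likelihood of two
fits is exp((AIC_min − AIC)/2).

## Cross-validated classification and stability

Per model and subject, 10 cross-validation iterations each hold out 10
random test trials; the model is fit to the mean of the remaining
training trials.  Out-of-sample quality is summarized by a combined
cAIC with MSE averaged over test trials and N equal to the mean
per-trial effective df times the number of test trials, averaged
across subjects.  Subject identification uses the RMSE tensor
comparing every test mean trace against every fitted model trace: the
*overall* score is the probability (in %) that the correct subject
beats every competitor, the *pairwise* score the probability of
beating one random competitor; ties count against the classifier.
Under exchangeable inputs the overall score is 100/M % for M subjects
and the pairwise score is 50%.  A model-free reference classifier uses
the training-trial mean itself in place of a fitted model.  Parameter
stability across iterations is quantified per parameter by
ICC = σ²_between/(σ²_between + σ²_within), with σ_within the pooled
(unbiased, subject-averaged) within-subject standard deviation and
σ_between the standard deviation of subject means; identical training
means (a noiseless cohort) share one cached fit, so the no-noise ICC
is exactly 1 rather than being blurred by optimizer jitter.

## Synthetic studies

Two experiment layouts are built in.  `STUDY1`: /a/ sustained for 4 s,
80 trials of which a quarter carry a −100 cent shift with a 110-ms
linear ramp (never two perturbed trials consecutively), onset jittered
1.0–1.5 s into the trial, parse window −500..+1500 ms.  `STUDY2`: /i/
sustained 3 s, 60 trials all carrying a ±100 cent step (at most five
consecutive same-direction shifts), onset jittered 0.5–1.0 s, parse
window −400..+1400 ms.

Each trial is the ground-truth controller's deviation trace scaled to
the subject's baseline f_o and corrupted multiplicatively by (a) an
AR(1) wobble — default stationary SD 0.003 (0.3% of f_o, roughly 5
cents), lag-1 coefficient 0.9 at 5-ms steps — and (b) a per-trial
constant baseline offset (default SD 0.003).  The AR(1) choice gives
baseline residuals a nontrivial autocorrelation so the effective-df
machinery is exercised by realistic inputs; real voices additionally
contain vibrato-like periodicity, microprosody and occasional octave
errors of the pitch tracker, none of which are modelled, so passing
tests demonstrate correctness of the pipeline under the stated noise
law rather than robustness to every artifact of real recordings.

Ground-truth cohorts (`default_truths`) draw per-subject gains around
the magnitudes seen in fits to adult group data (auditory gain
0.006–0.03 per step, somatosensory gain 0.008–0.04, delays 80–140 ms
snapped to the grid, baseline f_o 150–250 Hz), producing compensation
magnitudes in the experimentally observed range (tens of percent)
while keeping subjects distinguishable.

Preprocessing mirrors what is applied to real recordings: trials are
cropped to the parse window around their onset, divided by their own
baseline average (making every preprocessed trial's baseline mean
exactly zero and removing the per-trial offset), expressed as
fractional deviations, and upshift trials are negated so both
directions share the downshift sign convention.  The compensation
summary converts the mean deviation over the final 250 ms of the
window to cents and divides by the shift magnitude (100% = the heard
pitch fully restored).

## Scale of the shipped analyses

The test suite and the acceptance script run the full pipeline at a
reduced but statistically meaningful scale, chosen as the smallest
configuration at which every property remains comfortably measurable:
six-subject cohorts, a 1,000-particle swarm with 2–3 repeats for batch
fits, 10 cross-validation iterations for the separated cohort and 6/4
for the chance and no-noise checks.  The full-size defaults (10,000
particles, 10 repeats) remain the recommended settings for one-off
fits to real data.

## Known limitations

* The swarm's recombination details (replacement and elite fractions,
  jitter rule) are design choices exposed in `SwarmConfig`; published
  descriptions of this optimizer family fix only the population size,
  the 1% convergence band and the patience rule.
* Effective df is estimated from finite baselines; for very short
  baselines the taper rule can leave only a handful of lags, making N
  noisy.  N is always clipped to [1, n].
* The classifier's strict-inequality tie rule penalizes exact ties,
  which occur with probability zero for continuous data but matter for
  artificially degenerate inputs.
* Across-trial adaptation, feedforward learning and audio-level
  processing (formants, voicing irregularities) are out of scope; the
  package starts from extracted f_o traces.
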