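# pitchreflex

Feedback-control modelling of reflexive responses to vocal pitch
perturbations.

When the pitch a speaker hears of their own voice is shifted
unexpectedly (e.g. −100 cents through headphones mid-vowel), the
speaker reflexively steers their fundamental frequency (f_o) against
the shift, usually cancelling only part of it.  This *pitch-shift
reflex* probes the auditory and somatosensory feedback-control
circuitry of speech, and its parameters differ reliably between
individuals.  `pitchreflex` is for researchers who run such
perturbation experiments and want to go beyond descriptive response
curves: it fits mechanistic controller models to perturbation-aligned
f_o traces, compares them on equal footing, and quantifies how stable
and subject-specific the fitted parameters are.

## What is inside

* **19 discrete-time controller models** (`model_registry()`): four
  PID-family controllers and fifteen DIVA/state-space-family
  controllers (D1..D15) built from auditory and somatosensory
  position-, velocity-, and two-timescale error terms.  The plant is an
  accumulator, f[n+1] = f[n] + f_C[n] at dt = 5 ms, driven by delayed
  feedback of its own output.  The central three-parameter model D1,

      f_C = α_A (f_T − f_A) + α_S (f_T − f_S),

  is algebraically equivalent to a one-state state-space controller
  (A = −α_S, B = α_A) and, for α_A = α_S, to a first-order low-pass
  filter of the delayed auditory error — equivalences the test suite
  verifies to < 1e−12.
* **Particle-swarm fitting** (`fit_model`): elite-recombination swarm
  with a 1% convergence band and a repeat protocol that keeps the
  minimum-RMSE solution; only the post-onset window is scored.
* **Model comparison** (`caic`, `caic_threshold`): per-degree-of-freedom
  corrected AIC, cAIC = 2k/N + ln(MSE) + 1 + ln(2π), with effective
  degrees of freedom N from a Satterthwaite–Welch treatment of the
  baseline autocorrelation.
* **Cross-validated subject classification** (`run_crossval`):
  train/test splits per subject, out-of-sample combined cAIC, overall
  and pairwise identification scores, and per-parameter ICC stability.
* **Synthetic studies** (`generate_cohort`, `STUDY1`, `STUDY2`): two
  classic experiment layouts (ramped −100 cent shifts on a quarter of
  trials; ±100 cent steps on every trial) with an AR(1)-plus-offset
  noise law and known ground truth, so the whole pipeline is testable
  without human data.

## Worked example

```python
import numpy as np
from pitchreflex import (
    STUDY1, SubjectTruth, SwarmConfig, compensation_percent, fit_model,
    generate_subject, get_model, preprocess_trials, simulate,
    steady_state_compensation,
)

d1 = get_model("D1")
grid, pert = STUDY1.parse_grid, STUDY1.perturbation(-1)

# simulate the reflex with auditory gain 0.011/step, 115 ms delay,
# somatosensory gain 0.013 — a typical adult group-mean parameterization
params = d1.make_params([0.011, 0.115, 0.013])
trace = simulate(d1, params, pert, grid)
print("deviation at +1.0 s: %.4f" % trace.values[grid.index_of(1.0)])
print("steady-state compensation: %.1f%%"
      % (100 * steady_state_compensation(0.011, 0.013, -100)))

# generate a synthetic session for that speaker and fit it back
rng = np.random.default_rng(0)
truth = SubjectTruth(model="D1", params=params, f_T=220.0)
trials = generate_subject(STUDY1, truth, rng)
_, mean = preprocess_trials(trials, STUDY1)
res = fit_model(d1, mean, pert, grid,
                SwarmConfig(n_particles=1000, patience=30, n_repeats=3, seed=1))
print("recovered: alpha_A=%.4f tau_A=%.0f ms alpha_S=%.4f rmse=%.5f r=%.3f"
      % (res.params.alpha_A, 1000 * res.params.tau_A,
         res.params.alpha_S, res.rmse, res.pearson_r))
print("compensation of the mean trace: %.1f%%"
      % compensation_percent(mean, pert, STUDY1))
```

Output:

```
deviation at +1.0 s: 0.0263
steady-state compensation: 45.1%
recovered: alpha_A=0.0105 tau_A=108 ms alpha_S=0.0126 rmse=0.00067 r=0.997
compensation of the mean trace: 44.1%
```

The speaker raises their f_o about 2.6% against the downward shift —
roughly 45% of the perturbation in cents — and the fit recovers the
generating gains and delay from twenty noisy trials to within a few
percent and one 5-ms step.

## Command line

```bash
pitchreflex models                             # the 19-model registry as TSV
pitchreflex synth    --study study1 --subjects 6 --seed 1 --out cohort/
pitchreflex fit      --data cohort/trials.csv --models D1,D5 --out fits.json
pitchreflex compare  --data cohort/trials.csv --seed 1 --out compare.json
pitchreflex crossval --data cohort/trials.csv --models D1 --out report.json
pitchreflex simulate --model D1 --param alpha_A=0.011 --param tau_A=0.115 \
                     --param alpha_S=0.013
```

Trace data travels as long-format CSV with declared units; every
command records its seed and configuration in its outputs, and reruns
with identical settings are byte-identical.

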