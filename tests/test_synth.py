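"""Synthetic-study generator and preprocessing."""

import numpy as np
import pytest

from pitchreflex import (
    STUDY1,
    STUDY2,
    ControllerParams,
    StudyDesign,
    SubjectTruth,
    Trace,
    cents_to_fraction,
    compensation_percent,
    generate_subject,
    group_mean,
    preprocess_trials,
    simulate,
    steady_state_compensation,
)


def _truth(**kw) -> SubjectTruth:
    base = dict(
        model="D1",
        params=ControllerParams(alpha_A=0.011, tau_A=0.115, alpha_S=0.013),
        f_T=200.0,
    )
    base.update(kw)
    return SubjectTruth(**base)


def test_design_invariants():
    for design in (STUDY1, STUDY2):
        lo, hi = design.jitter_window_s
        p0, p1 = design.parse_window_s
        assert lo + p0 >= 0 and hi + p1 <= design.vowel_duration_s
    with pytest.raises(ValueError):
        StudyDesign(
            name="bad", vowel_duration_s=1.0, n_trials=10, perturbed_fraction=1.0,
            directions=(-1,), magnitude_cents=100, ramp_ms=0,
            jitter_window_s=(0.5, 0.9), parse_window_s=(-0.4, 1.4),
        )


def test_noiseless_trials_reproduce_the_controller_exactly(rng):
    truth = _truth(noise_sd=0.0, baseline_drift_sd=0.0)
    trials = generate_subject(STUDY1, truth, rng)
    assert len(trials) == STUDY1.n_trials
    for tr in trials:
        assert STUDY1.jitter_window_s[0] <= tr.onset_s <= STUDY1.jitter_window_s[1]
        if not tr.perturbed:
            np.testing.assert_array_equal(tr.f0_hz, truth.f_T)
    perturbed = [t for t in trials if t.perturbed]
    from pitchreflex import TimeGrid, build_perturbation

    tr = perturbed[0]
    grid = TimeGrid(-tr.onset_s, STUDY1.vowel_duration_s - tr.onset_s)
    pert = build_perturbation(grid, -STUDY1.magnitude_cents, STUDY1.ramp_ms, 0.0)
    dev = simulate(truth.spec, truth.params, pert, grid).values
    np.testing.assert_allclose(tr.f0_hz, truth.f_T * (1.0 + dev), rtol=1e-12)


def test_study1_has_20_perturbed_trials_none_consecutive(rng):
    trials = generate_subject(STUDY1, _truth(), rng)
    flags = np.array([t.perturbed for t in trials])
    assert flags.sum() == 20
    assert not np.any(flags[:-1] & flags[1:])
    assert all(t.direction == -1 for t in trials if t.perturbed)


def test_study2_directions_balanced_and_run_limited(rng):
    trials = generate_subject(STUDY2, _truth(), rng)
    dirs = np.array([t.direction for t in trials])
    assert np.all(dirs != 0)
    assert abs(int(np.sum(dirs))) <= 1
    run, longest = 1, 1
    for a, b in zip(dirs, dirs[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    assert longest <= STUDY2.max_consecutive_same


def test_noise_sd_matches_configuration():
    # unperturbed control trials carry only the noise law, so the
    # per-sample residual SD estimates the configured wobble directly
    rng = np.random.default_rng(99)
    truth = _truth(noise_sd=0.004, baseline_drift_sd=0.0, noise_ar1=0.6)
    samples = []
    for _ in range(10):  # 10 sessions x 60 control trials
        trials = generate_subject(STUDY1, truth, rng)
        samples += [tr.f0_hz / truth.f_T for tr in trials if not tr.perturbed]
    stack = np.vstack(samples)
    resid = stack - stack.mean(axis=0)
    assert resid.std() == pytest.approx(0.004, rel=0.05)
    # lag-1 autocorrelation of the wobble matches the configured AR(1)
    r1 = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in resid])
    assert r1 == pytest.approx(0.6, abs=0.05)


def test_preprocessing_baseline_zero_and_flip(rng):
    trials = generate_subject(STUDY2, _truth(), rng)
    traces, mean = preprocess_trials(trials, STUDY2)
    grid = STUDY2.parse_grid
    assert len(traces) == STUDY2.n_trials
    for tr in traces:
        assert np.mean(tr.baseline) == pytest.approx(0.0, abs=1e-12)
    assert mean.values.shape == (grid.n_samples,)
    # flipping is an involution
    flipped_twice = -(-traces[0].values)
    np.testing.assert_array_equal(flipped_twice, traces[0].values)


def test_flipped_upshift_matches_downshift_to_second_order(rng):
    """+100 and -100 cent responses agree after flipping, to O(P^2)."""
    truth = _truth(noise_sd=0.0, baseline_drift_sd=0.0)
    trials = generate_subject(STUDY2, truth, rng)
    traces, _ = preprocess_trials(trials, STUDY2)
    down = [t for t, tr in zip(traces, trials) if tr.direction == -1]
    up = [t for t, tr in zip(traces, trials) if tr.direction == +1]
    mean_down = np.mean([t.values for t in down], axis=0)
    mean_up = np.mean([t.values for t in up], axis=0)
    assert np.max(np.abs(mean_down - mean_up)) <= 0.004


def test_preprocess_requires_room_for_parse_window(rng):
    truth = _truth()
    trials = generate_subject(STUDY1, truth, rng)
    trials[0].f0_hz = trials[0].f0_hz[:100]  # truncate a trial
    trials[0].perturbed = True
    with pytest.raises(ValueError):
        preprocess_trials(trials, STUDY1)


def test_group_mean_and_sem(rng):
    grid = STUDY1.parse_grid
    a = Trace(grid=grid, values=np.full(grid.n_samples, 0.01))
    b = Trace(grid=grid, values=np.full(grid.n_samples, 0.03))
    gm, sem = group_mean([a, b])
    np.testing.assert_allclose(gm.values, 0.02)
    single, sem1 = group_mean([a])
    np.testing.assert_array_equal(single.values, a.values)
    assert np.all(sem1 == 0.0)
    # N identical subjects + iid noise: SEM ~ sigma / sqrt(N)
    sigma, n_subj = 0.005, 40
    subs = [Trace(grid=grid, values=rng.normal(0, sigma, grid.n_samples))
            for _ in range(n_subj)]
    _, sem = group_mean(subs)
    assert np.mean(sem) == pytest.approx(sigma / np.sqrt(n_subj), rel=0.1)


def test_compensation_percent_values():
    grid = STUDY1.parse_grid
    pert = STUDY1.perturbation(-1)
    zero = Trace(grid=grid, values=np.zeros(grid.n_samples))
    assert compensation_percent(zero, pert, STUDY1) == 0.0
    full = Trace(grid=grid, values=np.full(grid.n_samples, cents_to_fraction(100.0)))
    assert compensation_percent(full, pert, STUDY1) == pytest.approx(100.0, abs=1e-9)


def test_compensation_matches_steady_state_oracle():
    """A long sustained-shift run lands on the closed-form compensation."""
    from pitchreflex import TimeGrid, build_perturbation

    design = StudyDesign(
        name="long", vowel_duration_s=30.0, n_trials=1, perturbed_fraction=1.0,
        directions=(-1,), magnitude_cents=100.0, ramp_ms=0.0,
        jitter_window_s=(0.5, 0.5), parse_window_s=(-0.5, 29.0),
    )
    grid = design.parse_grid
    pert = design.perturbation(-1)
    trace = simulate(
        SubjectTruth(model="D1",
                     params=ControllerParams(alpha_A=0.011, tau_A=0.115, alpha_S=0.013)).spec,
        ControllerParams(alpha_A=0.011, tau_A=0.115, alpha_S=0.013), pert, grid,
    )
    expected = 100.0 * steady_state_compensation(0.011, 0.013, -100.0)
    got = compensation_percent(trace, pert, design)
    assert got == pytest.approx(expected, rel=0.01)
    assert got == pytest.approx(45.1, abs=0.5)
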