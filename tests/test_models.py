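"""Model registry, simulation oracles and structural equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchreflex import (
    ControllerParams,
    PerturbationProfile,
    TimeGrid,
    build_perturbation,
    cents_to_fraction,
    get_model,
    model_registry,
    registry_table,
    simulate,
    simulate_lowpass,
    simulate_state_space,
    steady_state_compensation,
)

EXPECTED_REGISTRY = {
    "P": ("pid", ("alpha_P", "tau_A")),
    "PI": ("pid", ("alpha_P", "alpha_I", "tau_A")),
    "PD": ("pid", ("alpha_P", "alpha_D", "tau_A")),
    "PID": ("pid", ("alpha_P", "alpha_I", "alpha_D", "tau_A")),
    "D1": ("diva", ("alpha_A", "tau_A", "alpha_S")),
    "D2": ("diva", ("alpha_A", "tau_A", "alpha_S", "tau_S")),
    "D3": ("diva_velocity", ("alpha_A", "tau_A", "alpha_Av")),
    "D4": ("diva_velocity", ("alpha_A", "tau_A", "alpha_Av", "tau_Av")),
    "D5": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "alpha_Av")),
    "D6": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av")),
    "D7": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av")),
    "D8": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "alpha_Av", "tau_Av", "alpha_Sv")),
    "D9": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av", "alpha_Sv")),
    "D10": ("diva_velocity", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av", "alpha_Sv", "tau_Sv")),
    "D11": ("diva_twostage", ("alpha_A", "tau_A", "alpha_As", "tau_As")),
    "D12": ("diva_twostage", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As")),
    "D13": ("diva_twostage", ("alpha_A", "tau_A", "alpha_S", "alpha_As", "tau_As", "alpha_Ss")),
    "D14": ("diva_twostage", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As", "alpha_Ss")),
    "D15": ("diva_twostage", ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As", "alpha_Ss", "tau_Ss")),
}


def test_registry_matches_canonical_table():
    registry = {s.name: s for s in model_registry()}
    assert len(registry) == 19
    assert set(registry) == set(EXPECTED_REGISTRY)
    for name, (eq, free) in EXPECTED_REGISTRY.items():
        assert registry[name].equation == eq
        assert registry[name].free_params == free
    # parameter counts span 2..8
    counts = sorted(s.n_free for s in model_registry())
    assert counts[0] == 2 and counts[-1] == 8
    table = registry_table()
    assert list(table["n_params"]) == [registry[n].n_free for n in table["name"]]


def test_unknown_model_rejected():
    with pytest.raises(KeyError):
        get_model("D99")


def test_no_perturbation_means_no_response(study1_grid, d1):
    pert = build_perturbation(study1_grid, 0.0, 0.0, 0.0)
    tr = simulate(d1, d1.make_params([0.05, 0.1, 0.02]), pert, study1_grid)
    assert np.all(tr.values == 0.0)


def test_zero_gains_mean_no_response(study1_grid, step_down):
    for name in ("P", "PID", "D1", "D5", "D15"):
        spec = get_model(name)
        tr = simulate(spec, ControllerParams(), step_down, study1_grid)
        assert np.all(tr.values == 0.0)


def test_masked_parameters_rejected(study1_grid, step_down, d1):
    with pytest.raises(ValueError):
        simulate(d1, ControllerParams(alpha_P=0.1), step_down, study1_grid)


def test_nonfinite_and_oversized_delays_rejected(study1_grid, step_down, d1):
    with pytest.raises(ValueError):
        simulate(d1, ControllerParams(alpha_A=float("nan")), step_down, study1_grid)
    with pytest.raises(ValueError):
        # a delay longer than the whole grid cannot be represented
        huge = ControllerParams(alpha_A=0.01, tau_A=10.0)
        simulate(d1, huge, step_down, study1_grid)


def test_step_response_matches_geometric_recursion(study1_grid, d1):
    """Undelayed auditory-only controller: f_n = f* + (1 - f*) r^n."""
    P, alpha = -0.05, 0.01
    pert = PerturbationProfile(
        grid=study1_grid,
        magnitude_cents=1200.0 * np.log2(1.0 + P),
        ramp_ms=0.0,
        onset_index=study1_grid.onset_index,
        values=np.where(study1_grid.times >= 0.0, P, 0.0),
    )
    tr = simulate(d1, d1.make_params([alpha, 0.0, 0.0]), pert, study1_grid)
    f_star = 1.0 / (1.0 + P)
    r = 1.0 - alpha * (1.0 + P)
    n = np.arange(tr.post_onset.size)
    oracle = f_star + (1.0 - f_star) * r**n - 1.0
    np.testing.assert_allclose(tr.post_onset, oracle, atol=1e-12)
    assert tr.values[study1_grid.index_of(0.5)] == pytest.approx(0.032369, abs=1e-6)


def test_sustained_step_converges_to_equilibrium(d1):
    """Long-run deviation equals (a_A + a_S)/(a_A (1+P) + a_S) - 1."""
    alpha_A, alpha_S = 0.011, 0.013
    grid = TimeGrid(-0.5, 30.0)
    pert = build_perturbation(grid, -100.0, 0.0, 0.0)
    tr = simulate(d1, d1.make_params([alpha_A, 0.115, alpha_S]), pert, grid)
    P = cents_to_fraction(-100.0)
    f_star = (alpha_A + alpha_S) / (alpha_A * (1.0 + P) + alpha_S)
    assert tr.values[-1] == pytest.approx(f_star - 1.0, rel=1e-3)
    assert tr.values[-1] == pytest.approx(0.026397, rel=1e-3)


def test_convergence_within_twenty_time_constants(d1, rng):
    """Stable parameterizations reach equilibrium to 0.1% after 20 tau."""
    P = cents_to_fraction(-100.0)
    for _ in range(10):
        alpha_A = rng.uniform(0.005, 0.1)
        alpha_S = rng.uniform(0.0, 0.1)
        rate = alpha_A * (1.0 + P) + alpha_S
        n_steps = int(20.0 / rate) + 1
        grid = TimeGrid(-0.05, n_steps * 0.005)
        pert = build_perturbation(grid, -100.0, 0.0, 0.0)
        tr = simulate(d1, d1.make_params([alpha_A, 0.0, alpha_S]), pert, grid)
        f_star = (alpha_A + alpha_S) / rate
        assert abs(tr.values[-1] - (f_star - 1.0)) <= 1e-3 * abs(f_star - 1.0)


def test_baseline_window_is_exactly_silent(study1_grid, ramp_down, rng):
    for spec in model_registry():
        theta = rng.uniform(0.0, 0.05, spec.n_free)
        tr = simulate(spec, spec.make_params(theta), ramp_down, study1_grid)
        assert np.all(tr.baseline == 0.0)
        assert tr.values[study1_grid.onset_index] == 0.0


# --- structural equivalences ------------------------------------------------


@given(
    alpha_A=st.floats(0.001, 0.1),
    alpha_S=st.floats(0.0, 0.1),
    tau_A=st.sampled_from([0.0, 0.05, 0.115, 0.2]),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_diva_equals_state_space(alpha_A, alpha_S, tau_A):
    """D1 with tau_S = 0 equals f_C = A (f - f_T) + B e_A, A = -a_S, B = a_A."""
    grid = TimeGrid(-0.5, 1.5)
    pert = build_perturbation(grid, -100.0, 110.0, 0.0)
    d1 = get_model("D1")
    diva = simulate(d1, d1.make_params([alpha_A, tau_A, alpha_S]), pert, grid)
    ss = simulate_state_space(A=-alpha_S, B=alpha_A, tau_A=tau_A, pert=pert, grid=grid)
    assert np.max(np.abs(diva.values - ss.values)) < 1e-12


@given(alpha=st.floats(0.001, 0.1), tau_A=st.sampled_from([0.0, 0.115]))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_diva_equals_lowpass_when_gains_match(alpha, tau_A):
    """a_A = a_S = a: D1 is a first-order low-pass of the delayed error."""
    grid = TimeGrid(-0.5, 1.5)
    pert = build_perturbation(grid, -100.0, 110.0, 0.0)
    d1 = get_model("D1")
    diva = simulate(d1, d1.make_params([alpha, tau_A, alpha]), pert, grid)
    lp = simulate_lowpass(alpha=alpha, tau_A=tau_A, pert=pert, grid=grid)
    assert np.max(np.abs(diva.values - lp.values)) < 1e-12


def test_pd_and_d3_traces_bit_identical(study1_grid, ramp_down, rng):
    pd_spec, d3 = get_model("PD"), get_model("D3")
    for _ in range(10):
        gain, der, tau = rng.uniform(0.001, 0.05), rng.uniform(0.0, 0.9), rng.choice([0.0, 0.1, 0.25])
        t_pd = simulate(pd_spec, pd_spec.make_params([gain, der, tau]), ramp_down, study1_grid)
        t_d3 = simulate(d3, d3.make_params([gain, tau, der]), ramp_down, study1_grid)
        np.testing.assert_array_equal(t_pd.values, t_d3.values)


def test_p_model_equals_d1_without_somatosensory_gain(study1_grid, ramp_down, rng):
    p_spec, d1 = get_model("P"), get_model("D1")
    for _ in range(10):
        gain, tau = rng.uniform(0.001, 0.05), rng.choice([0.0, 0.1, 0.25])
        t_p = simulate(p_spec, p_spec.make_params([gain, tau]), ramp_down, study1_grid)
        t_d1 = simulate(d1, d1.make_params([gain, tau, 0.0]), ramp_down, study1_grid)
        np.testing.assert_array_equal(t_p.values, t_d1.values)


# --- steady-state compensation ---------------------------------------------


def test_compensation_limits_and_group_mean_value():
    assert steady_state_compensation(0.02, 0.0, -100.0) == pytest.approx(1.0, abs=1e-12)
    assert steady_state_compensation(0.0, 0.02, -100.0) == pytest.approx(0.0, abs=1e-12)
    assert steady_state_compensation(0.011, 0.013, -100.0) == pytest.approx(0.451, abs=5e-4)
    with pytest.raises(ValueError):
        steady_state_compensation(0.011, 0.013, 0.0)
    with pytest.raises(ValueError):
        steady_state_compensation(-0.5, 0.0, -100.0)


def test_compensation_small_perturbation_limit():
    for alpha_A, alpha_S in [(0.011, 0.013), (0.02, 0.01), (0.005, 0.05)]:
        got = steady_state_compensation(alpha_A, alpha_S, 1.0)
        assert abs(got - alpha_A / (alpha_A + alpha_S)) < 1e-4


def test_compensation_monotone_in_gains():
    a_grid = np.linspace(0.005, 0.1, 8)
    comp_a = [steady_state_compensation(a, 0.02, -100.0) for a in a_grid]
    assert np.all(np.diff(comp_a) > 0)
    comp_s = [steady_state_compensation(0.02, s, -100.0) for s in a_grid]
    assert np.all(np.diff(comp_s) < 0)
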