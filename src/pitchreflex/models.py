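"""Discrete-time feedback-control models of the pitch-shift reflex.

The plant is a pure accumulator: at each 5-ms step the produced f_o is
incremented by the controller output, ``f[n+1] = f[n] + f_C[n]``.  The
controller sees *delayed* sensory copies of its own output — an auditory
channel carrying the (possibly perturbed) heard pitch,

    f_A(t) = f(t - tau_A) * (1 + P(t - tau_A)),

and a somatosensory channel carrying the unperturbed produced pitch,

    f_S(t) = f(t - tau_S).

Four controller laws are supported, spanning two families:

* ``pid`` — proportional / integral / derivative control on the auditory
  error, f_C = a_P e_A + a_I * sum(e_A) - a_D * fdot_A.
* ``diva`` — the DIVA model's feedback controller, a weighted sum of
  auditory and somatosensory position errors,
  f_C = a_A e_A + a_S e_S.  With tau_S = 0 it is algebraically identical
  to the one-state state-space controller f_C = A (f - f_T) + B e_A with
  A = -a_S, B = a_A, and (when a_A = a_S) to a first-order low-pass
  filter of the delayed auditory error with time constant dt/a_S.
* ``diva_velocity`` — adds velocity-error terms on both channels with
  differential delays tau_Av, tau_Sv.
* ``diva_twostage`` — adds a second, slower pair of position-error terms
  at differential delays tau_As, tau_Ss (a fast automatic response plus
  a slower, possibly volitional one).

The 19 named model configurations (P, PI, PD, PID, D1..D15) pick an
equation and a subset of free parameters; everything not free is pinned
at 0.  Simulation is in normalized units with the target f_T = 1, and
traces are returned as fractional deviations f - 1.  The controller is
silent (f_C = 0) throughout the baseline window, and delayed signals
reaching before the grid evaluate to the unperturbed target.

Velocity/derivative terms use a backward difference of the *plant*
signal scaled by the concurrent perturbation factor,
fdot_A(t) = (1 + P(t - tau_A)) * [f(t - tau_A) - f(t - tau_A - dt)],
so the discontinuity of the perturbation profile itself at onset does
not enter the derivative: the controller resists perceived pitch drift,
not the externally imposed jump.  The step interval is absorbed into
the velocity gains (they are per-step, like all other gains); an
explicit 1/dt factor would make the documented gain range of order 1
violently unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .core import PerturbationProfile, TimeGrid, Trace, cents_to_fraction

__all__ = [
    "ControllerParams",
    "ModelSpec",
    "GAIN_BOUNDS",
    "PARAM_BOUNDS",
    "model_registry",
    "get_model",
    "registry_table",
    "simulate",
    "simulate_population",
    "simulate_state_space",
    "simulate_lowpass",
    "steady_state_compensation",
]

EQ_PID = "pid"
EQ_DIVA = "diva"
EQ_DIVA_VEL = "diva_velocity"
EQ_DIVA_2TS = "diva_twostage"

GAIN_BOUNDS = (-0.1, 1.1)
#: Default optimization bounds per parameter: gains span -0.1..1.1 (negative
#: gains model "following" responses; 1 is immediate full compensation),
#: except the integral gain which lives at +-0.001.  Delays span 0-500 ms;
#: differential velocity delays may be negative (velocity response faster
#: than position response), down to -100 ms.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_P": GAIN_BOUNDS,
    "alpha_I": (-0.001, 0.001),
    "alpha_D": GAIN_BOUNDS,
    "alpha_A": GAIN_BOUNDS,
    "alpha_S": GAIN_BOUNDS,
    "alpha_Av": GAIN_BOUNDS,
    "alpha_Sv": GAIN_BOUNDS,
    "alpha_As": GAIN_BOUNDS,
    "alpha_Ss": GAIN_BOUNDS,
    "tau_A": (0.0, 0.5),
    "tau_S": (0.0, 0.5),
    "tau_Av": (-0.1, 0.5),
    "tau_Sv": (-0.1, 0.5),
    "tau_As": (0.0, 0.5),
    "tau_Ss": (0.0, 0.5),
}


@dataclass
class ControllerParams:
    """All controller gains (per-step increments) and delays (seconds)."""

    alpha_P: float = 0.0
    alpha_I: float = 0.0
    alpha_D: float = 0.0
    alpha_A: float = 0.0
    alpha_S: float = 0.0
    alpha_Av: float = 0.0
    alpha_Sv: float = 0.0
    alpha_As: float = 0.0
    alpha_Ss: float = 0.0
    tau_A: float = 0.0
    tau_S: float = 0.0
    tau_Av: float = 0.0
    tau_Sv: float = 0.0
    tau_As: float = 0.0
    tau_Ss: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        for name, value in self.as_dict().items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is non-finite")

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ControllerParams":
        return cls(**values)


@dataclass(frozen=True)
class ModelSpec:
    """A named model configuration: controller law + free parameters."""

    name: str
    equation: str
    free_params: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {p: PARAM_BOUNDS[p] for p in self.free_params}
        merged.update(self.bounds)
        object.__setattr__(self, "bounds", merged)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def make_params(self, theta) -> ControllerParams:
        """Build a full parameter record from free-parameter values."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError("theta length does not match free parameters")
        return ControllerParams(**dict(zip(self.free_params, theta)))

    def extract(self, params: ControllerParams) -> np.ndarray:
        return np.array([getattr(params, p) for p in self.free_params])

    def check_mask(self, params: ControllerParams) -> None:
        """Reject nonzero values in parameters the spec pins at 0."""
        for name, value in params.as_dict().items():
            if name not in self.free_params and value != 0.0:
                raise ValueError(
                    f"parameter {name} is fixed at 0 in model {self.name}"
                )


def _registry() -> list[ModelSpec]:
    rows = [
        ("P", EQ_PID, ("alpha_P", "tau_A")),
        ("PI", EQ_PID, ("alpha_P", "alpha_I", "tau_A")),
        ("PD", EQ_PID, ("alpha_P", "alpha_D", "tau_A")),
        ("PID", EQ_PID, ("alpha_P", "alpha_I", "alpha_D", "tau_A")),
        ("D1", EQ_DIVA, ("alpha_A", "tau_A", "alpha_S")),
        ("D2", EQ_DIVA, ("alpha_A", "tau_A", "alpha_S", "tau_S")),
        ("D3", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_Av")),
        ("D4", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_Av", "tau_Av")),
        ("D5", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "alpha_Av")),
        ("D6", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av")),
        ("D7", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av")),
        ("D8", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "alpha_Av", "tau_Av", "alpha_Sv")),
        ("D9", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av", "alpha_Sv")),
        ("D10", EQ_DIVA_VEL, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_Av", "tau_Av", "alpha_Sv", "tau_Sv")),
        ("D11", EQ_DIVA_2TS, ("alpha_A", "tau_A", "alpha_As", "tau_As")),
        ("D12", EQ_DIVA_2TS, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As")),
        ("D13", EQ_DIVA_2TS, ("alpha_A", "tau_A", "alpha_S", "alpha_As", "tau_As", "alpha_Ss")),
        ("D14", EQ_DIVA_2TS, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As", "alpha_Ss")),
        ("D15", EQ_DIVA_2TS, ("alpha_A", "tau_A", "alpha_S", "tau_S", "alpha_As", "tau_As", "alpha_Ss", "tau_Ss")),
    ]
    return [ModelSpec(name, eq, free) for name, eq, free in rows]


_REGISTRY = {spec.name: spec for spec in _registry()}


def model_registry() -> list[ModelSpec]:
    """The 19 model configurations, in canonical order."""
    return list(_REGISTRY.values())


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {list(_REGISTRY)}") from None


def registry_table():
    """Registry as a DataFrame (name, equation, n_params, free parameters)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "name": [s.name for s in model_registry()],
            "equation": [s.equation for s in model_registry()],
            "n_params": [s.n_free for s in model_registry()],
            "free_params": [", ".join(s.free_params) for s in model_registry()],
        }
    )


def _delayed(f: np.ndarray, t: int, d: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """f[t - d] per column, with pre-grid history equal to the target (1)."""
    idx = t - d
    vals = f[np.clip(idx, 0, None), cols]
    return np.where(idx < 0, 1.0, vals)


def simulate_population(
    spec: ModelSpec,
    theta: np.ndarray,
    pert: PerturbationProfile,
    grid: TimeGrid,
) -> np.ndarray:
    """Simulate many parameter sets of one model at once.

    ``theta`` has shape (n_sets, n_free) in ``spec.free_params`` order.
    Returns deviation traces of shape (n_sets, n_samples).  Used both for
    single simulations (n_sets = 1) and to evaluate whole swarm
    populations without a per-particle Python loop.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != spec.n_free:
        raise ValueError("theta width does not match free parameters")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameter value")
    n = theta.shape[0]
    p = {f.name: np.zeros(n) for f in fields(ControllerParams)}
    for j, name in enumerate(spec.free_params):
        p[name] = theta[:, j]

    T = grid.n_samples
    i0 = grid.onset_index
    dt = grid.dt
    P = pert.values
    if P.shape != (T,):
        raise ValueError("perturbation profile and grid disagree")
    cols = np.arange(n)

    def steps(tau):
        d = np.rint(tau / dt).astype(int)
        if np.any(d > T):
            raise ValueError("delay exceeds grid capacity")
        return d

    eq = spec.equation
    aud_delay = steps(p["tau_A"])
    f = np.ones((T, n))

    if eq == EQ_PID:
        aP, aI, aD = p["alpha_P"], p["alpha_I"], p["alpha_D"]
        integral = np.zeros(n)
        for t in range(i0, T - 1):
            idx = t - aud_delay
            Pa = pert.shifted(idx)
            eA = 1.0 - _delayed(f, t, aud_delay, cols) * (1.0 + Pa)
            integral += eA
            fdotA = (1.0 + Pa) * (
                _delayed(f, t, aud_delay, cols) - _delayed(f, t, aud_delay + 1, cols)
            )
            f[t + 1] = f[t] + aP * eA + aI * integral - aD * fdotA
    elif eq == EQ_DIVA:
        aA, aS = p["alpha_A"], p["alpha_S"]
        som_delay = steps(p["tau_S"])
        for t in range(i0, T - 1):
            eA = 1.0 - _delayed(f, t, aud_delay, cols) * (1.0 + pert.shifted(t - aud_delay))
            eS = 1.0 - _delayed(f, t, som_delay, cols)
            f[t + 1] = f[t] + aA * eA + aS * eS
    elif eq == EQ_DIVA_VEL:
        aA, aS = p["alpha_A"], p["alpha_S"]
        aAv, aSv = p["alpha_Av"], p["alpha_Sv"]
        som_delay = steps(p["tau_S"])
        # Differential delays add to the channel delay; the sum is floored
        # at 0 steps so a large negative tau_Av cannot look into the future.
        dAv = np.maximum(aud_delay + steps(p["tau_Av"]), 0)
        dSv = np.maximum(som_delay + steps(p["tau_Sv"]), 0)
        for t in range(i0, T - 1):
            eA = 1.0 - _delayed(f, t, aud_delay, cols) * (1.0 + pert.shifted(t - aud_delay))
            eS = 1.0 - _delayed(f, t, som_delay, cols)
            fdotA = (1.0 + pert.shifted(t - dAv)) * (
                _delayed(f, t, dAv, cols) - _delayed(f, t, dAv + 1, cols)
            )
            fdotS = _delayed(f, t, dSv, cols) - _delayed(f, t, dSv + 1, cols)
            f[t + 1] = f[t] + aA * eA - aAv * fdotA + aS * eS - aSv * fdotS
    elif eq == EQ_DIVA_2TS:
        aA, aS = p["alpha_A"], p["alpha_S"]
        aAs, aSs = p["alpha_As"], p["alpha_Ss"]
        som_delay = steps(p["tau_S"])
        dAs = aud_delay + steps(p["tau_As"])
        dSs = som_delay + steps(p["tau_Ss"])
        for t in range(i0, T - 1):
            eA = 1.0 - _delayed(f, t, aud_delay, cols) * (1.0 + pert.shifted(t - aud_delay))
            eAs = 1.0 - _delayed(f, t, dAs, cols) * (1.0 + pert.shifted(t - dAs))
            eS = 1.0 - _delayed(f, t, som_delay, cols)
            eSs = 1.0 - _delayed(f, t, dSs, cols)
            f[t + 1] = f[t] + aA * eA + aAs * eAs + aS * eS + aSs * eSs
    else:
        raise ValueError(f"unknown equation {eq!r}")

    return f.T - 1.0


def simulate(
    spec: ModelSpec,
    params: ControllerParams,
    pert: PerturbationProfile,
    grid: TimeGrid,
) -> Trace:
    """Simulate one model configuration; returns a deviation Trace."""
    params.validate()
    spec.check_mask(params)
    dev = simulate_population(spec, spec.extract(params)[None, :], pert, grid)[0]
    return Trace(grid=grid, values=dev)


def simulate_state_space(
    A: float,
    B: float,
    tau_A: float,
    pert: PerturbationProfile,
    grid: TimeGrid,
) -> Trace:
    """One-state state-space controller f_C = A (f - f_T) + B (f_T - f_A).

    Written independently of :func:`simulate`; with A = -alpha_S and
    B = alpha_A it reproduces the basic DIVA controller (tau_S = 0).
    """
    T, i0, dt = grid.n_samples, grid.onset_index, grid.dt
    d = int(round(tau_A / dt))
    f = np.ones(T)
    for t in range(i0, T - 1):
        idx = t - d
        fa = (f[idx] if idx >= 0 else 1.0) * (1.0 + (pert.values[idx] if idx >= 0 else 0.0))
        f[t + 1] = f[t] + A * (f[t] - 1.0) + B * (1.0 - fa)
    return Trace(grid=grid, values=f - 1.0)


def simulate_lowpass(
    alpha: float,
    tau_A: float,
    pert: PerturbationProfile,
    grid: TimeGrid,
) -> Trace:
    """Leaky-integrator controller: first-order low-pass of the delayed
    auditory error with time constant dt/alpha.

    The corrective state c obeys c[n+1] = (1 - alpha) c[n] + alpha e_A[n];
    equivalent to the basic DIVA controller with alpha_A = alpha_S = alpha.
    """
    T, i0, dt = grid.n_samples, grid.onset_index, grid.dt
    d = int(round(tau_A / dt))
    c = np.zeros(T)
    for t in range(i0, T - 1):
        idx = t - d
        fa = ((1.0 + c[idx]) if idx >= 0 else 1.0) * (
            1.0 + (pert.values[idx] if idx >= 0 else 0.0)
        )
        c[t + 1] = (1.0 - alpha) * c[t] + alpha * (1.0 - fa)
    return Trace(grid=grid, values=c)


def steady_state_compensation(
    alpha_A: float, alpha_S: float, magnitude_cents: float
) -> float:
    """Asymptotic fraction of a sustained shift opposed by the basic DIVA
    controller, measured in cents.

    The controller settles at f* = (a_A + a_S) / (a_A (1 + P) + a_S); the
    returned value is the produced shift in cents over the (negated)
    perturbation in cents, so 1 means the heard pitch is driven fully
    back to target and 0 means no response.
    """
    if magnitude_cents == 0:
        raise ValueError("undefined for a zero-magnitude perturbation")
    P = cents_to_fraction(magnitude_cents)
    denom = alpha_A * (1.0 + P) + alpha_S
    if denom <= 0:
        raise ValueError("no stable equilibrium: alpha_A*(1+P) + alpha_S <= 0")
    f_star = (alpha_A + alpha_S) / denom
    return float(-1200.0 * np.log2(f_star) / magnitude_cents)
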