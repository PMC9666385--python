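"""Synthetic pitch-perturbation experiments with known ground truth.

Two study designs are emulated.  In the first, speakers sustain /a/ for
4 s; a -100 cent shift with a 110-ms linear ramp is applied on a quarter
of 80 trials (never two perturbed trials in a row) at a random onset
1.0-1.5 s into the trial, and trials are parsed from -500 to +1500 ms
around onset.  In the second, speakers sustain /i/ for 3 s; every one of
60 trials carries a +-100 cent step (pseudorandomized so no more than
five consecutive trials shift the same way) at an onset 0.5-1.0 s after
voice onset, parsed from -400 to +1400 ms.

Each simulated trial is the ground-truth controller's deviation trace
scaled to the subject's baseline f_o, corrupted by multiplicative AR(1)
noise (vocal f_o wobbles slowly, not white) plus a per-trial constant
baseline offset (day-to-day / take-to-take drift).  The AR(1) structure
deliberately gives baseline residuals a nontrivial autocorrelation, so
downstream effective-degrees-of-freedom estimation is exercised by
realistic inputs.  Preprocessing mirrors what is done to real data:
trials are aligned to onset, divided by their own baseline average (so
every preprocessed trial has exactly zero baseline mean), expressed as
deviations, and upshift trials are flipped so both directions share the
downshift sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DEFAULT_DT, PerturbationProfile, TimeGrid, Trace, build_perturbation
from .models import ControllerParams, ModelSpec, get_model, simulate

__all__ = [
    "StudyDesign",
    "STUDY1",
    "STUDY2",
    "SubjectTruth",
    "Trial",
    "default_truths",
    "generate_subject",
    "generate_cohort",
    "preprocess_trials",
    "group_mean",
    "compensation_percent",
]


@dataclass(frozen=True)
class StudyDesign:
    """Timing and perturbation layout of one experiment."""

    name: str
    vowel_duration_s: float
    n_trials: int
    perturbed_fraction: float        # fraction of trials carrying a shift
    directions: tuple[int, ...]      # allowed shift signs, e.g. (-1,) or (-1, +1)
    magnitude_cents: float           # unsigned magnitude
    ramp_ms: float
    jitter_window_s: tuple[float, float]
    parse_window_s: tuple[float, float]
    dt: float = DEFAULT_DT
    max_consecutive_same: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.jitter_window_s
        p0, p1 = self.parse_window_s
        if not (p0 < 0 < p1):
            raise ValueError("parse window must straddle the onset")
        if not (0 < lo <= hi) or hi + p1 > self.vowel_duration_s or lo + p0 < 0:
            raise ValueError("jitter window incompatible with trial length")

    @property
    def parse_grid(self) -> TimeGrid:
        return TimeGrid(*self.parse_window_s, dt=self.dt)

    @property
    def baseline_window_s(self) -> float:
        return -self.parse_window_s[0]

    def perturbation(self, direction: int = -1) -> PerturbationProfile:
        """Canonical perturbation on the parse grid (onset at t = 0)."""
        return build_perturbation(
            self.parse_grid, direction * self.magnitude_cents, self.ramp_ms, 0.0
        )


STUDY1 = StudyDesign(
    name="study1",
    vowel_duration_s=4.0,
    n_trials=80,
    perturbed_fraction=0.25,
    directions=(-1,),
    magnitude_cents=100.0,
    ramp_ms=110.0,
    jitter_window_s=(1.0, 1.5),
    parse_window_s=(-0.5, 1.5),
)

STUDY2 = StudyDesign(
    name="study2",
    vowel_duration_s=3.0,
    n_trials=60,
    perturbed_fraction=1.0,
    directions=(-1, 1),
    magnitude_cents=100.0,
    ramp_ms=0.0,
    jitter_window_s=(0.5, 1.0),
    parse_window_s=(-0.4, 1.4),
    max_consecutive_same=5,
)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth controller and noise law for one synthetic speaker.

    Noise defaults emulate a steady healthy voice: ~0.3% multiplicative
    f_o wobble with slow (AR(1) lag-1 = 0.9 at 5-ms steps) dynamics and
    a 0.3% per-trial baseline offset.
    """

    model: str
    params: ControllerParams
    f_T: float = 200.0               # baseline f_o, Hz
    noise_sd: float = 0.003          # stationary SD of the AR(1) wobble (fractional)
    noise_ar1: float = 0.9           # lag-1 coefficient at the grid step
    baseline_drift_sd: float = 0.003  # SD of the per-trial constant offset (fractional)

    def __post_init__(self) -> None:
        get_model(self.model)
        if min(self.noise_sd, self.baseline_drift_sd) < 0 or not (0 <= self.noise_ar1 < 1):
            raise ValueError("invalid noise parameters")

    @property
    def spec(self) -> ModelSpec:
        return get_model(self.model)


def default_truths(
    n_subjects: int,
    rng: np.random.Generator,
    model: str = "D1",
    noise_sd: float = 0.003,
    baseline_drift_sd: float = 0.003,
    dt: float = DEFAULT_DT,
) -> list[SubjectTruth]:
    """Sample a cohort of plausible ground-truth speakers.

    Per-subject gains are drawn around the magnitudes seen in fits to
    adult group data (auditory gain ~0.006-0.03 per step, somatosensory
    gain ~0.008-0.04, feedback delays ~80-140 ms snapped to the grid),
    so synthetic cohorts produce response shapes and compensation levels
    in the experimentally observed range while differing enough between
    subjects to be identifiable.
    """
    spec = get_model(model)
    truths = []
    for _ in range(n_subjects):
        values = {}
        for name in spec.free_params:
            if name.startswith("tau"):
                values[name] = round(rng.uniform(0.08, 0.14) / dt) * dt
            elif name == "alpha_A" or name == "alpha_P":
                values[name] = rng.uniform(0.006, 0.03)
            elif name == "alpha_I":
                values[name] = rng.uniform(-1e-4, 1e-4)
            else:
                values[name] = rng.uniform(0.008, 0.04)
        truths.append(
            SubjectTruth(
                model=model,
                params=ControllerParams(**values),
                f_T=float(rng.uniform(150.0, 250.0)),
                noise_sd=noise_sd,
                baseline_drift_sd=baseline_drift_sd,
            )
        )
    return truths


@dataclass
class Trial:
    """One recorded trial: absolute f_o in Hz on the trial's own clock."""

    f0_hz: np.ndarray
    dt: float
    onset_s: float       # perturbation onset relative to trial start (grid-aligned)
    direction: int       # -1 downshift, +1 upshift, 0 unperturbed
    perturbed: bool


def _direction_sequence(design: StudyDesign, n: int, rng: np.random.Generator):
    """Perturbation flags and signs for a whole session."""
    n_pert = int(round(design.perturbed_fraction * n))
    if design.perturbed_fraction >= 1.0:
        perturbed = np.ones(n, dtype=bool)
    else:
        # no two perturbed trials in a row: rejection-sample the layout
        for _ in range(10_000):
            idx = np.sort(rng.choice(n, size=n_pert, replace=False))
            if not np.any(np.diff(idx) == 1):
                break
        else:  # pragma: no cover - layout always exists at 25% density
            raise RuntimeError("could not place perturbed trials without neighbors")
        perturbed = np.zeros(n, dtype=bool)
        perturbed[idx] = True

    signs = np.zeros(n, dtype=int)
    if len(design.directions) == 1:
        signs[perturbed] = design.directions[0]
    else:
        k = int(np.count_nonzero(perturbed))
        limit = design.max_consecutive_same or k
        for _ in range(10_000):
            seq = np.repeat(design.directions, -(-k // len(design.directions)))[:k]
            rng.shuffle(seq)
            runs = np.diff(np.flatnonzero(np.concatenate(([1], np.diff(seq) != 0, [1]))))
            if runs.max(initial=0) <= limit:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not pseudorandomize directions")
        signs[perturbed] = seq
    return perturbed, signs


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innovation_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innovation_sd, n - 1)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + shocks[t - 1]
    return eps


def generate_subject(
    design: StudyDesign, truth: SubjectTruth, rng: np.random.Generator
) -> list[Trial]:
    """Simulate a full session for one speaker."""
    n = design.n_trials
    perturbed, signs = _direction_sequence(design, n, rng)
    dt = design.dt
    n_samples = int(round(design.vowel_duration_s / dt)) + 1
    trials: list[Trial] = []
    for i in range(n):
        onset = rng.uniform(*design.jitter_window_s)
        onset = round(onset / dt) * dt  # align to the sampling grid
        if perturbed[i]:
            grid = TimeGrid(-onset, design.vowel_duration_s - onset, dt=dt)
            pert = build_perturbation(
                grid, signs[i] * design.magnitude_cents, design.ramp_ms, 0.0
            )
            dev = simulate(truth.spec, truth.params, pert, grid).values
            dev = dev[: n_samples]
        else:
            dev = np.zeros(n_samples)
        wobble = _ar1_noise(n_samples, truth.noise_sd, truth.noise_ar1, rng)
        offset = rng.normal(0.0, truth.baseline_drift_sd) if truth.baseline_drift_sd else 0.0
        f0 = truth.f_T * (1.0 + dev) * (1.0 + offset + wobble)
        trials.append(
            Trial(f0_hz=f0, dt=dt, onset_s=float(onset),
                  direction=int(signs[i]), perturbed=bool(perturbed[i]))
        )
    return trials


def generate_cohort(
    design: StudyDesign, truths: list[SubjectTruth], rng: np.random.Generator
) -> dict[str, list[Trial]]:
    """A full multi-subject dataset keyed S01, S02, ..."""
    return {
        f"S{i + 1:02d}": generate_subject(design, truth, rng)
        for i, truth in enumerate(truths)
    }


def preprocess_trials(
    trials: list[Trial], design: StudyDesign
) -> tuple[list[Trace], Trace]:
    """Align, normalize and sign-fold a session's perturbed trials.

    Each perturbed trial is cropped to the parse window around its onset,
    divided by its own baseline average (making the baseline-window mean
    exactly zero), expressed as a fractional deviation, and negated if it
    was an upshift trial.  Returns the per-trial traces and their
    per-timepoint mean.
    """
    grid = design.parse_grid
    i_rel = np.round(grid.times / design.dt).astype(int)
    out: list[Trace] = []
    for tr in (t for t in trials if t.perturbed):
        if abs(tr.dt - design.dt) > 1e-12:
            raise ValueError("trial dt does not match design dt")
        onset_idx = int(round(tr.onset_s / tr.dt))
        idx = onset_idx + i_rel
        if idx[0] < 0 or idx[-1] >= tr.f0_hz.size:
            raise ValueError("trial too short for the parse window")
        window = tr.f0_hz[idx]
        baseline = float(np.mean(window[: grid.onset_index]))
        dev = window / baseline - 1.0
        if tr.direction > 0:
            dev = -dev
        out.append(Trace(grid=grid, values=dev, f_T=baseline))
    if not out:
        raise ValueError("no perturbed trials to preprocess")
    mean = Trace(grid=grid, values=np.mean([t.values for t in out], axis=0))
    return out, mean


def group_mean(subject_means: list[Trace]) -> tuple[Trace, np.ndarray]:
    """Across-subject mean trace and its per-timepoint standard error."""
    if not subject_means:
        raise ValueError("need at least one subject mean")
    grid = subject_means[0].grid
    if any(t.grid != grid for t in subject_means):
        raise ValueError("subject means are on different grids")
    stack = np.stack([t.values for t in subject_means])
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.zeros(grid.n_samples)
    return Trace(grid=grid, values=mean), sem


def compensation_percent(
    trace: Trace, pert: PerturbationProfile, design: StudyDesign
) -> float:
    """Percent of the shift opposed over the final 250 ms of the window.

    The mean deviation over the last 250 ms is converted to cents and
    expressed against the full perturbation magnitude; positive values
    oppose the shift.
    """
    n_tail = int(round(0.250 / design.dt))
    if trace.values.size < n_tail or n_tail < 1:
        raise ValueError("trace shorter than the 250 ms summary window")
    mean_dev = float(np.mean(trace.values[-n_tail:]))
    response_cents = 1200.0 * np.log2(1.0 + mean_dev)
    return float(-100.0 * response_cents / pert.magnitude_cents)
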