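"""Time grids, perturbation profiles and normalized f_o traces.

All simulation happens in discrete time on a uniform grid aligned to the
perturbation onset (t = 0).  Traces are stored as *fractional deviations*
from the speaker's baseline fundamental frequency, so a value of 0 means
"at baseline" and -0.05 means "5% below baseline".  Pitch shifts are
specified in cents (100 cents = 1 semitone) and converted to fractional
multipliers via the standard 2**(cents/1200) relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_DT",
    "TimeGrid",
    "PerturbationProfile",
    "Trace",
    "cents_to_fraction",
    "fraction_to_cents",
    "build_perturbation",
]

#: Default simulation step, in seconds (5 ms).
DEFAULT_DT = 0.005


def cents_to_fraction(cents: float) -> float:
    """Convert a pitch shift in cents to a fractional f_o multiplier offset.

    A shift of ``cents`` scales frequency by ``2**(cents/1200)``; the
    returned value is that scale factor minus 1 (e.g. +100 cents ->
    +0.059463, -100 cents -> -0.056126).
    """
    cents = float(cents)
    if not np.isfinite(cents):
        raise ValueError("cents must be finite")
    return float(2.0 ** (cents / 1200.0) - 1.0)


def fraction_to_cents(fraction: float) -> float:
    """Inverse of :func:`cents_to_fraction`."""
    fraction = float(fraction)
    if not np.isfinite(fraction) or fraction <= -1.0:
        raise ValueError("fraction must be finite and > -1")
    return float(1200.0 * np.log2(1.0 + fraction))


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid relative to perturbation onset.

    ``t_start`` is negative; the half-open window [t_start, 0) is the
    baseline period during which the controller is silent and against
    which traces are normalized.
    """

    t_start: float
    t_end: float
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not (self.t_start < 0 < self.t_end):
            raise ValueError("grid must satisfy t_start < 0 < t_end")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def onset_index(self) -> int:
        """Index of the sample at t = 0 (perturbation onset)."""
        return int(round(-self.t_start / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_samples)

    def index_of(self, t: float) -> int:
        i = int(round((t - self.t_start) / self.dt))
        if not (0 <= i < self.n_samples):
            raise ValueError(f"time {t} s falls outside the grid")
        return i

    def steps(self, delay_s: float) -> int:
        """Round a delay in seconds to a whole number of grid steps."""
        return int(round(delay_s / self.dt))


@dataclass(frozen=True)
class PerturbationProfile:
    """Sampled fractional pitch shift P(t) applied to auditory feedback."""

    grid: TimeGrid
    magnitude_cents: float
    ramp_ms: float
    onset_index: int
    values: np.ndarray = field(repr=False)  # fractional shift per sample

    @property
    def full_shift(self) -> float:
        """Fractional shift after ramp completion."""
        return cents_to_fraction(self.magnitude_cents)

    def shifted(self, indices: np.ndarray) -> np.ndarray:
        """P at the given sample indices; 0 before the grid starts."""
        clipped = np.clip(indices, 0, None)
        return np.where(indices < 0, 0.0, self.values[clipped])


def build_perturbation(
    grid: TimeGrid,
    magnitude_cents: float,
    ramp_ms: float = 0.0,
    onset_s: float = 0.0,
) -> PerturbationProfile:
    """Sample a pitch-shift profile on ``grid``.

    The shift is zero before ``onset_s``, ramps linearly in *fraction*
    over ``ramp_ms`` milliseconds, and then holds at the full fractional
    shift ``2**(cents/1200) - 1``.  ``ramp_ms = 0`` gives a step.
    """
    if ramp_ms < 0:
        raise ValueError("ramp_ms must be non-negative")
    onset_index = grid.index_of(onset_s)
    t = grid.times
    full = cents_to_fraction(magnitude_cents)
    values = np.zeros(grid.n_samples)
    if magnitude_cents != 0.0:
        elapsed = t - t[onset_index]
        ramp_s = ramp_ms / 1000.0
        if ramp_s > 0:
            frac = np.clip(elapsed / ramp_s, 0.0, 1.0)
        else:
            frac = (elapsed >= 0).astype(float)
        values = np.where(elapsed < 0, 0.0, full * frac)
        values[frac >= 1.0 - 1e-9] = full  # plateau holds the exact full shift
    return PerturbationProfile(
        grid=grid,
        magnitude_cents=float(magnitude_cents),
        ramp_ms=float(ramp_ms),
        onset_index=onset_index,
        values=values,
    )


@dataclass
class Trace:
    """A normalized f_o time series on a grid, as deviation from baseline.

    ``values[i] = f(t_i)/f_baseline - 1``.  ``f_T`` optionally records the
    speaker's baseline mean in Hz for round-tripping to absolute units.
    """

    grid: TimeGrid
    values: np.ndarray
    f_T: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_samples,):
            raise ValueError("trace length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def baseline(self) -> np.ndarray:
        """Samples in the baseline window [t_start, 0)."""
        return self.values[: self.grid.onset_index]

    @property
    def post_onset(self) -> np.ndarray:
        """Samples from perturbation onset (t = 0) to the end of the grid."""
        return self.values[self.grid.onset_index :]
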