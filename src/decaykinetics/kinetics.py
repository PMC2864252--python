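"""Closed-form first-order kinetics of mRNA abundance.

The model: mRNA is produced at a constant rate ``beta`` (concentration/hour)
and degraded in proportion to its concentration with rate constant ``alpha``
(1/hour),

    dX/dt = beta - alpha * X.

At steady state X_ss = beta/alpha.  For a transition that starts at level
``x0`` (e.g. after an instantaneous change in beta),

    X(t) = x0 + (beta/alpha - x0) * (1 - exp(-alpha * t)),

so the speed of *any* transition between steady states is governed only by
alpha: half of the transition is completed at T_1/2 = ln2/alpha, which for
pure decay (beta = 0) is the transcript half-life.  If the transcription
rate is raised by a factor L, the time to reach a k-fold increase in
abundance is

    T_k = -log2(1 - f) * T_1/2,    f = (k - 1)/(L - 1),

linear in the half-life at fixed (k, L).  A corollary for suppression: even
a complete transcriptional shut-off (beta = 0) can only achieve a fold_down
drop by time t if T_1/2 <= t*ln2/ln(fold_down); observed drops faster than
that bound imply active destabilization of the transcript.

All times are hours.  The production path is purely closed-form; numerical
integration appears only as an oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KineticParameters",
    "PulseStimulus",
    "Trajectory",
    "FoldTarget",
    "steady_state_level",
    "half_life_from_rate",
    "rate_from_half_life",
    "transition_level",
    "time_to_fold_induction",
    "simulate_pulse",
    "calibrate_beta_for_level",
    "shutoff_max_half_life",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class KineticParameters:
    """Parameters (beta, alpha, x0) of one transcript.

    beta : transcription rate, concentration/hour, >= 0
    alpha: degradation rate constant, 1/hour, > 0
    x0   : concentration at t = 0, >= 0
    """

    beta: float
    alpha: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.x0 < 0:
            raise ValueError(f"x0 must be >= 0, got {self.x0}")

    @property
    def steady_state(self) -> float:
        return self.beta / self.alpha

    @property
    def half_life(self) -> float:
        return LN2 / self.alpha


@dataclass(frozen=True)
class PulseStimulus:
    """A square pulse of transcription: rate ``beta_on`` during
    [t_on, t_off), ``beta_off`` at all other times (including before t_on).
    The switch is instantaneous."""

    t_on: float
    t_off: float
    beta_on: float
    beta_off: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t_on < self.t_off):
            raise ValueError(f"t_on must be < t_off, got {self.t_on}, {self.t_off}")
        if self.beta_on < 0 or self.beta_off < 0:
            raise ValueError("transcription rates must be >= 0")


@dataclass
class Trajectory:
    """A simulated abundance time course on a fixed grid (hours)."""

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.shape != self.levels.shape or self.times.ndim != 1:
            raise ValueError("times and levels must be 1-d of equal length")
        if self.times.size == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.levels < 0):
            raise ValueError("levels must be non-negative")

    def level_at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t))
        if i >= self.times.size or not math.isclose(self.times[i], t, abs_tol=1e-12):
            raise KeyError(f"time {t} not on grid")
        return float(self.levels[i])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_h": self.times, "level": self.levels}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class FoldTarget:
    """A k-fold induction target after an L-fold rise in transcription rate.

    The fraction of the steady-state transition that must be traversed to
    reach k-fold is f = (k-1)/(L-1); the target is attainable iff k <= L,
    and reached in finite time iff k < L.
    """

    k: float
    L: float
    f: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.k > 1):
            raise ValueError(f"fold of induction k must be > 1, got {self.k}")
        if not (self.L > 1):
            raise ValueError(f"transcription factor L must be > 1, got {self.L}")
        if self.k > self.L:
            raise ValueError(
                f"k-fold induction unattainable: k={self.k} exceeds L={self.L} "
                "(new steady state is only L-fold above baseline)"
            )
        object.__setattr__(self, "f", (self.k - 1.0) / (self.L - 1.0))


def steady_state_level(p: KineticParameters) -> float:
    """Equilibrium abundance beta/alpha."""
    return p.beta / p.alpha


def half_life_from_rate(alpha: float) -> float:
    """T_1/2 = ln2/alpha (hours)."""
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return LN2 / alpha


def rate_from_half_life(t_half: float) -> float:
    """alpha = ln2/T_1/2 (1/hour)."""
    if not (t_half > 0):
        raise ValueError(f"half-life must be > 0, got {t_half}")
    return LN2 / t_half


def transition_level(t, p: KineticParameters):
    """Abundance at time ``t`` (hours) of the relaxation toward beta/alpha.

    X(t) = x0 + (beta/alpha - x0)*(1 - exp(-alpha t)).  Accepts a scalar or
    array of non-negative times; monotone from x0 toward the steady state.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = p.x0 + (p.steady_state - p.x0) * (-np.expm1(-p.alpha * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def time_to_fold_induction(target: FoldTarget, t_half: float) -> float:
    """Time T_k to reach a k-fold induction, -log2(1-f)*T_1/2.

    Returns ``math.inf`` when k == L (f = 1): k-fold is the asymptote of the
    new steady state and is approached but never attained.
    """
    if not (t_half > 0):
        raise ValueError(f"half-life must be > 0, got {t_half}")
    if target.f >= 1.0:
        return math.inf
    return -math.log2(1.0 - target.f) * t_half


def simulate_pulse(
    p_base: KineticParameters, stim: PulseStimulus, grid: Sequence[float]
) -> Trajectory:
    """Simulate a square-pulse response by piecewise closed form.

    ``p_base`` supplies alpha and the level x0 at the start of the grid; the
    transcription rate at every time comes from ``stim`` (beta_on inside
    [t_on, t_off), beta_off outside).  On each constant-rate segment the
    exact relaxation ``transition_level`` is applied with the level at the
    segment start as the new x0 — no numerical integration.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] > stim.t_on:
        raise ValueError("grid must start at or before pulse onset")

    bounds = [grid[0]]
    for edge in (stim.t_on, stim.t_off):
        if edge > bounds[-1] and edge < grid[-1]:
            bounds.append(edge)
    bounds.append(math.inf)

    def rate_at(t: float) -> float:
        return stim.beta_on if stim.t_on <= t < stim.t_off else stim.beta_off

    levels = np.empty_like(grid)
    x = p_base.x0
    for start, end in zip(bounds[:-1], bounds[1:]):
        seg = KineticParameters(beta=rate_at(start), alpha=p_base.alpha, x0=x)
        mask = (grid >= start) & (grid < end)
        levels[mask] = transition_level(grid[mask] - start, seg)
        if math.isfinite(end):
            x = transition_level(end - start, seg)
    return Trajectory(times=grid, levels=levels)


def calibrate_beta_for_level(
    target_level: float, alpha: float, t_end: float, x0: float = 0.0
) -> float:
    """Transcription rate bringing the transient to ``target_level`` at t_end.

    Inverts the closed form: beta = alpha*(target - x0*e^{-alpha t})/(1 - e^{-alpha t}).
    Raises if the target lies below the decayed remnant of x0 (a negative
    beta would be required).
    """
    if not (alpha > 0) or not (t_end > 0):
        raise ValueError("alpha and t_end must be > 0")
    if target_level < 0:
        raise ValueError("target level must be >= 0")
    decay = math.exp(-alpha * t_end)
    if target_level < x0 * decay:
        raise ValueError(
            f"target {target_level} unreachable: below residual "
            f"{x0 * decay:.6g} of x0 even with zero transcription"
        )
    return alpha * (target_level - x0 * decay) / (1.0 - decay)


def shutoff_max_half_life(fold_down: float, t: float) -> float:
    """Largest half-life compatible with a fold_down drop by time t under a
    complete transcriptional shut-off.

    With beta = 0, X(t) = X0*e^{-alpha t}; an observed drop of fold_down by
    time t requires alpha >= ln(fold_down)/t, i.e. T_1/2 <= t*ln2/ln(fold_down).
    A transcript whose resting half-life exceeds this bound must have been
    actively destabilized.
    """
    if not (fold_down > 1):
        raise ValueError(f"fold_down must be > 1, got {fold_down}")
    if not (t > 0):
        raise ValueError(f"time must be > 0, got {t}")
    return t * LN2 / math.log(fold_down)
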