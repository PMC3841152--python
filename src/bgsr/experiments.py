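"""The Monte-Carlo experiment protocol: P-vs-D sweeps, smoothing, peak tables.

The central observable is the probability of reach ``P``: the fraction of
trials whose settled state ends in the target basin.  ``P`` is estimated on
a grid of noise amplitudes ``D`` (default 0 to 10, step 0.2) for a given
stimulus duration ``T``.  Raw curves are noisy at large ``D``; before peak
extraction they are supersampled (linear midpoints, grid step 0.2 -> 0.1)
and smoothed with a centered moving average of odd window ``WIN`` (9 for
white noise, 15 for colored).  The peak of the smoothed curve, ``(D*, P*)``,
is the stochastic-resonance summary reported in the peak tables.

The fractional-time metric ``FT`` is an alternative per-trial observable:
the fraction of integration steps the state spends within a tolerance of the
target position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SRParams, Trajectory, simulate_batch
from .signals import KickStimulus, NoiseSpec

DEFAULT_D_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.2), 10)
DEFAULT_T_LIST_WHITE = (100, 250, 500, 1000, 5000, 10000)
DEFAULT_T_LIST_COLORED = (100, 250, 500, 750, 1000)
WIN_WHITE = 9
WIN_COLORED = 15


@dataclass
class SweepResult:
    """P over a D grid for one (T, noise kind); raw or smoothed."""

    D_grid: np.ndarray
    P: np.ndarray
    T: int
    n_trials: int
    noise_kind: str
    seed: int
    raw: bool = True
    win: int | None = None

    def __post_init__(self) -> None:
        self.D_grid = np.asarray(self.D_grid, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.D_grid.size != self.P.size:
            raise ValueError("D_grid and P must have equal length")
        if self.D_grid.size == 0:
            raise ValueError("empty sweep")


@dataclass(frozen=True)
class PeakSummary:
    """Smoothed-curve maximum for one stimulus duration."""

    T: int
    D_at_peak: float
    P_peak: float
    WIN: int


def estimate_P(
    p: SRParams,
    stim: KickStimulus,
    noise: NoiseSpec,
    n_trials: int,
    seed,
) -> float:
    """Fraction of reaches over ``n_trials`` seeded trials.

    Trial ``i`` uses the generator seeded by ``(*seed, i)``, so the estimate
    is reproducible and independent of chunking.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    reached = simulate_batch(p, stim, noise, n_trials, seed)
    return float(reached.mean())


def sweep_P_vs_D(
    p: SRParams,
    stim: KickStimulus,
    noise: NoiseSpec,
    D_grid: Sequence[float] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
) -> SweepResult:
    """One ``estimate_P`` per grid point; point ``j`` is seeded by (seed, j)."""
    grid = DEFAULT_D_GRID if D_grid is None else np.asarray(D_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("D grid is empty")
    if grid.size > 1 and not (np.diff(grid) > 0).all():
        raise ValueError("D grid must be strictly increasing")
    P = np.empty(grid.size)
    for j, D in enumerate(grid):
        P[j] = estimate_P(p, stim, noise.with_D(float(D)), n_trials, [seed, j])
    return SweepResult(grid, P, stim.T, n_trials, noise.kind, seed, raw=True)


def sweep_FT_vs_D(
    p: SRParams,
    stim: KickStimulus,
    noise: NoiseSpec,
    D_grid: Sequence[float] | None = None,
    n_trials: int = 300,
    seed: int = 0,
    tol: float = 0.1,
) -> SweepResult:
    """Mean fractional time at the target as a function of noise amplitude."""
    grid = DEFAULT_D_GRID if D_grid is None else np.asarray(D_grid, dtype=float)
    ft_mean = np.empty(grid.size)
    for j, D in enumerate(grid):
        _, ft = simulate_batch(p, stim, noise.with_D(float(D)), n_trials, [seed, j], ft_tol=tol)
        ft_mean[j] = ft.mean()
    return SweepResult(grid, ft_mean, stim.T, n_trials, noise.kind, seed, raw=True)


def supersample_and_smooth(curve: SweepResult, WIN: int) -> SweepResult:
    """Double the grid resolution by linear interpolation, then window-average.

    Stage 1 inserts the linear midpoint between each adjacent pair of points
    (grid step 0.2 -> 0.1).  Stage 2 replaces every value by the mean of the
    WIN nearest values; at the edges the window is truncated to the available
    points, so constant curves are preserved exactly.
    """
    if WIN < 1 or WIN % 2 == 0:
        raise ValueError(f"WIN must be odd and >= 1, got {WIN}")
    if not curve.raw:
        raise ValueError("curve is already smoothed")
    n = curve.D_grid.size
    if n == 1:
        grid2, v2 = curve.D_grid.copy(), curve.P.copy()
    else:
        grid2 = np.empty(2 * n - 1)
        v2 = np.empty(2 * n - 1)
        grid2[0::2] = curve.D_grid
        grid2[1::2] = 0.5 * (curve.D_grid[:-1] + curve.D_grid[1:])
        v2[0::2] = curve.P
        v2[1::2] = 0.5 * (curve.P[:-1] + curve.P[1:])
    if WIN > v2.size:
        raise ValueError(f"WIN = {WIN} exceeds the supersampled length {v2.size}")
    k = WIN // 2
    csum = np.concatenate([[0.0], np.cumsum(v2)])
    idx = np.arange(v2.size)
    lo = np.maximum(idx - k, 0)
    hi = np.minimum(idx + k, v2.size - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return SweepResult(
        grid2, smoothed, curve.T, curve.n_trials, curve.noise_kind, curve.seed,
        raw=False, win=WIN,
    )


def find_peak(curve: SweepResult) -> PeakSummary:
    """Grid point of the maximum P; ties broken toward the smallest D."""
    j = int(np.argmax(curve.P))  # argmax returns the first (smallest-D) maximum
    return PeakSummary(
        T=curve.T,
        D_at_peak=float(curve.D_grid[j]),
        P_peak=float(curve.P[j]),
        WIN=curve.win if curve.win is not None else 1,
    )


def fractional_time(traj: Trajectory, tol: float) -> float:
    """Fraction of steps with |x - x_target| < tol, relaxation included."""
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    return float(np.mean(np.abs(traj.x - traj.x_target) < tol))


def peak_table(
    T_list: Sequence[int],
    noise_kind: str,
    WIN: int,
    p: SRParams | None = None,
    A0: float = 0.25,
    D_grid: Sequence[float] | None = None,
    n_trials: int = 1000,
    seed: int = 0,
) -> list[PeakSummary]:
    """Sweep -> supersample & smooth -> peak, one row per stimulus duration."""
    p = p if p is not None else SRParams()
    rows = []
    for ti, T in enumerate(T_list):
        stim = KickStimulus(A0=A0, T=int(T))
        noise = NoiseSpec(kind=noise_kind, D=0.0)
        raw = sweep_P_vs_D(p, stim, noise, D_grid=D_grid, n_trials=n_trials, seed=seed + ti)
        rows.append(find_peak(supersample_and_smooth(raw, WIN)))
    return rows


def sweep_to_frame(curve: SweepResult) -> pd.DataFrame:
    """Tabular form with the fixed column layout of the sweep output files."""
    return pd.DataFrame(
        {
            "D": curve.D_grid,
            "P": curve.P,
            "T": curve.T,
            "noise_kind": curve.noise_kind,
            "n_trials": curve.n_trials,
            "seed": curve.seed,
        }
    )


def table_to_frame(rows: Sequence[PeakSummary]) -> pd.DataFrame:
    """Tabular form of a peak table: columns T, D_at_peak, P_peak, WIN."""
    return pd.DataFrame(
        {
            "T": [r.T for r in rows],
            "D_at_peak": [r.D_at_peak for r in rows],
            "P_peak": [r.P_peak for r in rows],
            "WIN": [r.WIN for r in rows],
        }
    )
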