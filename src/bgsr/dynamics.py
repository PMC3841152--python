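"""The reduced bistable dynamics of reaching and its stochastic integration.

Movement preparation is modelled as an overdamped particle in the quartic
double well ``V(x) = -a x^2/2 + b x^4/4`` whose minima at ``x = -sqrt(a/b)``
and ``x = +sqrt(a/b)`` are the resting and target positions of the arm.  A
trial integrates the Langevin equation

    dx = eps * [a x - b x^3 + s(t)] dt + sqrt(eps) * psi dW

with the half-sinusoid kick ``s`` and gated noise ``psi`` (see
:mod:`bgsr.signals`), then relaxes noise-free so the state settles into one
basin; the trial is a successful reach iff the settled state is in the
right-hand (target) basin.  ``eps`` is a global rate gain of the update: it
scales drift and kick and the noise variance alike, so increasing ``eps`` is
equivalent to lengthening the effective stimulus window.

Time bookkeeping: the stimulus duration ``T`` is expressed in ms; each ms is
integrated with ``steps_per_ms`` Euler-Maruyama steps of size ``dt`` (model
time units).  The product ``dt * steps_per_ms`` (default 0.4) is the
calibration constant mapping model time to ms; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .signals import KickStimulus, NoiseSpec, noise_sequence

_OVERFLOW_CHECK_EVERY = 8


class SimulationOverflowError(FloatingPointError):
    """State left the admissible range during integration.

    Carries the integration step and the indices of the offending trials so a
    failing configuration can be reported precisely instead of silently
    propagating NaNs.
    """

    def __init__(self, step: int, trial_indices):
        self.step = step
        self.trial_indices = list(np.atleast_1d(trial_indices))
        super().__init__(
            f"state exceeded the overflow limit at integration step {step} "
            f"in trial(s) {self.trial_indices}; the configuration is outside "
            f"the stable parameter range"
        )


@dataclass(frozen=True)
class SRParams:
    """Coefficients and integration constants of the reduced dynamics.

    a, b : quartic-well coefficients (> 0); minima at +-sqrt(a/b), barrier
        height a^2/(4b).
    epsilon : global rate gain of the update (> 0).
    dt : Euler-Maruyama step in model time units (> 0).
    steps_per_ms : integration steps per ms of stimulus time (>= 1).
    relax_steps : noise-free settling steps appended after the window (>= 0).
    settle_tol : admissible distance from a minimum for a settled state.
    overflow_limit : |x| beyond which a trial is aborted as an error.
    """

    a: float = 1.0
    b: float = 1.0
    epsilon: float = 1.0
    dt: float = 0.1
    steps_per_ms: int = 4
    relax_steps: int = 2000
    settle_tol: float = 1e-3
    overflow_limit: float = 50.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "epsilon", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"model.{name} must be > 0, got {getattr(self, name)}")
        if self.steps_per_ms < 1:
            raise ValueError(f"model.steps_per_ms must be >= 1, got {self.steps_per_ms}")
        if self.relax_steps < 0:
            raise ValueError(f"model.relax_steps must be >= 0, got {self.relax_steps}")

    @property
    def x_min(self) -> float:
        """Position of the stable minima, sqrt(a/b)."""
        return float(np.sqrt(self.a / self.b))

    @property
    def barrier_height(self) -> float:
        """Barrier height Delta V = a^2 / (4 b)."""
        return self.a * self.a / (4.0 * self.b)


@dataclass
class Trajectory:
    """A single simulated trial on the integration-step grid.

    ``t`` holds the integration-step indices, ``x`` the state, ``window_end``
    the step at which the stimulus/noise gate closes, ``x_final`` the settled
    terminal state and ``reached`` the basin dichotomy ``x_final > 0``.
    """

    t: np.ndarray
    x: np.ndarray
    window_end: int
    reached: bool
    x_final: float
    x_rest: float
    x_target: float
    steps_per_ms: int = 1

    @property
    def time_ms(self) -> np.ndarray:
        return self.t / self.steps_per_ms


def potential_value(x, p: SRParams):
    """The bistable potential V(x) = -a x^2/2 + b x^4/4 (even in x)."""
    x = np.asarray(x, dtype=float)
    v = -p.a * x**2 / 2.0 + p.b * x**4 / 4.0
    return v if v.ndim else float(v)


def drift(x, p: SRParams):
    """-dV/dx = a x - b x^3 (the rate gain epsilon is applied by the integrator)."""
    x = np.asarray(x, dtype=float)
    f = p.a * x - p.b * x**3
    return f if f.ndim else float(f)


def critical_amplitude(p: SRParams) -> float:
    """Saddle-node value of constant forcing that destroys the left well.

    The left stable equilibrium of ``x' = a x - b x^3 + xi0`` merges with the
    unstable equilibrium when drift and its derivative vanish together, at
    ``x = -sqrt(a/3b)``; the closed form is ``(2a/3) sqrt(a/(3b))``.  For
    a = b = 1 this is 2/(3 sqrt 3) ~= 0.3849.
    """
    return (2.0 * p.a / 3.0) * float(np.sqrt(p.a / (3.0 * p.b)))


def _kick_samples(stim: KickStimulus, p: SRParams) -> np.ndarray:
    n = stim.T * p.steps_per_ms
    return stim.A0 * np.sin(np.pi * np.arange(n) / n)


def _integrate(
    x: np.ndarray,
    psi: np.ndarray,
    s: np.ndarray,
    p: SRParams,
    record: bool = False,
):
    """Advance a vector of trials through window + relaxation.

    ``psi`` has one row per trial covering window (+ relaxation when the
    noise is ungated); ``s`` covers the window only.  Returns the final
    states, and the full per-step record when ``record`` is true.
    """
    n_window = s.size
    n_total = n_window + p.relax_steps
    g = p.dt * p.epsilon
    rt = np.sqrt(g)
    lim = p.overflow_limit
    rec = np.empty((n_total + 1, x.size)) if record else None
    if record:
        rec[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_total):
            f = p.a * x - p.b * x**3
            if i < n_window:
                f = f + s[i]
            x = x + g * f
            if i < psi.shape[1]:
                x = x + rt * psi[:, i]
            if record:
                rec[i + 1] = x
            if i % _OVERFLOW_CHECK_EVERY == 0 or i == n_total - 1:
                bad = ~(np.abs(x) <= lim)
                if bad.any():
                    raise SimulationOverflowError(i, np.nonzero(bad)[0])
    return x, rec


def simulate_trial(
    p: SRParams,
    stim: KickStimulus,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one trial and return its full trajectory.

    The state starts at the resting position ``-sqrt(a/b)``; during the
    stimulus window it feels the kick and the gated noise, afterwards it
    relaxes deterministically for ``relax_steps``.  The trajectory is fully
    determined by the generator's state.
    """
    n_window = stim.T * p.steps_per_ms
    n_total = n_window + p.relax_steps
    n_noise = n_window if noise.gated else n_total
    psi = noise_sequence(n_noise, noise, n_window, rng)[None, :]
    s = _kick_samples(stim, p)
    x0 = np.array([-p.x_min])
    xf, rec = _integrate(x0, psi, s, p, record=True)
    x_final = float(xf[0])
    return Trajectory(
        t=np.arange(n_total + 1),
        x=rec[:, 0],
        window_end=n_window,
        reached=x_final > 0.0,
        x_final=x_final,
        x_rest=-p.x_min,
        x_target=p.x_min,
        steps_per_ms=p.steps_per_ms,
    )


def _trial_chunks(n_trials: int, chunk: int) -> Iterator[tuple[int, int]]:
    for lo in range(0, n_trials, chunk):
        yield lo, min(lo + chunk, n_trials)


def simulate_batch(
    p: SRParams,
    stim: KickStimulus,
    noise: NoiseSpec,
    n_trials: int,
    seed,
    ft_tol: float | None = None,
    chunk: int = 256,
):
    """Vectorised Monte-Carlo batch of trials.

    Trial ``i`` draws its noise from ``numpy.random.default_rng([*seed, i])``,
    so individual trials are reproducible independently of the batch layout.
    Returns the boolean reach flags; when ``ft_tol`` is given, additionally
    returns each trial's fractional time (fraction of steps within ``ft_tol``
    of the target position, relaxation included).
    """
    seed_key = [int(v) for v in np.atleast_1d(seed)]
    n_window = stim.T * p.steps_per_ms
    n_total = n_window + p.relax_steps
    n_noise = n_window if noise.gated else n_total
    s = _kick_samples(stim, p)
    g = p.dt * p.epsilon
    rt = np.sqrt(g)
    lim = p.overflow_limit
    reached = np.empty(n_trials, dtype=bool)
    ft = np.zeros(n_trials) if ft_tol is not None else None
    if ft_tol is not None and ft_tol <= 0:
        raise ValueError(f"ft_tol must be > 0, got {ft_tol}")
    for lo, hi in _trial_chunks(n_trials, chunk):
        m = hi - lo
        psi = np.empty((m, n_noise))
        for j in range(m):
            rng = np.random.default_rng(seed_key + [lo + j])
            psi[j] = noise_sequence(n_noise, noise, n_window, rng)
        x = np.full(m, -p.x_min)
        if ft_tol is None:
            x, _ = _integrate(x, psi, s, p)
        else:
            near = np.zeros(m, dtype=np.int64)
            with np.errstate(over="ignore", invalid="ignore"):
                for i in range(n_total):
                    f = p.a * x - p.b * x**3
                    if i < n_window:
                        f = f + s[i]
                    x = x + g * f
                    if i < psi.shape[1]:
                        x = x + rt * psi[:, i]
                    near += np.abs(x - p.x_min) < ft_tol
                    if i % _OVERFLOW_CHECK_EVERY == 0 or i == n_total - 1:
                        bad = ~(np.abs(x) <= lim)
                        if bad.any():
                            raise SimulationOverflowError(i, lo + np.nonzero(bad)[0])
            ft[lo:hi] = near / n_total
        reached[lo:hi] = x > 0.0
    if ft_tol is not None:
        return reached, ft
    return reached
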