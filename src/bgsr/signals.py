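"""Forcing signals: the half-sinusoid "will" kick and gated white/colored noise.

The kick models an internally generated movement command.  It is a single
half-wave of a sinusoid with amplitude ``A0`` and duration ``T`` (in ms of
stimulus time); by construction ``A0`` is chosen below the saddle-node
threshold of the bistable well, so the kick alone can never produce a reach.

Noise models the exploratory drive attributed to the indirect pathway of the
basal ganglia.  White noise draws independent Gaussians; colored noise is a
discrete Ornstein-Uhlenbeck (AR(1)) process modelling the temporally
correlated subthalamic activity seen under dopamine depletion.  Both are
*gated*: samples outside the stimulus window are exactly zero, so the
relaxation phase after the kick is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

#: Per-sample white-noise standard deviation per unit of the D axis.
#: Calibrated once so that the white-noise probability-of-reach curve for a
#: T = 1000 ms stimulus peaks near D = 3.2 (see docs/methods.md).
WHITE_GAIN = 0.087

#: Stationary standard deviation of the colored (AR(1)) process per unit D.
#: Calibrated once so the colored T = 1000 ms curve peaks near D = 7.3.
COLORED_SD_PER_D = 0.008

#: AR(1) recursion constant per noise sample.  Samples are produced at the
#: integrator's step cadence (default 4 per ms), so 1/60 corresponds to a
#: noise correlation time of ~15 ms.
COLORED_LAM = 1.0 / 60.0


@dataclass(frozen=True)
class KickStimulus:
    """Half-wave sinusoid will signal: ``s(n) = A0 sin(pi n / T)`` on [0, T)."""

    A0: float = 0.25
    T: int = 1000

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValueError(f"stimulus.A0 must be >= 0, got {self.A0}")
        if self.T < 1:
            raise ValueError(f"stimulus.T must be >= 1 step, got {self.T}")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise process specification.

    Parameters
    ----------
    kind
        ``"white"`` (independent Gaussians) or ``"colored"`` (AR(1)).
    D
        Noise amplitude on the operational axis of the reach-probability
        sweeps.  ``D`` is not a physical diffusion constant; the per-sample
        scale is ``gain * D`` with a documented calibration gain.
    lam
        AR(1) recursion constant of the colored process; the lag-1
        autocorrelation of an ungated colored sequence is ``1 - lam``.
    gated
        If true (default), samples at indices >= the stimulus window are
        exactly zero.
    white_gain, colored_sd
        Calibration gains, see module constants.
    """

    kind: str = "white"
    D: float = 0.0
    lam: float = COLORED_LAM
    gated: bool = True
    white_gain: float = WHITE_GAIN
    colored_sd: float = COLORED_SD_PER_D

    def __post_init__(self) -> None:
        if self.kind not in ("white", "colored"):
            raise ValueError(f"noise.kind must be 'white' or 'colored', got {self.kind!r}")
        if self.D < 0:
            raise ValueError(f"noise.D must be >= 0, got {self.D}")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"noise.lam must be in (0, 1], got {self.lam}")

    def with_D(self, D: float) -> "NoiseSpec":
        return NoiseSpec(self.kind, D, self.lam, self.gated, self.white_gain, self.colored_sd)


def kick_value(n, stim: KickStimulus):
    """Kick forcing at step index ``n``: ``A0 sin(pi n / T)`` for 0 <= n < T, else 0.

    Accepts scalars or arrays; nonnegative everywhere, peaks at ``A0`` for
    ``n = T/2``, and vanishes outside the stimulus window.
    """
    n = np.asarray(n, dtype=float)
    inside = (n >= 0) & (n < stim.T)
    out = np.where(inside, stim.A0 * np.sin(np.pi * n / stim.T), 0.0)
    return out if out.ndim else float(out)


def kick_waveform(stim: KickStimulus, samples_per_step: int = 1) -> np.ndarray:
    """The kick sampled on a grid of ``T * samples_per_step`` points."""
    m = int(samples_per_step)
    idx = np.arange(stim.T * m) / m
    return np.asarray(kick_value(idx, stim))


def _colored_filter(innovations: np.ndarray, lam: float) -> np.ndarray:
    """AR(1) recursion c_{n+1} = (1-lam) c_n + innovation_n with c_0 = 0.

    Returns the sequence c_0 .. c_{N-1} (the last innovation is unused),
    filtering along the last axis.
    """
    c = lfilter([1.0], [1.0, -(1.0 - lam)], innovations[..., :-1], axis=-1)
    zero = np.zeros(innovations.shape[:-1] + (1,))
    return np.concatenate([zero, c], axis=-1)


def noise_sequence(
    n_samples: int,
    spec: NoiseSpec,
    window_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate a gated noise sample sequence of length ``n_samples``.

    White: ``psi_n = white_gain * D * eta_n`` with eta standard normal.
    Colored: ``c_{n+1} = (1 - lam) c_n + inj * eta_n`` with ``c_0 = 0`` and
    ``psi_n = c_n``, where the injection amplitude ``inj`` is chosen so the
    stationary standard deviation of c equals ``colored_sd * D``.  Gating
    zeroes every sample with index >= ``window_len``.
    """
    if not 0 <= window_len <= n_samples:
        raise ValueError(f"need 0 <= window_len <= n_samples, got {window_len} > {n_samples}")
    active = window_len if spec.gated else n_samples
    psi = np.zeros(n_samples)
    if active == 0 or spec.D == 0.0:
        return psi
    eta = rng.standard_normal(active)
    if spec.kind == "white":
        psi[:active] = spec.white_gain * spec.D * eta
    else:
        inj = spec.colored_sd * spec.D * np.sqrt(1.0 - (1.0 - spec.lam) ** 2)
        psi[:active] = _colored_filter(inj * eta, spec.lam)
    return psi
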