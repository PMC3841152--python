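"""Closed-form stochastic-resonance reference quantities.

These are the standard linear-response results for a periodically forced
bistable well: the Kramers escape rate, the stationary variance of the
unforced well, and the response amplitude at the forcing frequency.  They
serve as qualitative sanity oracles for the Monte-Carlo simulator (trend
checks), not as quantitative predictions of the reach-probability curves:
the simulated stimulus is a single half-wave, not a steady sinusoid.

``D`` in this module is the noise *intensity* of the Langevin equation
``dx = -V'(x) dt + sqrt(2 D) dW`` (the temperature of the stationary density
``exp(-V/D)``).  The mapping from the simulator's operational noise
amplitude is provided by :func:`noise_intensity`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .dynamics import SRParams, potential_value
from .signals import NoiseSpec


@dataclass(frozen=True)
class TheoryInputs:
    """Inputs to the linear-response formula: well, intensity and forcing."""

    p: SRParams
    D: float
    A0: float = 0.0
    f: float = 0.0

    @property
    def Omega(self) -> float:
        return 2.0 * np.pi * self.f


def noise_intensity(noise: NoiseSpec, p: SRParams) -> float:
    """Map the simulator's white-noise amplitude D to a Langevin intensity.

    The integrator injects ``sqrt(eps * dt) * gain * D`` per step, i.e. the
    variance accumulates at rate ``eps * (gain * D)^2`` per unit model time,
    which corresponds to intensity ``eps * (gain * D)^2 / 2``.
    """
    return p.epsilon * (noise.white_gain * noise.D) ** 2 / 2.0


def kramers_rate(p: SRParams, D: float) -> float:
    """Kramers escape rate over the barrier of the quartic well.

    r_K = sqrt(V''(x_min) |V''(x_max)|) / (2 pi) * exp(-Delta V / D); for the
    quartic well the curvature prefactor is a / (sqrt(2) pi).  Strictly
    increasing in D.
    """
    if D <= 0:
        raise ValueError(f"noise intensity D must be > 0, got {D}")
    prefactor = np.sqrt(2.0 * p.a * p.a) / (2.0 * np.pi)
    return float(prefactor * np.exp(-p.barrier_height / D))


def stationary_variance(p: SRParams, D: float) -> float:
    """Variance <x^2> of the stationary density exp(-V(x)/D) by quadrature.

    The integration range is truncated where the Boltzmann weight falls below
    1e-12 of its peak, so the neglected tail mass is negligible at the
    returned precision.
    """
    if D <= 0:
        raise ValueError(f"noise intensity D must be > 0, got {D}")
    # V(L) - V(x_min) >= D * 60 puts the tail weight below e-60 of the peak.
    L = p.x_min + np.sqrt(2.0) * (60.0 * D * 4.0 / p.b) ** 0.25 + 1.0
    vmin = potential_value(p.x_min, p)
    w = lambda x: np.exp(-(potential_value(x, p) - vmin) / D)
    crit = [-p.x_min, 0.0, p.x_min]
    kw = dict(limit=200, points=crit, epsabs=0.0, epsrel=1e-11)
    num, err_n = quad(lambda x: x * x * w(x), -L, L, **kw)
    den, err_d = quad(w, -L, L, **kw)
    if den <= 0 or err_d > 1e-6 * den or err_n > 1e-6 * max(num, 1e-300):
        raise ArithmeticError("stationary_variance quadrature did not converge")
    return float(num / den)


def response_amplitude(inputs: TheoryInputs) -> float:
    """Linear-response amplitude at the forcing frequency.

    x_bar = (A0 <x0^2> / D) * 2 r_K / sqrt(4 r_K^2 + Omega^2).  For fixed A0
    and f > 0 this exhibits the stochastic-resonance maximum at an
    intermediate intensity D, and it grows monotonically as f -> 0.
    """
    if inputs.A0 < 0 or inputs.f < 0:
        raise ValueError("A0 and f must be >= 0")
    rk = kramers_rate(inputs.p, inputs.D)
    var = stationary_variance(inputs.p, inputs.D)
    omega = inputs.Omega
    return float(inputs.A0 * var / inputs.D * 2.0 * rk / np.sqrt(4.0 * rk * rk + omega * omega))
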