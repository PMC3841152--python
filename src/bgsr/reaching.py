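"""Actor-critic reaching model: arm, motor cortex, and basal-ganglia update.

The full model from which the bistable reduction is derived.  A two-joint
planar arm with four muscles is driven by the combined activation
``g = alpha * g_m + beta * g_bg``: the motor-cortex perceptron output
``g_m`` (trained, deliberate) plus the basal-ganglia output ``g_bg``
(labile, exploratory).  A striatal critic values the current hand position
by its distance to the target, the dopamine signal is the temporal
difference error of that value, and the increment of ``g_bg`` follows the
Go/Explore/NoGo regime rule: repeat the previous increment when the TD
error is high (direct pathway, hill-climbing), reverse it when the TD error
is strongly negative, and take a random fixed-norm step in between (indirect
pathway, exploration).  Successful reaches supply the teaching signal for
the motor cortex via the delta rule, so control transfers from the basal
ganglia to the cortex over training.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class ArmParams:
    """Two-link planar arm with agonist/antagonist muscle pairs per joint.

    Joint angles are a logistic squashing of the activation difference of
    the joint's muscle pair, affinely mapped into the joint range; the map
    from activations to configuration is static (no dynamics).
    """

    L1: float = 1.0
    L2: float = 1.0
    theta1_range: tuple[float, float] = (-np.pi / 2, np.pi / 2)
    theta2_range: tuple[float, float] = (0.0, np.pi)
    slope: float = 4.0

    def __post_init__(self) -> None:
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("link lengths must be > 0")
        for rng in (self.theta1_range, self.theta2_range):
            if rng[1] <= rng[0]:
                raise ValueError(f"empty joint range {rng}")


@dataclass
class MCWeights:
    """Motor-cortex perceptron: g_m = sigmoid(W @ xi) for a one-hot TSV xi."""

    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (4, 4) or not np.isfinite(self.W).all():
            raise ValueError("W must be a finite 4x4 matrix")

    @classmethod
    def random(cls, rng: np.random.Generator, scale: float = 0.1) -> "MCWeights":
        return cls(scale * rng.standard_normal((4, 4)))

    def output(self, xi: np.ndarray) -> np.ndarray:
        return _sigmoid(self.W @ xi)


@dataclass
class BGState:
    """Basal-ganglia output and its last two increments."""

    g_bg: np.ndarray
    dg: np.ndarray
    dg_prev: np.ndarray

    @classmethod
    def initial(cls, g0: np.ndarray | None = None) -> "BGState":
        g0 = np.full(4, 0.5) if g0 is None else np.asarray(g0, dtype=float)
        return cls(g_bg=g0.copy(), dg=np.zeros(4), dg_prev=np.zeros(4))


class Regime(enum.Enum):
    GO = "Go"
    NOGO = "NoGo"
    EXPLORE = "Explore"


@dataclass(frozen=True)
class RLConfig:
    """Parameters of the reaching model.

    alpha, beta : mixing coefficients of cortex and basal ganglia.
    gamma : discount of the TD error (fixed at 1 in this model).
    A, R_small : reward magnitude and reward radius (r = A when d < R_small).
    R_tol : reach-termination radius on the end-effector distance.
    D_hi, D_lo : dopamine thresholds; delta > D_hi -> Go, delta < D_lo ->
        NoGo, otherwise Explore.
    eta : Euclidean norm of the random Explore increment.
    kappa : momentum coefficient on the previous increment, in (0, 1).
    eta_m : motor-cortex delta-rule learning rate.
    sigma_V : length-scale of the critic's value function.
    max_steps : per-episode step budget (budget exhaustion is a normal
        unsuccessful outcome).
    targets : the four reachable target positions; defaults derived from the
        default arm geometry.
    """

    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 1.0
    A: float = 1.0
    R_small: float = 0.15
    R_tol: float = 0.1
    D_hi: float = 0.005
    D_lo: float = -0.005
    eta: float = 0.08
    kappa: float = 0.3
    eta_m: float = 1.0
    sigma_V: float = 1.0
    max_steps: int = 2000
    targets: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.D_lo < self.D_hi:
            raise ValueError("need D_lo < D_hi")
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("need 0 <= kappa < 1")
        if self.sigma_V <= 0 or self.eta < 0 or self.max_steps < 1:
            raise ValueError("invalid sigma_V, eta or max_steps")


def forward_kinematics(g, arm: ArmParams):
    """Joint angles and end-effector position for muscle activations ``g``.

    theta1 is driven by g1 - g2 (shoulder pair), theta2 by g3 - g4 (forearm
    pair); each is a strictly increasing logistic map into its joint range.
    """
    g = np.asarray(g, dtype=float)
    lo1, hi1 = arm.theta1_range
    lo2, hi2 = arm.theta2_range
    th1 = lo1 + (hi1 - lo1) * _sigmoid(arm.slope * (g[0] - g[1]))
    th2 = lo2 + (hi2 - lo2) * _sigmoid(arm.slope * (g[2] - g[3]))
    x = arm.L1 * np.cos(th1) + arm.L2 * np.cos(th1 + th2)
    y = arm.L1 * np.sin(th1) + arm.L2 * np.sin(th1 + th2)
    return float(th1), float(th2), np.array([x, y])


_CANONICAL_G = (
    (0.65, 0.35, 0.35, 0.65),
    (0.35, 0.65, 0.65, 0.35),
    (0.65, 0.35, 0.65, 0.35),
    (0.35, 0.65, 0.35, 0.65),
)


def default_targets(arm: ArmParams) -> tuple[tuple[float, float], ...]:
    """Four target positions, reachable by construction (endpoints of
    canonical activation patterns of the given arm)."""
    return tuple(tuple(forward_kinematics(g, arm)[2]) for g in _CANONICAL_G)


def tsv(target_id: int) -> np.ndarray:
    """One-hot target-selection vector for target_id in {1..4}."""
    if target_id not in (1, 2, 3, 4):
        raise ValueError(f"target_id must be in 1..4, got {target_id}")
    xi = np.zeros(4)
    xi[target_id - 1] = 1.0
    return xi


def value(X, X_target, sigma_V: float) -> float:
    """Critic value V = exp(-d^2 / sigma_V^2), d the Euclidean distance."""
    if sigma_V <= 0:
        raise ValueError(f"sigma_V must be > 0, got {sigma_V}")
    d = float(np.linalg.norm(np.asarray(X, float) - np.asarray(X_target, float)))
    return float(np.exp(-(d * d) / (sigma_V * sigma_V)))


def td_error(r: float, V_t: float, V_prev: float, gamma: float = 1.0) -> float:
    """Dopamine signal delta = r + gamma V(t) - V(t-1)."""
    return float(r + gamma * V_t - V_prev)


def classify_regime(delta: float, cfg: RLConfig) -> Regime:
    if delta > cfg.D_hi:
        return Regime.GO
    if delta < cfg.D_lo:
        return Regime.NOGO
    return Regime.EXPLORE


def bg_update(
    delta: float,
    state: BGState,
    cfg: RLConfig,
    rng: np.random.Generator,
) -> tuple[BGState, Regime]:
    """One Go/Explore/NoGo step of the basal-ganglia output.

    The core increment repeats the previous one (Go), negates it (NoGo), or
    is a random 4-vector of Euclidean norm eta (Explore); the momentum term
    kappa * dg(t-1) is then added and g_bg accumulates the new increment.
    The accumulated g_bg is kept inside the admissible activation range
    [0, 1] per muscle: activations are bounded neural drives, and without
    the bound exploration wanders into the saturated (flat-value) region of
    the activation-to-angle map and stalls there.
    """
    regime = classify_regime(delta, cfg)
    if regime is Regime.GO:
        core = state.dg.copy()
    elif regime is Regime.NOGO:
        core = -state.dg
    else:
        phi = rng.standard_normal(4)
        nrm = np.linalg.norm(phi)
        while nrm == 0.0:  # measure-zero, but keep the norm contract exact
            phi = rng.standard_normal(4)
            nrm = np.linalg.norm(phi)
        core = (cfg.eta / nrm) * phi
    dg_new = core + cfg.kappa * state.dg
    g_bg = np.clip(state.g_bg + dg_new, 0.0, 1.0)
    return BGState(g_bg=g_bg, dg=dg_new, dg_prev=state.dg), regime


@dataclass
class EpisodeResult:
    """Trajectory and outcome of one reaching episode."""

    endpoints: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    regime: list[str]
    success: bool
    g_final: np.ndarray
    steps: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": np.arange(self.steps),
                "theta1": self.theta[:, 0],
                "theta2": self.theta[:, 1],
                "x": self.endpoints[:, 0],
                "y": self.endpoints[:, 1],
                "d": self.d,
                "V": self.V,
                "delta": self.delta,
                "regime": self.regime,
            }
        )


def run_episode(
    target_id: int,
    W: MCWeights,
    cfg: RLConfig,
    arm: ArmParams,
    rng: np.random.Generator,
) -> EpisodeResult:
    """Run one reaching episode until d < R_tol or the step budget is hit."""
    xi = tsv(target_id)
    targets = cfg.targets if cfg.targets is not None else default_targets(arm)
    X_target = np.asarray(targets[target_id - 1], dtype=float)
    g_m = W.output(xi)
    state = BGState.initial()
    rows_end, rows_th, rows_d, rows_V, rows_delta, rows_reg = [], [], [], [], [], []

    g = cfg.alpha * g_m + cfg.beta * state.g_bg
    th1, th2, X = forward_kinematics(g, arm)
    d = float(np.linalg.norm(X - X_target))
    V_prev = value(X, X_target, cfg.sigma_V)
    delta = 0.0  # no previous value: the first update explores
    success = d < cfg.R_tol
    step = 0
    while not success and step < cfg.max_steps:
        state, regime = bg_update(delta, state, cfg, rng)
        g = cfg.alpha * g_m + cfg.beta * state.g_bg
        th1, th2, X = forward_kinematics(g, arm)
        d = float(np.linalg.norm(X - X_target))
        r = cfg.A if d < cfg.R_small else 0.0
        V_t = value(X, X_target, cfg.sigma_V)
        delta = td_error(r, V_t, V_prev, cfg.gamma)
        V_prev = V_t
        rows_end.append(X)
        rows_th.append((th1, th2))
        rows_d.append(d)
        rows_V.append(V_t)
        rows_delta.append(delta)
        rows_reg.append(regime.value)
        success = d < cfg.R_tol
        step += 1
    return EpisodeResult(
        endpoints=np.array(rows_end) if rows_end else np.empty((0, 2)),
        theta=np.array(rows_th) if rows_th else np.empty((0, 2)),
        d=np.array(rows_d),
        V=np.array(rows_V),
        delta=np.array(rows_delta),
        regime=rows_reg,
        success=success,
        g_final=g.copy(),
        steps=step,
    )


def train_mc(
    W: MCWeights,
    xi: np.ndarray,
    g_success: np.ndarray,
    eta_m: float,
) -> MCWeights:
    """One delta-rule step toward the successful activation vector.

    The target is clipped into the open output range of the logistic
    perceptron; the gradient passes through the output nonlinearity, so
    repeated application with a fixed target contracts the output error for
    sufficiently small eta_m.
    """
    target = np.clip(np.asarray(g_success, dtype=float), 0.02, 0.98)
    g_m = W.output(xi)
    err = target - g_m
    grad = err * g_m * (1.0 - g_m)
    return MCWeights(W.W + eta_m * np.outer(grad, xi))


@dataclass
class TrainingReport:
    """Pre/post comparison of cortex-dominant reaching performance."""

    pre_success_rate: float
    post_success_rate: float
    successes_per_target: dict[int, int]
    W: MCWeights


def _success_rate(
    W: MCWeights,
    cfg: RLConfig,
    arm: ArmParams,
    seed,
    n_episodes: int,
) -> float:
    wins = 0
    for k in range(n_episodes):
        rng = np.random.default_rng([*np.atleast_1d(seed), k])
        res = run_episode(1 + k % 4, W, cfg, arm, rng)
        wins += res.success
    return wins / n_episodes


def training_run(
    cfg: RLConfig | None = None,
    arm: ArmParams | None = None,
    seed: int = 0,
    episodes_per_target: int = 12,
    delta_steps_per_success: int = 25,
    alpha_train: float = 0.1,
    beta_train: float = 1.0,
    alpha_test: float = 1.0,
    beta_test: float = 0.2,
    eval_episodes: int = 40,
    eval_max_steps: int = 100,
) -> TrainingReport:
    """Train the motor cortex from basal-ganglia-driven successes.

    Training episodes run BG-dominant (alpha_train, beta_train); each
    success supplies the reached activation vector as the delta-rule target.
    Performance is evaluated cortex-dominant (alpha_test, beta_test) before
    and after training on a paired set of seeded episodes.
    """
    cfg = cfg if cfg is not None else RLConfig()
    arm = arm if arm is not None else ArmParams()
    rng = np.random.default_rng([seed, 777])
    W = MCWeights.random(rng)
    # evaluation is cortex-dominant on a short budget: a trained cortex
    # reaches almost immediately, the basal ganglia alone usually cannot
    test_cfg = replace(cfg, alpha=alpha_test, beta=beta_test, max_steps=eval_max_steps)
    pre = _success_rate(W, test_cfg, arm, [seed, 1], eval_episodes)
    train_cfg = replace(cfg, alpha=alpha_train, beta=beta_train)
    per_target: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}
    for tid in (1, 2, 3, 4):
        xi = tsv(tid)
        for ep in range(episodes_per_target):
            ep_rng = np.random.default_rng([seed, 2, tid, ep])
            res = run_episode(tid, W, train_cfg, arm, ep_rng)
            if res.success:
                per_target[tid] += 1
                for _ in range(delta_steps_per_success):
                    W = train_mc(W, xi, res.g_final, cfg.eta_m)
    post = _success_rate(W, test_cfg, arm, [seed, 1], eval_episodes)
    return TrainingReport(pre, post, per_target, W)
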