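"""Binary dragonfly algorithm (BDA) for subset selection.

Each dragonfly carries a binary position vector over the feature universe
(1 = feature selected).  Five behaviours drive a real-valued step vector:

    separation  S_i = -sum_j (X - X_j)
    alignment   V_i = mean_j dX_j
    cohesion    C_i = (1/M) sum_j (X - X_j)          [printed convention]
    attraction  F_i = 1/2 [(X_pb - X) + (X_f - X)]
    distraction E_i = 1/2 [(X_pw + X) + (X_f - X_e)] [printed convention]

where X_f / X_e are the best ("food") and worst ("enemy") positions seen so
far and X_pb / X_pw are the current best ("leader") and worst ("laggard")
swarm members.  The step is dX = a1*S + a2*V + a3*C + a4*F + a5*E and each
bit flips independently with probability TF(dX_d) = |dX_d| / sqrt(dX_d^2+1).

The cohesion and distraction terms are implemented exactly as printed in
the source method; those signs differ from the original dragonfly
algorithm, so the conventional forms (``standard``: mean(X_j) - X and
X_e + X) are selectable by configuration.  Likewise the personal/group
learning rates (defaults 0.4 / 0.7) are applied as multipliers on the two
attraction components, the most direct reading of the reference settings;
they can be disabled.

The neighbourhood is the whole swarm (the usual simplification for small
binary swarms).  Ties between equal-objective masks prefer fewer selected
features, then the lexicographically smallest mask, so reports are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_io import RunConfig

__all__ = [
    "separation", "alignment", "cohesion", "attraction", "distraction",
    "transfer_function", "SwarmState", "init_swarm", "step_swarm",
    "optimize", "OptimizeResult",
]


def _as2d(vectors: Sequence[np.ndarray], width: int) -> np.ndarray:
    arr = np.asarray(vectors, dtype=float)
    if arr.size and arr.shape[-1] != width:
        raise ValueError("vector length mismatch")
    return arr.reshape(-1, width)


def separation(x: np.ndarray, neighbors: Sequence[np.ndarray]) -> np.ndarray:
    """-sum_j (X - X_j); zero vector when there are no neighbours."""
    x = np.asarray(x, dtype=float)
    if len(neighbors) == 0:
        return np.zeros_like(x)
    nb = _as2d(neighbors, x.size)
    return -(x[None, :] - nb).sum(axis=0)


def alignment(neighbor_steps: Sequence[np.ndarray]) -> np.ndarray:
    """Mean neighbour step; empty neighbourhood gives the zero vector."""
    if len(neighbor_steps) == 0:
        return np.zeros(0)
    nb = np.asarray(neighbor_steps, dtype=float)
    if nb.ndim != 2:
        raise ValueError("vector length mismatch")
    return nb.mean(axis=0)


def cohesion(x: np.ndarray, neighbors: Sequence[np.ndarray],
             convention: str = "printed") -> np.ndarray:
    """Cohesion term.

    ``printed``: (1/M) sum_j (X - X_j) as in the source description;
    ``standard``: mean_j(X_j) - X, the sign that points at the group centre.
    """
    x = np.asarray(x, dtype=float)
    if len(neighbors) == 0:
        return np.zeros_like(x)
    nb = _as2d(neighbors, x.size)
    centered = x[None, :] - nb
    if convention == "printed":
        return centered.mean(axis=0)
    if convention == "standard":
        return -centered.mean(axis=0)
    raise ValueError("unknown cohesion convention")


def attraction(x: np.ndarray, x_pb: np.ndarray, x_f: np.ndarray,
               personal_rate: float = 1.0,
               group_rate: float = 1.0) -> np.ndarray:
    """1/2 [pr*(X_pb - X) + gr*(X_f - X)] toward leader and food."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (personal_rate * (np.asarray(x_pb, dtype=float) - x)
                  + group_rate * (np.asarray(x_f, dtype=float) - x))


def distraction(x: np.ndarray, x_pw: np.ndarray, x_f: np.ndarray,
                x_e: np.ndarray, convention: str = "printed") -> np.ndarray:
    """Enemy-avoidance term.

    ``printed``: 1/2 [(X_pw + X) + (X_f - X_e)] as in the source
    description; ``standard``: X_e + X (the original algorithm's enemy
    term).
    """
    x = np.asarray(x, dtype=float)
    if convention == "printed":
        return 0.5 * ((np.asarray(x_pw, dtype=float) + x)
                      + (np.asarray(x_f, dtype=float)
                         - np.asarray(x_e, dtype=float)))
    if convention == "standard":
        return np.asarray(x_e, dtype=float) + x
    raise ValueError("unknown distraction convention")


def transfer_function(dx):
    """TF(dX) = |dX| / sqrt(dX^2 + 1): bit-flip probability in [0, 1)."""
    dx = np.asarray(dx, dtype=float)
    return np.abs(dx) / np.sqrt(dx * dx + 1.0)


def _mask_key(mask: np.ndarray) -> tuple:
    # better-than ordering for tie-breaks: fewer bits, then lexicographic
    return (int(mask.sum()), tuple(int(b) for b in mask))


def _improves(value: float, mask: np.ndarray,
              best_value: float, best_mask: np.ndarray) -> bool:
    if value < best_value:
        return True
    if value == best_value and _mask_key(mask) < _mask_key(best_mask):
        return True
    return False


@dataclass
class SwarmState:
    """Positions, steps and bookkeeping for one swarm."""

    positions: np.ndarray          # (k, p) int8 in {0, 1}
    steps: np.ndarray              # (k, p) float
    objectives: np.ndarray         # (k,) float
    food: np.ndarray               # best-ever position
    food_value: float
    enemy: np.ndarray              # worst-ever position
    enemy_value: float
    rng: np.random.Generator
    config: RunConfig
    n_iter: int = 0
    trace: list[float] = field(default_factory=list)

    @property
    def leader(self) -> np.ndarray:
        """Current member nearest the food, measured in objective value."""
        return self.positions[int(np.argmin(self.objectives))]

    @property
    def laggard(self) -> np.ndarray:
        """Current member nearest the enemy (worst current objective)."""
        return self.positions[int(np.argmax(self.objectives))]


def init_swarm(objective_fn: Callable[[np.ndarray], float], n_features: int,
               config: RunConfig, rng: np.random.Generator) -> SwarmState:
    """Bernoulli(0.5) positions, zero steps, food/enemy from the initial
    evaluations."""
    k = config.swarm_size
    positions = (rng.random((k, n_features)) < 0.5).astype(np.int8)
    steps = np.zeros((k, n_features))
    objectives = np.array([objective_fn(p) for p in positions])

    best = 0
    worst = 0
    for i in range(1, k):
        if _improves(objectives[i], positions[i], objectives[best],
                     positions[best]):
            best = i
        if objectives[i] >= objectives[worst]:
            worst = i
    return SwarmState(
        positions=positions, steps=steps, objectives=objectives,
        food=positions[best].copy(), food_value=float(objectives[best]),
        enemy=positions[worst].copy(), enemy_value=float(objectives[worst]),
        rng=rng, config=config)


def step_swarm(swarm: SwarmState,
               objective_fn: Callable[[np.ndarray], float]) -> SwarmState:
    """One synchronous iteration: recompute every step vector from the
    current swarm, flip bits by transfer-function probability, re-evaluate,
    and refresh food/enemy/leader/laggard."""
    cfg = swarm.config
    a1, a2, a3, a4, a5 = cfg.behavior_weights
    pr = cfg.personal_rate if cfg.use_learning_rates else 1.0
    gr = cfg.group_rate if cfg.use_learning_rates else 1.0

    pos = swarm.positions.astype(float)
    x_pb = swarm.leader.astype(float)
    x_pw = swarm.laggard.astype(float)
    food = swarm.food.astype(float)
    enemy = swarm.enemy.astype(float)
    k = pos.shape[0]

    # Vectorized equivalents (neighbourhood = all other members) of the
    # per-member behaviour functions above; tests pin their agreement.
    pos_total = pos.sum(axis=0)
    step_total = swarm.steps.sum(axis=0)
    if k > 1:
        s = pos_total[None, :] - k * pos                  # separation
        v = (step_total[None, :] - swarm.steps) / (k - 1)  # alignment
        c = pos - (pos_total[None, :] - pos) / (k - 1)     # cohesion, printed
        if cfg.cohesion_convention == "standard":
            c = -c
    else:
        s = np.zeros_like(pos)
        v = np.zeros_like(pos)
        c = np.zeros_like(pos)
    f = 0.5 * (pr * (x_pb[None, :] - pos) + gr * (food[None, :] - pos))
    if cfg.distraction_convention == "printed":
        e = 0.5 * ((x_pw[None, :] + pos) + (food - enemy)[None, :])
    else:
        e = enemy[None, :] + pos
    new_steps = a1 * s + a2 * v + a3 * c + a4 * f + a5 * e

    flip = swarm.rng.random(pos.shape) < transfer_function(new_steps)
    new_positions = np.where(flip, 1 - swarm.positions, swarm.positions)
    new_positions = new_positions.astype(np.int8)

    objectives = np.array([objective_fn(p) for p in new_positions])
    swarm.positions = new_positions
    swarm.steps = new_steps
    swarm.objectives = objectives
    for i in range(k):
        if _improves(objectives[i], new_positions[i], swarm.food_value,
                     swarm.food):
            swarm.food = new_positions[i].copy()
            swarm.food_value = float(objectives[i])
        if objectives[i] > swarm.enemy_value:
            swarm.enemy = new_positions[i].copy()
            swarm.enemy_value = float(objectives[i])
    swarm.n_iter += 1
    return swarm


@dataclass
class OptimizeResult:
    best_mask: np.ndarray
    best_value: float
    trace: list[float]
    n_iter: int


def optimize(objective_fn: Callable[[np.ndarray], float], n_features: int,
             config: RunConfig,
             rng: np.random.Generator | None = None) -> OptimizeResult:
    """Run the swarm for up to ``config.max_iter`` iterations.

    Stops early once the best (food) objective is <= the early-stop
    threshold EE.  The returned trace holds the food objective after each
    iteration and is nonincreasing by construction.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    swarm = init_swarm(objective_fn, n_features, config, rng)
    for _ in range(config.max_iter):
        step_swarm(swarm, objective_fn)
        swarm.trace.append(swarm.food_value)
        if swarm.food_value <= config.objective_threshold:
            break
    return OptimizeResult(best_mask=swarm.food.copy(),
                          best_value=swarm.food_value,
                          trace=list(swarm.trace), n_iter=swarm.n_iter)
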