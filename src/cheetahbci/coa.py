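"""Cheetah optimization algorithm (COA).

A population metaheuristic over a bounded real search space, generic over
any objective callback (minimization convention).  Each candidate solution
("cheetah") applies one of four hunting strategies per iteration:

* **search** — a small bound-scaled random walk, X += r_hat * a, where r_hat
  is a per-component standard-normal draw and the step length
  a = 0.001 * (upper - lower) * (1 - t/T) anneals linearly over the run;
* **wait** — the position is left untouched (and its fitness is not
  re-evaluated);
* **attack** — a rush toward the best-so-far position ("prey"):
  X_new = X_best + r_breve * beta, with turning factor
  r_breve = |u|^(exp(u/2)) * sin(2*pi*u), u ~ N(0,1), and interaction factor
  beta = X_k - X_i for a uniformly chosen other cheetah k;
* **leave and return home** — after ``home_return_patience`` iterations
  without improvement the worst half of the population is re-randomized
  within the bounds, keeping the best-so-far (elitism).

Strategies are drawn independently per component: each coordinate of each
cheetah chooses search / wait / attack with the configured probabilities,
so one update typically mixes prey coordinates with the cheetah's own —
this coordinate-wise mixing is what lets the algorithm make progress in
high-dimensional spaces such as neural-network weight vectors.  A candidate
replaces the cheetah's position only when it improves that cheetah's own
fitness (greedy acceptance); the best-so-far is elitist on top of that.

All updates are clipped to the box bounds; objectives that return
non-finite values see that candidate assigned +inf and the run continues.
The reported best fitness is monotone non-increasing, and a fixed
(config, seed) pair reproduces the trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEARCH, WAIT, ATTACK = 0, 1, 2


@dataclass
class COAConfig:
    n: int = 30
    D: int = 2
    lower: np.ndarray | float = -5.0
    upper: np.ndarray | float = 5.0
    T: int = 500
    p_search: float = 0.3
    p_wait: float = 0.3
    p_attack: float = 0.4
    home_return_patience: int = 20
    step_scale: float = 0.05
    f_tol: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size n must be >= 2")
        if self.D < 1:
            raise ValueError("dimension D must be >= 1")
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.D,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.D,)).copy()
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ValueError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        probs = (self.p_search, self.p_wait, self.p_attack)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("strategy probabilities must be nonnegative and sum to 1")


@dataclass
class CheetahState:
    """Population positions, fitnesses, best-so-far and bookkeeping."""

    positions: np.ndarray  # (n x D)
    fitness: np.ndarray  # (n,)
    best_position: np.ndarray
    best_fitness: float
    t: int = 0
    stagnation: int = 0
    history: list[float] = field(default_factory=list)


def _eval(objective, x: np.ndarray) -> float:
    v = objective(x)
    v = float(v)
    return v if np.isfinite(v) else np.inf


def step_length(cfg: COAConfig, t: int) -> np.ndarray:
    """Annealed, bound-scaled step length a_t for the search strategy."""
    return cfg.step_scale * (cfg.upper - cfg.lower) * (1.0 - t / cfg.T)


def search_step(x: np.ndarray, cfg: COAConfig, t: int, rng: np.random.Generator) -> np.ndarray:
    """Random-walk scan of the neighbourhood, clipped to bounds."""
    r_hat = rng.standard_normal(x.shape)
    return np.clip(x + r_hat * step_length(cfg, t), cfg.lower, cfg.upper)


def wait_step(x: np.ndarray) -> np.ndarray:
    """Sit-and-wait: the position is returned unchanged."""
    return x


def turning_factor(rng: np.random.Generator, size) -> np.ndarray:
    """r_breve = |u|^(exp(u/2)) * sin(2*pi*u) with u ~ N(0,1), per component."""
    u = rng.standard_normal(size)
    return np.abs(u) ** np.exp(u / 2.0) * np.sin(2.0 * np.pi * u)


def attack_step(
    x: np.ndarray,
    best: np.ndarray,
    neighbour: np.ndarray,
    cfg: COAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rush toward the prey with a neighbour-coupled interaction term."""
    beta = neighbour - x
    r_breve = turning_factor(rng, x.shape)
    return np.clip(best + r_breve * beta, cfg.lower, cfg.upper)


def leave_and_return(state: CheetahState, cfg: COAConfig, objective, rng: np.random.Generator) -> None:
    """Re-randomize the worst half of the population; keep the best-so-far."""
    n_reset = cfg.n // 2
    order = np.argsort(state.fitness)  # ascending: best first
    worst = order[cfg.n - n_reset :]
    fresh = rng.uniform(cfg.lower, cfg.upper, size=(n_reset, cfg.D))
    state.positions[worst] = fresh
    for i in worst:
        state.fitness[i] = _eval(objective, state.positions[i])
    state.stagnation = 0
    # elitism: best_position / best_fitness deliberately untouched
    i_best = int(np.argmin(state.fitness))
    if state.fitness[i_best] < state.best_fitness:
        state.best_fitness = float(state.fitness[i_best])
        state.best_position = state.positions[i_best].copy()


def init_state(objective, cfg: COAConfig, rng: np.random.Generator) -> CheetahState:
    positions = rng.uniform(cfg.lower, cfg.upper, size=(cfg.n, cfg.D))
    fitness = np.array([_eval(objective, p) for p in positions])
    i_best = int(np.argmin(fitness))
    return CheetahState(
        positions=positions,
        fitness=fitness,
        best_position=positions[i_best].copy(),
        best_fitness=float(fitness[i_best]),
    )


def optimize(
    objective,
    cfg: COAConfig,
    rng: np.random.Generator | int | None = None,
    callback=None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the full hunting loop.

    Parameters
    ----------
    objective : callable mapping a length-D vector to a scalar (minimized).
    cfg : COAConfig.
    rng : Generator, int seed, or None (falls back to cfg.seed).

    Returns
    -------
    (best_position, best_fitness, history) where history[t] is the best
    fitness after iteration t (monotone non-increasing).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    state = init_state(objective, cfg, rng)
    probs = np.array([cfg.p_search, cfg.p_wait, cfg.p_attack])

    for t in range(cfg.T):
        state.t = t
        improved = False
        for i in range(cfg.n):
            strategies = rng.choice(3, size=cfg.D, p=probs)
            searching = strategies == SEARCH
            attacking = strategies == ATTACK
            if not (searching.any() or attacking.any()):
                continue  # full sit-and-wait: position and cached fitness untouched
            candidate = state.positions[i].copy()
            if searching.any():
                a = step_length(cfg, t)[searching]
                candidate[searching] += rng.standard_normal(int(searching.sum())) * a
            if attacking.any():
                k = int(rng.integers(cfg.n - 1))
                if k >= i:
                    k += 1
                r_breve = turning_factor(rng, int(attacking.sum()))
                beta = state.positions[k][attacking] - state.positions[i][attacking]
                candidate[attacking] = state.best_position[attacking] + r_breve * beta
            np.clip(candidate, cfg.lower, cfg.upper, out=candidate)
            f = _eval(objective, candidate)
            if f < state.fitness[i]:  # greedy acceptance per cheetah
                state.positions[i] = candidate
                state.fitness[i] = f
            if f < state.best_fitness:
                state.best_fitness = f
                state.best_position = candidate.copy()
                improved = True

        state.stagnation = 0 if improved else state.stagnation + 1
        if state.stagnation >= cfg.home_return_patience:
            leave_and_return(state, cfg, objective, rng)
        state.history.append(state.best_fitness)
        if callback is not None:
            callback(state)
        if cfg.f_tol is not None and state.best_fitness <= cfg.f_tol:
            break

    return state.best_position.copy(), state.best_fitness, np.asarray(state.history)
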