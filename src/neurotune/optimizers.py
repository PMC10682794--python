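"""Sine-cosine search, firefly search, and their hybrid (HASCA).

The hybrid adaptive sine-cosine algorithm couples two ideas:

* **Chaotic initialization** — half the initial population is drawn
  uniformly, the other half is produced by scaling those solutions with
  successive iterates of the logistic map ``beta <- mu*beta*(1-beta)``
  (chaotic at mu=4), which spreads the initial guesses without spending
  extra fitness evaluations.
* **Self-adaptive search alternation** — every component update flips a
  coin against a *search mode* probability ``sm``: with probability ``sm``
  the component takes a firefly step toward an attractor, otherwise a
  sine-cosine step around the destination point P*.  ``sm`` starts at 0.8
  and drains to zero over the run, so exploration-heavy firefly moves
  dominate early and the exploitative sine-cosine moves dominate late.

Plain SCA and FA runners are provided as baselines under the exact same
bookkeeping (same FFE accounting, elitist best tracking, history export),
so comparative campaigns measure search behavior and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .space import (
    Population,
    RunResult,
    SearchSpace,
    Solution,
    clip_to_bounds,
    conventional_init,
    evaluate,
    mean_pairwise_distance,
)

__all__ = [
    "SCAControls",
    "FAParams",
    "HASCAConfig",
    "RunState",
    "ChaoticSequence",
    "logistic_map_step",
    "chaotic_init",
    "r1_schedule",
    "sm_schedule",
    "draw_sca_controls",
    "sca_update_component",
    "fa_update_component",
    "hasca_optimize",
    "sca_optimize",
    "fa_optimize",
    "OPTIMIZERS",
]


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class SCAControls:
    """One draw of the sine-cosine control parameters.

    r1 is the scheduled movement amplitude, r2 the phase in [0, 2pi],
    r3 the destination weight in [0, 2], r4 the sine/cosine branch
    selector in [0, 1].
    """

    r1: float
    r2: float
    r3: float
    r4: float


@dataclass(frozen=True)
class FAParams:
    """Firefly-move constants.

    attract0 is the base attractiveness (the beta0 of the firefly move,
    distinct from the chaotic seed), gamma the light-absorption
    coefficient, alpha0 the initial randomization weight.  The noise draw
    kappa is standard normal, taken fresh per component.
    """

    attract0: float = 1.0
    gamma: float = 1.0
    alpha0: float = 0.5

    def __post_init__(self) -> None:
        if self.attract0 <= 0 or self.gamma <= 0 or self.alpha0 < 0:
            raise ValueError("attract0, gamma must be > 0 and alpha0 >= 0")


@dataclass(frozen=True)
class HASCAConfig:
    """Full configuration of a HASCA (or baseline) run.

    Defaults follow the hyperparameter-tuning budget used throughout:
    six agents, eight iterations, sm0 = 0.8, logistic-map mu = 4.
    """

    N: int = 6
    T: int = 8
    a: float = 2.0
    sm0: float = 0.8
    mu: float = 4.0
    fa: FAParams = field(default_factory=FAParams)
    #: "printed" = cumulative drain sm <- sm - t/T (clamped at 0);
    #: "linear" = sm0 * (1 - t/T).
    sm_mode: str = "printed"
    #: firefly partner inside HASCA: "best" (destination point P*) or
    #: "random_brighter".
    partner: str = "best"

    def __post_init__(self) -> None:
        if self.N % 2 != 0 or self.N < 2:
            raise ValueError("population size N must be even and >= 2")
        if self.T < 0:
            raise ValueError("iteration count T must be >= 0")
        if not (0.0 < self.sm0 <= 1.0):
            raise ValueError("sm0 must lie in (0, 1]")
        if self.sm_mode not in ("printed", "linear"):
            raise ValueError("sm_mode must be 'printed' or 'linear'")
        if self.partner not in ("best", "random_brighter"):
            raise ValueError("partner must be 'best' or 'random_brighter'")

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "T": self.T,
            "a": self.a,
            "sm0": self.sm0,
            "mu": self.mu,
            "fa": {
                "attract0": self.fa.attract0,
                "gamma": self.fa.gamma,
                "alpha0": self.fa.alpha0,
            },
            "sm_mode": self.sm_mode,
            "partner": self.partner,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HASCAConfig":
        d = dict(d)
        fa = d.pop("fa", {})
        return cls(fa=FAParams(**fa), **d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "HASCAConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunState:
    """Mutable per-run state: iteration counter, search mode, best P*."""

    t: int
    sm: float
    best: Solution


# ---------------------------------------------------------------------------
# chaotic initialization


def logistic_map_step(beta: float, mu: float = 4.0) -> float:
    """One iterate of the logistic map, beta' = mu * beta * (1 - beta)."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return mu * beta * (1.0 - beta)


#: seeds for which the mu=4 logistic map is periodic or collapses.
_EXCLUDED_SEEDS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ChaoticSequence:
    """Logistic-map iterate stream from a rejected-sampled seed beta0."""

    beta0: float
    mu: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.beta0 < 1.0) or self.beta0 in _EXCLUDED_SEEDS:
            raise ValueError(
                "beta0 must lie in (0,1) excluding {0.25, 0.5, 0.75}"
            )

    @classmethod
    def draw(cls, rng: np.random.Generator, mu: float = 4.0) -> "ChaoticSequence":
        while True:
            b = float(rng.random())
            if 0.0 < b < 1.0 and b not in _EXCLUDED_SEEDS:
                return cls(beta0=b, mu=mu)

    def generate(self, n: int) -> np.ndarray:
        """The first ``n`` iterates after the seed (beta_1 .. beta_n)."""
        out = np.empty(n)
        b = self.beta0
        for i in range(n):
            b = logistic_map_step(b, self.mu)
            out[i] = b
        return out


def chaotic_init(
    space: SearchSpace,
    cfg: HASCAConfig,
    objective,
    rng: np.random.Generator,
) -> tuple[Population, RunState]:
    """Chaos-augmented initialization.

    N/2 uniform solutions are drawn; each is scaled component-wise by its
    logistic-map iterate to form a chaotic companion; the merged N
    solutions are evaluated (exactly N FFEs) and stably sorted ascending
    by fitness.  The destination point P* is the front of the sorted
    population.
    """
    half = cfg.N // 2
    pop = conventional_init(space, half, rng)
    chaos = ChaoticSequence.draw(rng, mu=cfg.mu).generate(half)
    for beta_i, sol in zip(chaos, list(pop.members)):
        companion = clip_to_bounds(beta_i * sol.position, space)
        pop.members.append(Solution(companion))
    evaluate(pop, objective)
    pop.sort_by_fitness()
    state = RunState(t=0, sm=cfg.sm0, best=pop.members[0].copy())
    return pop, state


# ---------------------------------------------------------------------------
# schedules and component moves


def r1_schedule(t: int, T: int, a: float = 2.0) -> float:
    """Movement-amplitude schedule r1 = a * (1 - t/T), from a down to 0."""
    if T == 0:
        raise ValueError("T must be >= 1 for the r1 schedule")
    if not (0 <= t <= T):
        raise ValueError("t must lie in [0, T]")
    return a * (1.0 - t / T)


def sm_schedule(sm_prev: float, t: int, T: int) -> float:
    """Search-mode drain sm_t = max(0, sm_{t-1} - t/T).

    As printed the recurrence subtracts a growing amount each round and
    goes negative within a handful of iterations; the clamp keeps sm a
    probability while preserving the intended firefly-early /
    sine-cosine-late behavior.
    """
    if T == 0:
        raise ValueError("T must be >= 1 for the sm schedule")
    if not (0 <= t <= T):
        raise ValueError("t must lie in [0, T]")
    if sm_prev < 0:
        raise ValueError("sm_prev must be >= 0")
    return max(0.0, sm_prev - t / T)


def draw_sca_controls(
    state: RunState, cfg: HASCAConfig, rng: np.random.Generator
) -> SCAControls:
    """Fresh sine-cosine controls for one component update."""
    return SCAControls(
        r1=r1_schedule(state.t, cfg.T, cfg.a),
        r2=float(rng.uniform(0.0, 2.0 * math.pi)),
        r3=float(rng.uniform(0.0, 2.0)),
        r4=float(rng.random()),
    )


def sca_update_component(x: float, p_star: float, c: SCAControls) -> float:
    """One sine-cosine component move (not yet bound-repaired)."""
    step = abs(c.r3 * p_star - x)
    if c.r4 < 0.5:
        return x + c.r1 * math.sin(c.r2) * step
    return x + c.r1 * math.cos(c.r2) * step


def fa_update_component(
    xi: float,
    xj: float,
    distance: float,
    t: int,
    cfg: HASCAConfig,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> float:
    """One firefly component move toward the partner xj.

    attraction decays as exp(-gamma * distance^2); the randomization
    weight alpha decays linearly to 0 over the run and the noise is
    scaled by ``scale`` (the dimension's bound span) so it is meaningful
    across heterogeneous hyperparameter ranges.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    fa = cfg.fa
    alpha_t = fa.alpha0 * (1.0 - t / cfg.T) if cfg.T > 0 else 0.0
    kappa = float(rng.standard_normal())
    attract = fa.attract0 * math.exp(-fa.gamma * distance**2)
    return xi + attract * (xj - xi) + alpha_t * (kappa - 0.5) * scale


# ---------------------------------------------------------------------------
# main loops


def _normalized_distance(x: np.ndarray, y: np.ndarray, space: SearchSpace) -> float:
    """Euclidean distance after mapping each dimension to [0, 1]."""
    span = np.where(space.span > 0, space.span, 1.0)
    return float(np.linalg.norm((x - y) / span))


def _alpha(cfg: HASCAConfig, t: int) -> float:
    return cfg.fa.alpha0 * (1.0 - t / cfg.T) if cfg.T > 0 else 0.0


class MoveCounter:
    """Instrumentation: counts FA vs SCA component moves."""

    def __init__(self) -> None:
        self.fa_moves = 0
        self.sca_moves = 0


def _hasca_move_solution(
    sol: Solution,
    partner_pos: np.ndarray,
    best_pos: np.ndarray,
    state: RunState,
    cfg: HASCAConfig,
    space: SearchSpace,
    rng: np.random.Generator,
    counter: MoveCounter | None,
) -> np.ndarray:
    """Per-component stochastic switch between FA and SCA moves.

    All per-component random draws (branch coin, r2/r3/r4, kappa) are
    taken as vectors in component order, which is equivalent to fresh
    per-component draws and an order of magnitude cheaper.
    """
    d = space.dim
    x = sol.position
    u = rng.random(d)
    r2 = rng.uniform(0.0, 2.0 * math.pi, d)
    r3 = rng.uniform(0.0, 2.0, d)
    r4 = rng.random(d)
    kappa = rng.standard_normal(d)

    r1 = r1_schedule(state.t, cfg.T, cfg.a)
    trig = np.where(r4 < 0.5, np.sin(r2), np.cos(r2))
    sca_new = x + r1 * trig * np.abs(r3 * best_pos - x)

    dist = _normalized_distance(x, partner_pos, space)
    attract = cfg.fa.attract0 * math.exp(-cfg.fa.gamma * dist**2)
    fa_new = x + attract * (partner_pos - x) + _alpha(cfg, state.t) * (
        kappa - 0.5
    ) * space.span

    fa_mask = u < state.sm
    if counter is not None:
        counter.fa_moves += int(fa_mask.sum())
        counter.sca_moves += int(d - fa_mask.sum())
    return clip_to_bounds(np.where(fa_mask, fa_new, sca_new), space)


def _refresh_sm(state: RunState, cfg: HASCAConfig) -> None:
    if cfg.sm_mode == "printed":
        state.sm = sm_schedule(state.sm, state.t, cfg.T)
    else:
        state.sm = cfg.sm0 * (1.0 - state.t / cfg.T)


def hasca_optimize(
    space: SearchSpace,
    objective,
    cfg: HASCAConfig,
    rng: np.random.Generator,
    seed: int | None = None,
    counter: MoveCounter | None = None,
) -> RunResult:
    """Run the hybrid adaptive sine-cosine algorithm.

    Chaotic initialization, then T iterations of per-component
    FA-or-SCA moves (sm-gated), box repair, evaluation, and elitist
    refresh of the destination point P*.
    """
    pop, state = chaotic_init(space, cfg, objective, rng)
    history = [state.best.fitness]
    diversity = [mean_pairwise_distance(pop)]

    for t in range(1, cfg.T + 1):
        state.t = t
        snapshot = [s.fitness for s in pop.members]
        best_pos = state.best.position
        for i, sol in enumerate(pop.members):
            if cfg.partner == "best":
                partner_pos = best_pos
            else:
                brighter = [
                    j for j, f in enumerate(snapshot) if f < snapshot[i]
                ]
                partner_pos = (
                    pop.members[int(rng.choice(brighter))].position
                    if brighter
                    else sol.position
                )
            sol.position = _hasca_move_solution(
                sol, partner_pos, best_pos, state, cfg, space, rng, counter
            )
            sol.fitness = None
        evaluate(pop, objective)
        cand = pop.best()
        if cand.fitness < state.best.fitness:
            state.best = cand.copy()
        history.append(state.best.fitness)
        diversity.append(mean_pairwise_distance(pop))
        _refresh_sm(state, cfg)

    return RunResult(
        best_position=state.best.position.copy(),
        best_fitness=state.best.fitness,
        history=history,
        diversity=diversity,
        ffe_count=pop.ffe_count,
        seed=seed,
    )


def sca_optimize(
    space: SearchSpace,
    objective,
    cfg: HASCAConfig,
    rng: np.random.Generator,
    seed: int | None = None,
) -> RunResult:
    """Plain sine-cosine baseline: uniform init, pure SCA moves."""
    pop = conventional_init(space, cfg.N, rng)
    evaluate(pop, objective)
    best = pop.best().copy()
    history = [best.fitness]
    diversity = [mean_pairwise_distance(pop)]

    for t in range(1, cfg.T + 1):
        r1 = r1_schedule(t, cfg.T, cfg.a)
        best_pos = best.position
        for sol in pop.members:
            d = space.dim
            x = sol.position
            r2 = rng.uniform(0.0, 2.0 * math.pi, d)
            r3 = rng.uniform(0.0, 2.0, d)
            r4 = rng.random(d)
            trig = np.where(r4 < 0.5, np.sin(r2), np.cos(r2))
            sol.position = clip_to_bounds(
                x + r1 * trig * np.abs(r3 * best_pos - x), space
            )
            sol.fitness = None
        evaluate(pop, objective)
        cand = pop.best()
        if cand.fitness < best.fitness:
            best = cand.copy()
        history.append(best.fitness)
        diversity.append(mean_pairwise_distance(pop))

    return RunResult(
        best_position=best.position.copy(),
        best_fitness=best.fitness,
        history=history,
        diversity=diversity,
        ffe_count=pop.ffe_count,
        seed=seed,
    )


def fa_optimize(
    space: SearchSpace,
    objective,
    cfg: HASCAConfig,
    rng: np.random.Generator,
    seed: int | None = None,
) -> RunResult:
    """Firefly baseline with linearly decaying randomization.

    Each solution moves toward every brighter solution (full-vector
    move); brightness is the fitness snapshot at the start of the
    iteration; the iteration-best moves only by the noise term.
    """
    pop = conventional_init(space, cfg.N, rng)
    evaluate(pop, objective)
    best = pop.best().copy()
    history = [best.fitness]
    diversity = [mean_pairwise_distance(pop)]

    for t in range(1, cfg.T + 1):
        snapshot = [(s.fitness, s.position.copy()) for s in pop.members]
        alpha_t = _alpha(cfg, t)
        for i, sol in enumerate(pop.members):
            x = sol.position.copy()
            moved = False
            for fj, pj in snapshot:
                if fj < snapshot[i][0]:
                    dist = _normalized_distance(x, pj, space)
                    attract = cfg.fa.attract0 * math.exp(
                        -cfg.fa.gamma * dist**2
                    )
                    kappa = rng.standard_normal(space.dim)
                    x = x + attract * (pj - x) + alpha_t * (
                        kappa - 0.5
                    ) * space.span
                    moved = True
            if not moved:
                kappa = rng.standard_normal(space.dim)
                x = x + alpha_t * (kappa - 0.5) * space.span
            sol.position = clip_to_bounds(x, space)
            sol.fitness = None
        evaluate(pop, objective)
        cand = pop.best()
        if cand.fitness < best.fitness:
            best = cand.copy()
        history.append(best.fitness)
        diversity.append(mean_pairwise_distance(pop))

    return RunResult(
        best_position=best.position.copy(),
        best_fitness=best.fitness,
        history=history,
        diversity=diversity,
        ffe_count=pop.ffe_count,
        seed=seed,
    )


#: registry used by campaigns and the CLI; user optimizers may be added.
OPTIMIZERS: dict[str, object] = {
    "hasca": hasca_optimize,
    "sca": sca_optimize,
    "fa": fa_optimize,
}
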