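"""Search-space representation and population bookkeeping.

Everything here is shared by all optimizers: box bounds with integer
tagging, solutions, fitness-function-evaluation (FFE) accounting, and the
seedable randomness contract that makes multi-run campaigns reproducible
run by run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "Solution",
    "Population",
    "RunResult",
    "clip_to_bounds",
    "conventional_init",
    "evaluate",
    "spawn_rng",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained search space.

    Parameters
    ----------
    lower, upper
        Per-dimension bounds (LB / UB).
    integer_dims
        Indices of dimensions that decode to integers downstream.  The
        search itself stays continuous; discreteness is the decoder's job.
    """

    lower: np.ndarray
    upper: np.ndarray
    integer_dims: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "integer_dims", frozenset(self.integer_dims))
        if lo.ndim != 1 or lo.shape != hi.shape:
            raise ValueError("lower and upper must be 1-d vectors of equal length")
        if np.any(lo > hi):
            raise ValueError("every lower bound must be <= its upper bound")
        if any(d < 0 or d >= lo.size for d in self.integer_dims):
            raise ValueError("integer_dims outside 0..dim-1")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class Solution:
    """A candidate position with (optionally) its objective value."""

    position: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Solution":
        return Solution(self.position.copy(), self.fitness)


@dataclass
class Population:
    """Ordered collection of solutions plus the FFE counter."""

    members: list[Solution] = field(default_factory=list)
    ffe_count: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def sort_by_fitness(self) -> None:
        """Stable ascending sort; unset fitness sorts last."""
        self.members.sort(
            key=lambda s: np.inf if s.fitness is None else s.fitness
        )

    def best(self) -> Solution:
        return min(
            self.members,
            key=lambda s: np.inf if s.fitness is None else s.fitness,
        )


@dataclass
class RunResult:
    """Outcome of one optimizer run.

    ``history`` holds the elitist best fitness after initialization and
    after every iteration, so it is non-increasing and has T+1 entries.
    ``diversity`` holds the mean pairwise Euclidean distance of the
    population at the same checkpoints.
    """

    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    diversity: list[float]
    ffe_count: int
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_position": self.best_position.tolist(),
                "best_fitness": self.best_fitness,
                "history": list(self.history),
                "diversity": list(self.diversity),
                "ffe_count": self.ffe_count,
                "seed": self.seed,
            }
        )

    def history_to_csv(self, path) -> None:
        """Convergence/diversity export: iteration, best_fitness,
        mean_pairwise_distance."""
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": range(len(self.history)),
                "best_fitness": self.history,
                "mean_pairwise_distance": self.diversity,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_json(cls, text: str) -> "RunResult":
        d = json.loads(text)
        return cls(
            best_position=np.asarray(d["best_position"], dtype=float),
            best_fitness=float(d["best_fitness"]),
            history=[float(x) for x in d["history"]],
            diversity=[float(x) for x in d["diversity"]],
            ffe_count=int(d["ffe_count"]),
            seed=d.get("seed"),
        )


def spawn_rng(base_seed: int, run_index: int = 0) -> np.random.Generator:
    """Independent, reproducible stream for run ``run_index``.

    Streams are spawned from ``(base_seed, run_index)`` so a 30-run
    campaign can be reproduced run by run.
    """
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(run_index)]))


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Component-wise clamp into [lower, upper] (box repair)."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise ValueError(
            f"position has shape {position.shape}, expected ({space.dim},)"
        )
    return np.clip(position, space.lower, space.upper)


def conventional_init(
    space: SearchSpace, count: int, rng: np.random.Generator
) -> Population:
    """Uniform initialization: X = LB + (UB - LB) * U(0,1), per component."""
    if count < 1:
        raise ValueError("count must be >= 1")
    members = [
        Solution(space.lower + space.span * rng.random(space.dim))
        for _ in range(count)
    ]
    return Population(members=members)


def evaluate(pop: Population, objective) -> Population:
    """Set every member's fitness; count one FFE per member.

    A non-finite objective value is recorded as +inf (with a warning) so a
    single failed training run cannot kill a whole campaign.
    """
    for sol in pop.members:
        value = float(objective(sol.position))
        if not np.isfinite(value):
            warnings.warn(
                "objective returned a non-finite value; recording +inf",
                stacklevel=2,
            )
            value = np.inf
        sol.fitness = value
        pop.ffe_count += 1
    return pop


def mean_pairwise_distance(pop: Population) -> float:
    """Population diversity: mean Euclidean distance over all pairs."""
    if len(pop) < 2:
        return 0.0
    X = np.stack([s.position for s in pop.members])
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(pop), k=1)
    return float(dist[iu].mean())
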