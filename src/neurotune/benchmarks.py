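"""Analytic benchmark objectives for verifying the optimizers.

Both functions follow the minimization convention used everywhere in the
package and have their global minimum (value 0) at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import SearchSpace

__all__ = ["sphere", "rastrigin", "BenchmarkProblem", "SPHERE", "RASTRIGIN"]


def sphere(position: np.ndarray) -> float:
    """Sum of squared components — convex, unimodal."""
    x = np.asarray(position, dtype=float)
    return float(np.sum(x**2))


def rastrigin(position: np.ndarray) -> float:
    """10*d + sum(x^2 - 10*cos(2*pi*x)) — highly multimodal."""
    x = np.asarray(position, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


@dataclass(frozen=True)
class BenchmarkProblem:
    name: str
    dimension: int
    bounds: tuple[float, float]
    objective: object
    optimum_position: np.ndarray
    optimum_value: float

    def space(self) -> SearchSpace:
        lo, hi = self.bounds
        return SearchSpace(
            lower=np.full(self.dimension, lo),
            upper=np.full(self.dimension, hi),
        )


def SPHERE(dimension: int = 10, bounds: tuple[float, float] = (-5.12, 5.12)) -> BenchmarkProblem:
    return BenchmarkProblem(
        "sphere", dimension, bounds, sphere, np.zeros(dimension), 0.0
    )


def RASTRIGIN(dimension: int = 10, bounds: tuple[float, float] = (-5.12, 5.12)) -> BenchmarkProblem:
    return BenchmarkProblem(
        "rastrigin", dimension, bounds, rastrigin, np.zeros(dimension), 0.0
    )
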