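"""Minimize a benchmark function with the hybrid optimizer.

Runs HASCA and plain SCA on the 10-dimensional sphere function under an
identical evaluation budget and prints both best values: the hybrid's
chaotic start and early firefly moves typically land one or more orders
of magnitude lower.
"""

from neurotune import HASCAConfig, hasca_optimize, sca_optimize, spawn_rng
from neurotune.benchmarks import SPHERE

problem = SPHERE(10)
cfg = HASCAConfig(N=20, T=100)

hasca = hasca_optimize(problem.space(), problem.objective, cfg, spawn_rng(1))
sca = sca_optimize(problem.space(), problem.objective, cfg, spawn_rng(1))

print(f"evaluation budget: {hasca.ffe_count} fitness evaluations each")
print(f"HASCA best fitness: {hasca.best_fitness:.3e}")
print(f"SCA   best fitness: {sca.best_fitness:.3e}")
print("(0 is the global optimum; lower is better)")
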