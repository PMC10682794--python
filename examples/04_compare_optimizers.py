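"""Compare optimizers with the run-aggregation and significance harness.

Runs 30 seeded HASCA and SCA campaigns on the 10-d Rastrigin function,
prints the Best/Worst/Mean/Median/Std/Var table, checks normality per
method (Shapiro-Wilk) and, since metaheuristic samples are rarely
normal, compares methods with the paired Wilcoxon signed-rank test
using HASCA as the control.
"""

import numpy as np

from neurotune import (
    HASCAConfig,
    compare_methods,
    hasca_optimize,
    sca_optimize,
    spawn_rng,
    summarize_runs,
)
from neurotune.benchmarks import RASTRIGIN

problem = RASTRIGIN(10)
cfg = HASCAConfig(N=20, T=100)

samples = {}
for name, opt in (("hasca", hasca_optimize), ("sca", sca_optimize)):
    samples[name] = np.array(
        [
            opt(problem.space(), problem.objective, cfg, spawn_rng(k)).best_fitness
            for k in range(30)
        ]
    )

print(f"{'method':<12} {'Best':>9}  {'Worst':>9}  {'Mean':>9}  {'Median':>9}  {'Std':>8}  {'Var':>8}")
for name, vals in samples.items():
    print(summarize_runs(vals).to_row(name))

report = compare_methods(samples, control="hasca")
for name, p in report.shapiro_p.items():
    print(f"Shapiro-Wilk p ({name}): {p:.4g}")
for name, p in report.wilcoxon_p.items():
    print(f"Wilcoxon signed-rank p (hasca vs {name}): {p:.4g}")
print("(p < 0.05 in the last line: the difference in best fitness is significant)")
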