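"""Hybrid hyperparameter search: Hyperband pre-filter, then particle swarm.

First shows the swarm recovering a known optimum (the sphere function) with
the reference settings — 30 particles, c1 = c2 = 2.0, inertia decaying
0.9 -> 0.4 over 50 iterations — then runs the two-stage search over the
model's own space with a cheap surrogate objective so the mechanics are
visible in seconds.
"""

import numpy as np

from capscan.optimize import PSOConfig, SearchSpace, decode_hyperparams, default_search_space, optimize

# 1) sanity benchmark: minimize ||x||^2 on [-5, 5]^4 (maximize its negative)
space = SearchSpace(names=list("abcd"), lower=[-5] * 4, upper=[5] * 4, integer=[False] * 4)
result = optimize(lambda x: -float(np.sum(x**2)), space, PSOConfig(seed=1))
print(f"sphere: gbest fitness {result.best_fitness:.2e} "
      f"(|x*| = {np.linalg.norm(result.best_position):.3f}; true optimum 0)")
print(f"gbest trace is non-decreasing: {all(a <= b for a, b in zip(result.trace, result.trace[1:]))}")

# 2) two-stage search over the model's tuning ranges with a surrogate
#    validation-accuracy landscape peaked at 128 units / dropout 0.3
model_space = default_search_space()


def surrogate(x, resource=50.0):
    units, dense, dropout, layers, batch = x
    score = 1.0 - ((units - 128) / 192) ** 2 - ((dropout - 0.3) / 0.3) ** 2 - 0.02 * abs(layers - 2)
    return float(score * min(1.0, resource / 50.0 + 0.5))


tuned = optimize(
    lambda x: surrogate(x),
    model_space,
    PSOConfig(swarm_size=15, iterations=25, seed=3),
    prefilter=True,
    prefilter_objective=surrogate,
    max_resource=27,
)
hp = decode_hyperparams(model_space, tuned.best_position)
print(f"\nnarrowed box: {np.round(tuned.narrowed_space.lower, 2)} .. "
      f"{np.round(tuned.narrowed_space.upper, 2)}")
print(f"best configuration: {hp}")
print(f"surrogate fitness {tuned.best_fitness:.4f} after {tuned.evaluations} evaluations")
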