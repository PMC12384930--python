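"""PSO velocity/position updates, inertia schedule, Hyperband pre-filter."""

import numpy as np
import pytest

from capscan.optimize import (
    PSOConfig,
    SearchSpace,
    Swarm,
    decode_hyperparams,
    default_search_space,
    hyperband_prefilter,
    inertia_schedule,
    optimize,
    pso_update,
)


class TestInertiaSchedule:
    def test_endpoints(self):
        assert inertia_schedule(0, 50) == 0.9
        assert abs(inertia_schedule(49, 50) - 0.4) < 1e-12

    def test_linearity_symmetry(self):
        for t in range(50):
            assert abs(inertia_schedule(t, 50) + inertia_schedule(49 - t, 50) - 1.3) < 1e-12

    def test_too_few_iterations_raises(self):
        with pytest.raises(ValueError):
            inertia_schedule(0, 1)


class _FixedRng:
    """Stand-in RNG yielding preset r1 then r2 draws."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, shape):
        return np.full(shape, self.values.pop(0))


def _one_particle_swarm(p, v, pbest, gbest):
    return Swarm(
        positions=np.array([[float(p)]]),
        velocities=np.array([[float(v)]]),
        pbest_positions=np.array([[float(pbest)]]),
        pbest_fitness=np.array([0.0]),
        gbest_position=np.array([float(gbest)]),
        gbest_fitness=0.0,
    )


class TestPsoUpdate:
    def test_fixed_point_at_consensus(self):
        space = SearchSpace(names=["x"], lower=[-10], upper=[10], integer=[False])
        swarm = _one_particle_swarm(p=2, v=0, pbest=2, gbest=2)
        pso_update(swarm, space, w=0.7, c1=2, c2=2, rng=_FixedRng([0.3, 0.8]))
        assert swarm.velocities[0, 0] == 0.0
        assert swarm.positions[0, 0] == 2.0

    def test_hand_computed_single_step(self):
        # w=0.5, c1=c2=2, r1=0.25, r2=0.5, p=1, v=1, pbest=2, gbest=3:
        # v' = 0.5*1 + 2*0.25*(2-1) + 2*0.5*(3-1) = 3.0 ; p' = 1 + 3 = 4
        space = SearchSpace(names=["x"], lower=[-10], upper=[10], integer=[False])
        swarm = _one_particle_swarm(p=1, v=1, pbest=2, gbest=3)
        pso_update(swarm, space, w=0.5, c1=2, c2=2, rng=_FixedRng([0.25, 0.5]))
        assert swarm.velocities[0, 0] == pytest.approx(3.0)
        assert swarm.positions[0, 0] == pytest.approx(4.0)

    def test_pure_inertial_decay(self):
        space = SearchSpace(names=["x"], lower=[-100], upper=[100], integer=[False])
        swarm = _one_particle_swarm(p=0, v=8, pbest=0, gbest=0)
        w = 0.5
        for t in range(1, 5):
            pso_update(swarm, space, w=w, c1=0, c2=0, rng=_FixedRng([0.1, 0.1]))
            assert abs(swarm.velocities[0, 0]) == pytest.approx(8 * w**t)

    def test_positions_clipped_and_velocity_zeroed(self):
        space = SearchSpace(names=["x"], lower=[0], upper=[1], integer=[False])
        swarm = _one_particle_swarm(p=0.9, v=0.4, pbest=0.9, gbest=0.9)
        pso_update(swarm, space, w=1.0, c1=0, c2=0, rng=_FixedRng([0.5, 0.5]))
        assert swarm.positions[0, 0] == 1.0
        assert swarm.velocities[0, 0] == 0.0


class TestHyperband:
    SPACE = SearchSpace(names=list("abcd"), lower=[-5] * 4, upper=[5] * 4, integer=[False] * 4)

    def test_narrowed_box_contains_optimum(self):
        hits = 0
        for seed in range(100):
            opt = np.random.default_rng(seed).uniform(-4, 4, 4)
            nb = hyperband_prefilter(
                self.SPACE, lambda x, r: -float(np.sum((x - opt) ** 2)), max_resource=27, seed=seed
            )
            hits += bool((nb.lower <= opt).all() and (opt <= nb.upper).all())
        assert hits >= 95

    def test_single_survivor_degenerates_to_point(self):
        nb = hyperband_prefilter(
            self.SPACE, lambda x, r: -float(np.sum(x**2)), max_resource=27, seed=0, top_q=1
        )
        assert np.all(nb.upper - nb.lower <= 0.2 * (self.SPACE.upper - self.SPACE.lower) + 1e-6)

    def test_narrowed_box_inside_original(self):
        for seed in range(10):
            nb = hyperband_prefilter(
                self.SPACE, lambda x, r: float(np.sum(np.sin(x))), max_resource=27, seed=seed
            )
            assert (nb.lower >= self.SPACE.lower - 1e-9).all()
            assert (nb.upper <= self.SPACE.upper + 1e-9).all()

    def test_no_budget_raises(self):
        with pytest.raises(ValueError):
            hyperband_prefilter(self.SPACE, lambda x, r: 0.0, max_resource=0.5)


class TestOptimize:
    SPHERE_SPACE = SearchSpace(names=list("abcd"), lower=[-5] * 4, upper=[5] * 4, integer=[False] * 4)

    def test_sphere_optimum_recovered(self):
        res = optimize(lambda x: -float(np.sum(x**2)), self.SPHERE_SPACE, PSOConfig(seed=1))
        assert -res.best_fitness < 1e-2

    def test_constant_objective_trivial(self):
        res = optimize(lambda x: 3.14, self.SPHERE_SPACE, PSOConfig(seed=0, iterations=5))
        assert res.best_fitness == 3.14
        assert res.trace[0] == 3.14

    def test_gbest_trace_monotone_over_seeds(self):
        for seed in range(20):
            res = optimize(
                lambda x: float(np.sum(np.cos(x))),
                self.SPHERE_SPACE,
                PSOConfig(seed=seed, swarm_size=8, iterations=10),
            )
            assert all(a <= b + 1e-12 for a, b in zip(res.trace, res.trace[1:]))

    def test_discrete_decode_stays_in_range(self):
        space = default_search_space()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            hp = decode_hyperparams(space, space.sample(rng, 1)[0])
            assert 1 <= hp.n_recurrent_layers <= 3
            assert 64 <= hp.units_per_layer <= 256
            assert 0.2 <= hp.dropout <= 0.5
            assert 32 <= hp.dense_units <= 128
            assert 32 <= hp.batch_size <= 128

    def test_prefilter_path_runs_and_narrows(self):
        res = optimize(
            lambda x: -float(np.sum(x**2)),
            self.SPHERE_SPACE,
            PSOConfig(seed=2, swarm_size=10, iterations=10),
            prefilter=True,
            prefilter_objective=lambda x, r: -float(np.sum(x**2)),
        )
        assert res.narrowed_space is not None
        assert (res.narrowed_space.lower >= self.SPHERE_SPACE.lower).all()
        assert -res.best_fitness < 1.0
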