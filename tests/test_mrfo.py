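"""MRFO movement rules, population sweep and full optimization loop."""

import numpy as np
import pytest

from mrfopt.fitness import AnalyticFitness
from mrfopt.mrfo import (
    MRFOParams,
    Population,
    UpdateDraws,
    chain_update,
    cyclone_update,
    init_population,
    run_mrfo,
    somersault_update,
    update_population,
)

P = MRFOParams(n_max=2, t_max=2, seed=0)


def vec(*vals):
    return np.array(vals, dtype=float)


class TestMovementRules:
    def test_cyclone_exploitation_hand_value(self):
        # 1-D, second-ranked member, exploitation branch:
        # 0.9 + 0.5*(0.6-0.2) + 1*(0.9-0.2) = 1.8, clipped to 1
        d = UpdateDraws(r=0.5, beta=1.0, phase_draw=0.0)
        out = cyclone_update(vec(0.2), vec(0.6), vec(0.9), d, i=2, t=1, params=P)
        assert out[0] == pytest.approx(1.0)

    def test_cyclone_exploitation_fixed_point(self):
        x = vec(0.4, 0.6)
        for r, beta in [(0.1, 0.5), (0.9, 2.0)]:
            d = UpdateDraws(r=r, beta=beta, phase_draw=0.0)
            out = cyclone_update(x, x, x, d, i=1, t=2, params=P)
            np.testing.assert_allclose(out, x)

    def test_cyclone_exploration_fixed_point_at_reference(self):
        # leader sitting exactly on the random reference does not move
        d = UpdateDraws(r=0.7, beta=1.3, phase_draw=0.99, reference=vec(0.5))
        out = cyclone_update(vec(0.5), vec(0.5), vec(0.1), d, i=1, t=1, params=P)
        assert out[0] == pytest.approx(0.5)

    def test_cyclone_exploration_requires_reference(self):
        d = UpdateDraws(r=0.5, beta=1.0, phase_draw=0.99, reference=None)
        with pytest.raises(ValueError):
            cyclone_update(vec(0.2), vec(0.2), vec(0.9), d, i=1, t=1, params=P)

    def test_chain_hand_value_and_fixed_points(self):
        # 0.2 + 0.5*(0.8-0.2) + 0.5*(0.8-0.2) = 0.8
        d = UpdateDraws(r=0.5, alpha=0.5)
        assert chain_update(vec(0.2), vec(0.2), vec(0.8), d, i=1)[0] == pytest.approx(0.8)
        x = vec(0.3)
        d = UpdateDraws(r=0.6, alpha=0.9)
        assert chain_update(x, x, x, d, i=2)[0] == pytest.approx(0.3)
        # alpha=0, r=1 is a full convex step onto the anchor
        d = UpdateDraws(r=1.0, alpha=0.0)
        assert chain_update(vec(0.1), vec(0.9), vec(0.7), d, i=1)[0] == pytest.approx(0.7)

    def test_somersault_hand_value_and_fixed_points(self):
        p = MRFOParams(n_max=1, t_max=1, somersault_factor=2.0)
        d = UpdateDraws(r2=0.5, r3=0.25)
        # 0.4 + 2*(0.5*0.8 - 0.25*0.4) = 1.0
        assert somersault_update(vec(0.4), vec(0.8), d, p)[0] == pytest.approx(1.0)
        d = UpdateDraws(r2=0.3, r3=0.3)
        assert somersault_update(vec(0.6), vec(0.6), d, p)[0] == pytest.approx(0.6)
        d = UpdateDraws(r2=0.0, r3=0.0)
        assert somersault_update(vec(0.2), vec(0.9), d, p)[0] == pytest.approx(0.2)

    def test_all_rules_preserve_bounds_under_fuzzed_draws(self):
        rng = np.random.default_rng(7)
        p = MRFOParams(n_max=1, t_max=5, somersault_factor=2.0)
        for _ in range(500):
            x_i, x_prev, x_best = rng.uniform(size=(3, 4))
            d = UpdateDraws(
                r=rng.uniform(),
                alpha=rng.uniform(0, 3),
                beta=rng.uniform(-4, 4),
                r2=rng.uniform(),
                r3=rng.uniform(),
                phase_draw=rng.uniform(),
                reference=rng.uniform(size=4),
            )
            t = rng.integers(1, 6)
            for out in (
                cyclone_update(x_i, x_prev, x_best, d, i=2, t=t, params=p),
                chain_update(x_i, x_prev, x_best, d, i=2, params=p),
                somersault_update(x_i, x_best, d, p),
            ):
                assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestPopulation:
    def test_init_population_bounds_and_determinism(self):
        p = MRFOParams(n_max=10, t_max=1, seed=7)
        pop1 = init_population(p, 15)
        pop2 = init_population(p, 15)
        assert len(pop1.solutions) == 10
        for a, b in zip(pop1.solutions, pop2.solutions):
            np.testing.assert_array_equal(a, b)
            assert a.shape == (15,) and np.all((a >= 0) & (a <= 1))

    def test_constant_fitness_keeps_best(self):
        p = MRFOParams(n_max=3, t_max=4, seed=1)
        _, best, hist = run_mrfo(2, lambda x: 0.5, p)
        assert best == 0.5
        assert all(b == 0.5 for b in hist.best_scores)

    def test_single_member_population_runs(self):
        p = MRFOParams(n_max=1, t_max=1, seed=3)
        bx, bs, _ = run_mrfo(3, AnalyticFitness(np.full(3, 0.5)), p)
        assert bx.shape == (3,) and 0 <= bs <= 1

    def test_update_population_never_worsens_best(self):
        p = MRFOParams(n_max=5, t_max=3, seed=11)
        f = AnalyticFitness(np.array([0.2, 0.8]))
        pop = init_population(p, 2)
        pop.scores = [f(x) for x in pop.solutions]
        best_before = max(pop.scores)
        for t in range(1, 4):
            pop = update_population(pop, f, p, t)
            assert pop.best_score >= best_before
            best_before = pop.best_score

    def test_failing_member_gets_sentinel_and_run_continues(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise RuntimeError("training crashed")
            return float(x[0])

        p = MRFOParams(n_max=3, t_max=2, seed=5)
        bx, bs, _ = run_mrfo(1, flaky, p)
        assert np.isfinite(bs)


class TestFullLoop:
    def test_history_shape_and_monotonicity(self):
        p = MRFOParams(n_max=4, t_max=6, seed=2)
        _, _, hist = run_mrfo(2, AnalyticFitness(np.array([0.5, 0.5])), p)
        assert len(hist.per_iteration) == 6
        bs = hist.best_scores
        assert all(b >= a for a, b in zip(bs, bs[1:]))

    def test_determinism_bit_identical_histories(self):
        p = MRFOParams(n_max=5, t_max=5, seed=9)
        f = AnalyticFitness(np.array([0.3, 0.7]))
        _, s1, h1 = run_mrfo(2, f, p)
        _, s2, h2 = run_mrfo(2, f, p)
        assert s1 == s2
        assert [r["score"] for r in h1.records] == [r["score"] for r in h2.records]

    def test_bounds_preserved_throughout(self):
        p = MRFOParams(n_max=6, t_max=8, seed=13)
        seen = []

        def spy(x):
            seen.append(np.array(x))
            return AnalyticFitness(np.array([0.5] * 3))(x)

        run_mrfo(3, spy, p)
        stacked = np.stack(seen)
        assert stacked.min() >= 0.0 and stacked.max() <= 1.0

    def test_converges_to_sphere_optimum(self):
        # grid-search oracle on the same domain locates the optimum cell
        target = np.array([0.25, 0.65])
        f = AnalyticFitness(target)
        grid = np.linspace(0, 1, 101)
        oracle_best = max(
            f(np.array([a, b])) for a in grid for b in grid
        )
        p = MRFOParams(n_max=10, t_max=50, seed=4)
        _, bs, _ = run_mrfo(2, f, p)
        assert abs(bs - oracle_best) < 1e-2


def algorithm_sweep_oracle(solutions, scores, fitness, params, t, draws):
    """Straight-line re-implementation of the population-update pseudocode.

    Independent of the package's update functions: equations are written
    out literally, members updated in place in rank order.
    """
    order = sorted(range(len(scores)), key=lambda j: -scores[j])
    sols = [np.array(solutions[j], dtype=float) for j in order]
    best = np.array(sols[0], dtype=float)
    best_score = scores[order[0]]
    n = len(sols)
    for idx in range(n):
        d = draws[(t, idx + 1, 1)]
        x = sols[idx]
        if d.branch_draw < 0.5:
            if t / params.t_max < d.phase_draw:
                ref = np.asarray(d.reference, float)
                if idx == 0:
                    x = ref + d.r * (ref - x) + d.beta * (ref - x)
                else:
                    x = ref + d.r * (sols[idx - 1] - x) + d.beta * (ref - x)
            else:
                if idx == 0:
                    x = best + d.r * (best - x) + d.beta * (best - x)
                else:
                    x = best + d.r * (sols[idx - 1] - x) + d.beta * (best - x)
        else:
            if idx == 0:
                x = x + d.r * (best - x) + d.alpha * (best - x)
            else:
                x = x + d.r * (sols[idx - 1] - x) + d.alpha * (best - x)
        sols[idx] = np.clip(x, 0, 1)
    new_scores = []
    for idx in range(n):
        s = fitness(sols[idx])
        new_scores.append(s)
        if s > best_score:
            best_score, best = s, np.array(sols[idx])
    for idx in range(n):
        d = draws[(t, idx + 1, 2)]
        sols[idx] = np.clip(
            sols[idx] + params.somersault_factor * (d.r2 * best - d.r3 * sols[idx]), 0, 1
        )
    final_scores = []
    for idx in range(n):
        s = fitness(sols[idx])
        final_scores.append(s)
        if s > best_score:
            best_score, best = s, np.array(sols[idx])
    return sols, final_scores, best, best_score


class TestSweepOracle:
    def test_matches_hand_traced_pseudocode_member_for_member(self):
        fitness = lambda x: 1.0 - float((x[0] - 0.6) ** 2)  # 1-D quadratic
        params = MRFOParams(n_max=3, t_max=2, somersault_factor=2.0, seed=0)
        rng = np.random.default_rng(2024)
        draws = {}
        for i in (1, 2, 3):
            draws[(1, i, 1)] = UpdateDraws(
                branch_draw=rng.uniform(),
                phase_draw=rng.uniform(),
                reference=rng.uniform(size=1),
                r=rng.uniform(),
                alpha=rng.uniform(0, 2),
                beta=rng.uniform(-2, 2),
            )
            draws[(1, i, 2)] = UpdateDraws(r2=rng.uniform(), r3=rng.uniform())

        solutions = [np.array([0.2]), np.array([0.9]), np.array([0.55])]
        scores = [fitness(x) for x in solutions]

        pop = Population(solutions=[np.array(s) for s in solutions], scores=list(scores))
        out = update_population(
            pop, fitness, params, t=1, draws_fn=lambda t, i, sweep: draws[(t, i, sweep)]
        )
        exp_sols, exp_scores, exp_best, exp_best_score = algorithm_sweep_oracle(
            solutions, scores, fitness, params, 1, draws
        )
        for got, want in zip(out.solutions, exp_sols):
            np.testing.assert_allclose(got, want)
        assert out.scores == pytest.approx(exp_scores)
        assert out.best_score == pytest.approx(exp_best_score)
        np.testing.assert_allclose(out.best_solution, exp_best)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_max=0), dict(t_max=0), dict(somersault_factor=0),
                   dict(lower_bound=1.0, upper_bound=0.0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MRFOParams(**kwargs)
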