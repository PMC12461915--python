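"""Cost function, MH gate, random-walk seeding, LGP surrogate, DE loop."""

import math

import numpy as np
import pytest

from eccforge.campaigns import (
    PLANTED_OPTIMUM,
    planted_quadratic_stage,
    rosenbrock_evaluator,
)
from eccforge.lgp import LocalGaussianProcess, SurrogateError
from eccforge.optimizer import (
    EvaluatedSample,
    OptimizerError,
    OracleSurrogate,
    ParameterVector,
    PropertyTarget,
    PropertyTargetSet,
    cost,
    de_generation,
    evaluate_sample,
    mh_accept,
    random_walk_seed,
    run_campaign,
    run_stage,
    scaling_factor_histogram,
    StageConfig,
)


class TestCost:
    def test_zero_at_reference_with_special_variance(self):
        """σ² = 1/(2π) kills the log term; zero residual kills the quadratic."""
        targets = PropertyTargetSet([PropertyTarget("a", 2.0, 1.0 / (2 * math.pi))])
        assert cost({"a": 2.0}, targets) == pytest.approx(0.0, abs=1e-14)

    def test_two_target_hand_evaluation(self):
        targets = PropertyTargetSet(
            [PropertyTarget("a", 1.0, 1.0), PropertyTarget("b", 0.0, 4.0)]
        )
        n = 2
        expected = (
            n / 2 * math.log(2 * math.pi * 1.0) + 1.0**2 / 2.0
            + n / 2 * math.log(2 * math.pi * 4.0) + (-2.0) ** 2 / 8.0
        )
        assert cost({"a": 2.0, "b": -2.0}, targets) == pytest.approx(expected)

    def test_variance_scaling_monotonicity(self):
        """Growing σ² at fixed residual shrinks the quadratic term and grows the log term."""
        def parts(s2):
            return math.log(2 * math.pi * s2) / 2, 1.0 / (2 * s2)

        l1, q1 = parts(1.0)
        l2, q2 = parts(4.0)
        assert l2 > l1 and q2 < q1
        # total cost reflects both
        t_small = PropertyTargetSet([PropertyTarget("a", 0.0, 1.0)])
        t_big = PropertyTargetSet([PropertyTarget("a", 0.0, 4.0)])
        assert cost({"a": 1.0}, t_big) != cost({"a": 1.0}, t_small)

    def test_missing_property_named(self):
        targets = PropertyTargetSet([PropertyTarget("rho", 1.0, 1.0)])
        with pytest.raises(OptimizerError, match="rho"):
            cost({}, targets)


class TestMHAccept:
    def test_better_offspring_always_accepted(self):
        assert mh_accept(5.0, 3.0, u=1.0)
        assert mh_accept(5.0, 5.0, u=1.0)  # boundary: A = 1

    def test_worse_offspring_accepted_with_boltzmann_probability(self):
        assert mh_accept(3.0, 3.0 + math.log(2.0), u=0.49)
        assert not mh_accept(3.0, 3.0 + math.log(2.0), u=0.51)

    def test_empirical_frequency_small_sample(self):
        rng = np.random.default_rng(5)
        draws = rng.random(20_000)
        acc = np.mean([mh_accept(0.0, math.log(2.0), u) for u in draws])
        assert acc == pytest.approx(0.5, abs=0.012)

    def test_infinite_cost_rejected(self):
        assert not mh_accept(1.0, math.inf, 0.0)
        assert mh_accept(math.inf, 1.0, 1.0)


class TestRandomWalk:
    def _start(self, bounds):
        mid = [(lo + hi) / 2 for lo, hi in bounds]
        return ParameterVector(["a", "b"], mid, bounds)

    def test_single_sample_is_the_start_point(self):
        bounds = [(0.0, 1.0), (-1.0, 1.0)]
        out = random_walk_seed(bounds, self._start(bounds), n_samples=1)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].values, [0.5, 0.0])

    def test_all_samples_respect_bounds(self):
        rng_master = np.random.default_rng(99)
        for _ in range(50):
            lo = rng_master.uniform(-5, 0, 2)
            hi = lo + rng_master.uniform(0.1, 3, 2)
            bounds = list(zip(lo, hi))
            rng = np.random.default_rng(int(rng_master.integers(2**31)))
            out = random_walk_seed(bounds, self._start(bounds), 200,
                                   step_frac=0.3, rng=rng)
            arr = np.stack([pv.values for pv in out])
            assert np.all(arr >= lo - 1e-12) and np.all(arr <= hi + 1e-12)

    def test_deterministic_under_seed(self):
        bounds = [(0.0, 1.0), (0.0, 2.0)]
        a = random_walk_seed(bounds, self._start(bounds), 50,
                             rng=np.random.default_rng(7))
        b = random_walk_seed(bounds, self._start(bounds), 50,
                             rng=np.random.default_rng(7))
        np.testing.assert_array_equal(
            np.stack([p.values for p in a]), np.stack([p.values for p in b])
        )

    def test_zero_width_bounds_rejected(self):
        bounds = [(0.0, 0.0), (0.0, 1.0)]
        with pytest.raises(OptimizerError, match="zero-width"):
            random_walk_seed(bounds, ParameterVector(["a", "b"], [0.0, 0.5], bounds), 10)


class TestLocalGaussianProcess:
    bounds = [(0.0, 1.0), (0.0, 1.0)]

    def _training(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, 2))
        y = 3.0 * X[:, 0] - X[:, 1]
        return X, {"y": y}

    def test_interpolates_training_point(self):
        X, props = self._training()
        gp = LocalGaussianProcess(self.bounds, locality=None, noise_level=1e-10)
        gp.fit(X, props)
        mu, _var = gp.predict(X[7])
        assert mu["y"] == pytest.approx(props["y"][7], abs=1e-4)

    def test_linear_function_held_out_rmse(self):
        X, props = self._training(50, seed=1)
        gp = LocalGaussianProcess(self.bounds, locality=30)
        gp.fit(X, props)
        rng = np.random.default_rng(2)
        Xq = rng.uniform(0.1, 0.9, (40, 2))
        preds = np.array([gp.predict(x)[0]["y"] for x in Xq])
        truth = 3.0 * Xq[:, 0] - Xq[:, 1]
        rmse = np.sqrt(np.mean((preds - truth) ** 2))
        assert rmse < 0.01 * (props["y"].max() - props["y"].min())

    def test_full_locality_equals_global_gp(self):
        X, props = self._training(30, seed=3)
        g_local = LocalGaussianProcess(self.bounds, locality=30)
        g_global = LocalGaussianProcess(self.bounds, locality=None)
        g_local.fit(X, props)
        g_global.fit(X, props)
        q = np.array([0.4, 0.6])
        assert g_local.predict(q)[0]["y"] == pytest.approx(
            g_global.predict(q)[0]["y"], abs=1e-10
        )

    def test_untrained_prediction_rejected(self):
        gp = LocalGaussianProcess(self.bounds)
        with pytest.raises(SurrogateError, match="untrained"):
            gp.predict(np.array([0.5, 0.5]))


def _quad_evaluator(theta, seed):
    return {"f": (theta["x"] - 0.2) ** 2 + (theta["y"] + 0.4) ** 2}


def _make_population(n, rng, targets):
    bounds = [(-1.0, 1.0), (-1.0, 1.0)]
    pop = []
    for _ in range(n):
        v = rng.uniform(-1, 1, 2)
        pv = ParameterVector(["x", "y"], v, bounds)
        pop.append(evaluate_sample(pv, targets, _quad_evaluator, 0, "random-walk"))
    return pop


class TestDEGeneration:
    targets = PropertyTargetSet([PropertyTarget("f", 0.0, 1.0)])

    def test_small_population_rejected(self):
        rng = np.random.default_rng(0)
        pop = _make_population(3, rng, self.targets)
        with pytest.raises(OptimizerError, match="at least 4"):
            de_generation(pop, self.targets, _quad_evaluator,
                          OracleSurrogate(_quad_evaluator), rng)

    def test_convex_bowl_reaches_optimum_with_oracle_surrogate(self):
        """Plain DE + exact MH gate solves a 2-D quadratic to <1e-6."""
        rng = np.random.default_rng(4)
        pop = _make_population(12, rng, self.targets)
        surrogate = OracleSurrogate(_quad_evaluator)
        best = min(s.cost for s in pop)
        for _gen in range(200):
            pop, _ = de_generation(pop, self.targets, _quad_evaluator, surrogate, rng)
            new_best = min(s.cost for s in pop)
            assert new_best <= best + 1e-15  # selection is greedy
            best = new_best
        f_best = min(s.properties["f"] for s in pop)
        assert f_best < 1e-6

    def test_oracle_surrogate_matches_plain_de_reimplementation(self):
        """Given identical predictions and seeds the gate decisions coincide
        with an independent rand/1/bin + MH reimplementation."""
        targets = self.targets
        pop = _make_population(8, np.random.default_rng(11), targets)
        rng1 = np.random.default_rng(21)
        _, decisions = de_generation(
            pop, targets, _quad_evaluator, OracleSurrogate(_quad_evaluator), rng1
        )
        # independent reimplementation consuming the same RNG stream
        rng2 = np.random.default_rng(21)
        n, dim = len(pop), 2
        lo = np.array([-1.0, -1.0])
        hi = np.array([1.0, 1.0])
        ref_pop = list(pop)
        for i, dec in enumerate(decisions):
            parent = ref_pop[i]
            choices = [j for j in range(n) if j != i]
            r1, r2, r3 = rng2.choice(choices, size=3, replace=False)
            mutant = ref_pop[r1].theta.values + 0.8 * (
                ref_pop[r2].theta.values - ref_pop[r3].theta.values
            )
            cross = rng2.random(dim) < 0.9
            cross[rng2.integers(dim)] = True
            trial = np.clip(np.where(cross, mutant, parent.theta.values), lo, hi)
            J_pred = cost(_quad_evaluator(dict(zip(["x", "y"], trial)), 0), targets)
            u = float(rng2.random())
            expected_accept = u <= min(1.0, math.exp(min(parent.cost - J_pred, 0.0)))
            assert dec.accepted == expected_accept
            np.testing.assert_allclose(dec.candidate.values, trial)
            if dec.accepted and dec.evaluated.cost < parent.cost:
                ref_pop[i] = dec.evaluated


class TestCampaign:
    def test_empty_stage_list_rejected(self):
        with pytest.raises(OptimizerError, match="empty"):
            run_campaign([])

    def test_planted_optimum_recovery_and_retrain_cadence(self):
        stage = planted_quadratic_stage(max_evaluations=400)
        result = run_stage(stage, seed=2)
        best = result.best.theta.as_dict()
        assert best["a"] == pytest.approx(PLANTED_OPTIMUM["a"], abs=0.02)
        assert best["b"] == pytest.approx(PLANTED_OPTIMUM["b"], abs=0.02)
        accepted = sum(
            1 for s in result.archive if s.provenance == "de-offspring" and not s.failed
        )
        assert result.n_retrains == 1 + accepted // 50

    def test_failed_evaluations_are_flagged_and_skipped(self):
        def flaky(theta, seed):
            if theta["x"] > 0.5:
                raise RuntimeError("diverged")
            return {"f": theta["x"] ** 2}

        targets = PropertyTargetSet([PropertyTarget("f", 0.0, 1.0)])
        pv = ParameterVector(["x"], [0.9], [(-1.0, 1.0)])
        sample = evaluate_sample(pv, targets, flaky, 0, "random-walk")
        assert sample.failed and math.isinf(sample.cost)

    def test_stage_freezing_passes_parameters_forward(self):
        def eval1(theta, seed):
            return {"f": (theta["x"] - 0.3) ** 2}

        seen = {}

        def eval2(theta, seed):
            seen["x"] = theta["x"]
            return {"g": (theta["y"] - theta["x"]) ** 2}

        t1 = PropertyTargetSet([PropertyTarget("f", 0.0, 1.0)])
        t2 = PropertyTargetSet([PropertyTarget("g", 0.0, 1.0)])
        s1 = StageConfig("one", ["x"], [(-1.0, 1.0)], [0.0], t1, eval1,
                         n_seed=12, n_generations=40, max_evaluations=120,
                         use_oracle_surrogate=True)
        s2 = StageConfig("two", ["y"], [(-1.0, 1.0)], [0.0], t2, eval2,
                         n_seed=12, n_generations=10, max_evaluations=40,
                         use_oracle_surrogate=True, freeze_from_previous=["x"])
        result = run_campaign([s1, s2], seed=1)
        x_best = result.stages[0].best.theta.as_dict()["x"]
        assert x_best == pytest.approx(0.3, abs=0.02)
        assert seen["x"] == x_best
        y_best = result.stages[1].best.theta.as_dict()["y"]
        assert y_best == pytest.approx(x_best, abs=0.05)

    def test_scaling_histogram_over_top_samples(self):
        targets = PropertyTargetSet([PropertyTarget("f", 0.0, 1.0)])
        rng = np.random.default_rng(8)
        archive = []
        for _ in range(60):
            v = rng.uniform(0.7, 0.95)
            pv = ParameterVector(["s"], [v], [(0.7, 0.95)])
            archive.append(
                EvaluatedSample(pv, {"f": (v - 0.81) ** 2},
                                cost((
                                    {"f": (v - 0.81) ** 2}), targets),
                                "random-walk", 0)
            )
        hist = scaling_factor_histogram(archive, "s", top_n=25, bin_width=0.01)
        assert hist["counts"].sum() == 25
        # top samples cluster near the optimum scaling factor
        centers = 0.5 * (hist["bin_edges"][:-1] + hist["bin_edges"][1:])
        mode = centers[np.argmax(hist["counts"])]
        assert abs(mode - 0.81) < 0.03
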