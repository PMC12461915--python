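"""Surrogate-assisted global optimization of force-field parameters.

The campaign loop mirrors the active-learning protocol used to fit the
scaled-charge ion models: a reflective random walk seeds ~200 evaluated
parameter sets; differential evolution (rand/1/bin) then proposes
offspring, whose cost is first *predicted* by the local Gaussian-process
surrogate and gated by a Metropolis–Hastings rule

    A(θ, θ′) = min(1, exp(J(θ′) − J(θ)))

comparing the parent's evaluated cost J(θ′) against the offspring's
predicted cost J(θ).  Accepted offspring are sent to full evaluation,
added to the training archive (the surrogate is retrained every 50 new
points), and replace their parent only if the fully evaluated cost
improves on the parent's.  The cost is the negative log-likelihood

    J(θ) = Σ_i [ (n/2)·log(2π σ_i²) + (y_i(θ) − μ_i)² / (2σ_i²) ]

over n property targets with reference values μ_i and predefined
variances σ_i².  Multi-stage protocols freeze earlier-stage optima
(e.g. a shared anion model and scaling factor) into later stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .lgp import RETRAIN_EVERY, LocalGaussianProcess

DEFAULT_F = 0.8
DEFAULT_CR = 0.9
DEFAULT_N_SEED = 200


class OptimizerError(ValueError):
    pass


# -- domain types ----------------------------------------------------------


@dataclass
class ParameterVector:
    """Named, bounded point in force-field parameter space."""

    names: list[str]
    values: np.ndarray
    bounds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size or len(self.bounds) != self.values.size:
            raise OptimizerError("names/values/bounds length mismatch")
        for name, v, (lo, hi) in zip(self.names, self.values, self.bounds):
            if lo > hi:
                raise OptimizerError(f"{name}: invalid bounds ({lo}, {hi})")
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise OptimizerError(f"{name}={v} outside bounds ({lo}, {hi})")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def replace(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(self.names, np.asarray(values, dtype=float), self.bounds)


@dataclass(frozen=True)
class PropertyTarget:
    name: str
    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise OptimizerError(f"{self.name}: variance must be positive")


@dataclass
class PropertyTargetSet:
    targets: list[PropertyTarget]

    def __post_init__(self) -> None:
        if not self.targets:
            raise OptimizerError("need at least one target")

    def __iter__(self):
        return iter(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class EvaluatedSample:
    theta: ParameterVector
    properties: dict[str, float]
    cost: float
    provenance: str  # "random-walk" | "de-offspring"
    seed: int
    failed: bool = False


# -- cost and acceptance ---------------------------------------------------


def cost(properties: Mapping[str, float], targets: PropertyTargetSet) -> float:
    """Negative log-likelihood cost J over the target set.

    The (n/2)·log(2πσ_i²) factor sits inside the per-target sum with n
    the total number of targets.
    """
    n = len(targets)
    J = 0.0
    for t in targets:
        if t.name not in properties:
            raise OptimizerError(f"missing property value for target {t.name}")
        y = properties[t.name]
        J += 0.5 * n * math.log(2.0 * math.pi * t.sigma2) + (y - t.mu) ** 2 / (2.0 * t.sigma2)
    return J


def mh_accept(J_parent: float, J_offspring_predicted: float, u: float) -> bool:
    """Metropolis–Hastings gate: accept iff u ≤ min(1, exp(J_parent − J_pred)).

    Offspring predicted to be no worse than the parent are always
    accepted; worse offspring survive with probability exp(−ΔJ).
    """
    if not (math.isfinite(J_parent) and math.isfinite(J_offspring_predicted)):
        return J_offspring_predicted < J_parent
    delta = J_parent - J_offspring_predicted
    if delta >= 0.0:
        return True
    return u <= math.exp(delta)


# -- random-walk seeding ---------------------------------------------------


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard reflection)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def random_walk_seed(
    bounds: Sequence[tuple[float, float]],
    start: ParameterVector,
    n_samples: int = DEFAULT_N_SEED,
    step_frac: float = 0.05,
    rng: np.random.Generator | None = None,
) -> list[ParameterVector]:
    """Reflective Gaussian random walk from ``start``; deterministic under seed.

    Step standard deviation is ``step_frac`` of each bound span.  The
    first sample is the start point itself.
    """
    rng = rng or np.random.default_rng(0)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise OptimizerError("zero-width bounds dimension")
    sigma = step_frac * (hi - lo)
    out = [start]
    x = start.values.copy()
    for _ in range(n_samples - 1):
        x = _reflect(x + rng.normal(0.0, sigma), lo, hi)
        out.append(start.replace(x))
    return out


# -- differential evolution ------------------------------------------------


@dataclass
class OffspringDecision:
    parent_index: int
    candidate: ParameterVector
    predicted_cost: float
    accepted: bool
    evaluated: EvaluatedSample | None = None
    replaced_parent: bool = False


class OracleSurrogate:
    """Pass-through surrogate: predicts by running the true evaluator.

    Substituting this for the LGP reduces the algorithm to plain DE with
    an exact MH gate; used for oracle-equivalence checks.
    """

    def __init__(self, evaluator: Callable[[dict[str, float], int], dict[str, float]],
                 seed: int = 0) -> None:
        self.evaluator = evaluator
        self.seed = seed

    def predict_properties(self, pv: ParameterVector) -> dict[str, float]:
        return self.evaluator(pv.as_dict(), self.seed)


def de_generation(
    population: list[EvaluatedSample],
    targets: PropertyTargetSet,
    evaluator: Callable[[dict[str, float], int], dict[str, float]],
    surrogate: LocalGaussianProcess | OracleSurrogate,
    rng: np.random.Generator,
    F: float = DEFAULT_F,
    CR: float = DEFAULT_CR,
    eval_seed: int = 0,
) -> tuple[list[EvaluatedSample], list[OffspringDecision]]:
    """One rand/1/bin DE generation with surrogate pre-screening.

    Returns the updated population and the per-parent decision records.
    Population must hold at least 4 members (three distinct non-parent
    donors are needed for rand/1 mutation).
    """
    if len(population) < 4:
        raise OptimizerError("population must have at least 4 members")
    if isinstance(surrogate, LocalGaussianProcess) and surrogate.X is None:
        raise OptimizerError("surrogate is untrained")
    n = len(population)
    dim = population[0].theta.values.size
    lo = np.array([b[0] for b in population[0].theta.bounds])
    hi = np.array([b[1] for b in population[0].theta.bounds])
    new_pop = list(population)
    decisions: list[OffspringDecision] = []
    for i in range(n):
        parent = new_pop[i]
        choices = [j for j in range(n) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        mutant = (
            new_pop[r1].theta.values
            + F * (new_pop[r2].theta.values - new_pop[r3].theta.values)
        )
        cross = rng.random(dim) < CR
        cross[rng.integers(dim)] = True  # at least one gene from the mutant
        trial = np.where(cross, mutant, parent.theta.values)
        trial = np.clip(trial, lo, hi)
        candidate = parent.theta.replace(trial)

        if isinstance(surrogate, OracleSurrogate):
            pred_props = surrogate.predict_properties(candidate)
        else:
            pred_props, _ = surrogate.predict(candidate.values)
        J_pred = cost(pred_props, targets)
        u = float(rng.random())
        accepted = mh_accept(parent.cost, J_pred, u)
        decision = OffspringDecision(
            parent_index=i, candidate=candidate, predicted_cost=J_pred, accepted=accepted
        )
        if accepted:
            sample = evaluate_sample(candidate, targets, evaluator, eval_seed, "de-offspring")
            decision.evaluated = sample
            if not sample.failed and sample.cost < parent.cost:
                new_pop[i] = sample
                decision.replaced_parent = True
        decisions.append(decision)
    return new_pop, decisions


def evaluate_sample(
    theta: ParameterVector,
    targets: PropertyTargetSet,
    evaluator: Callable[[dict[str, float], int], dict[str, float]],
    seed: int,
    provenance: str,
) -> EvaluatedSample:
    """Run the full evaluator; failures yield cost +inf and a failed flag."""
    try:
        props = evaluator(theta.as_dict(), seed)
        J = cost(props, targets)
        return EvaluatedSample(theta, props, J, provenance, seed)
    except OptimizerError:
        raise
    except Exception:
        return EvaluatedSample(theta, {}, math.inf, provenance, seed, failed=True)


# -- campaign --------------------------------------------------------------


@dataclass
class StageConfig:
    """One optimization stage: its own bounds, targets and evaluator."""

    name: str
    parameter_names: list[str]
    bounds: list[tuple[float, float]]
    start: list[float]
    targets: PropertyTargetSet
    evaluator: Callable[[dict[str, float], int], dict[str, float]]
    n_seed: int = DEFAULT_N_SEED
    n_generations: int = 50
    max_evaluations: int | None = None
    F: float = DEFAULT_F
    CR: float = DEFAULT_CR
    locality: int | None = 50
    step_frac: float = 0.05
    freeze_from_previous: list[str] = field(default_factory=list)
    use_oracle_surrogate: bool = False


@dataclass
class StageResult:
    name: str
    archive: list[EvaluatedSample]
    best: EvaluatedSample
    n_evaluations: int
    n_retrains: int
    frozen: dict[str, float]


@dataclass
class CampaignResult:
    stages: list[StageResult]

    @property
    def best(self) -> EvaluatedSample:
        return self.stages[-1].best


def run_stage(
    stage: StageConfig,
    seed: int,
    frozen: Mapping[str, float] | None = None,
) -> StageResult:
    """Seed, evaluate, and run the active-learning DE loop for one stage."""
    frozen = dict(frozen or {})
    rng = np.random.default_rng(seed)

    def eval_with_frozen(theta: dict[str, float], s: int) -> dict[str, float]:
        return stage.evaluator({**theta, **frozen}, s)

    start = ParameterVector(stage.parameter_names, np.asarray(stage.start, float), stage.bounds)
    seeds = random_walk_seed(stage.bounds, start, stage.n_seed, stage.step_frac, rng)
    archive: list[EvaluatedSample] = []
    for pv in seeds:
        archive.append(evaluate_sample(pv, stage.targets, eval_with_frozen, seed, "random-walk"))
    n_evaluations = len(archive)

    if stage.use_oracle_surrogate:
        surrogate: LocalGaussianProcess | OracleSurrogate = OracleSurrogate(
            eval_with_frozen, seed
        )
        n_retrains = 0
    else:
        surrogate = LocalGaussianProcess(stage.bounds, locality=stage.locality, rng=rng)
        _retrain(surrogate, archive)
        n_retrains = 1
    since_retrain = 0

    population = [s for s in archive if not s.failed]
    if len(population) < 4:
        raise OptimizerError("fewer than 4 successful seed evaluations")

    for _gen in range(stage.n_generations):
        if stage.max_evaluations is not None and n_evaluations >= stage.max_evaluations:
            break
        population, decisions = de_generation(
            population, stage.targets, eval_with_frozen, surrogate, rng,
            F=stage.F, CR=stage.CR, eval_seed=seed,
        )
        for d in decisions:
            if d.evaluated is not None:
                archive.append(d.evaluated)
                n_evaluations += 1
                if not d.evaluated.failed:
                    since_retrain += 1
                    if (
                        not stage.use_oracle_surrogate
                        and since_retrain >= RETRAIN_EVERY
                    ):
                        _retrain(surrogate, archive)
                        n_retrains += 1
                        since_retrain = 0
                if stage.max_evaluations is not None and n_evaluations >= stage.max_evaluations:
                    break

    ok = [s for s in archive if not s.failed]
    best = min(ok, key=lambda s: s.cost)
    return StageResult(stage.name, archive, best, n_evaluations, n_retrains, frozen)


def _retrain(surrogate: LocalGaussianProcess, archive: list[EvaluatedSample]) -> None:
    ok = [s for s in archive if not s.failed]
    thetas = np.stack([s.theta.values for s in ok])
    props = {k: np.array([s.properties[k] for s in ok]) for k in ok[0].properties}
    surrogate.fit(thetas, props)


def run_campaign(stages: list[StageConfig], seed: int = 0) -> CampaignResult:
    """Execute a staged campaign, freezing earlier-stage optima into later stages."""
    if not stages:
        raise OptimizerError("empty stage list")
    results: list[StageResult] = []
    frozen: dict[str, float] = {}
    for k, stage in enumerate(stages):
        if stage.freeze_from_previous:
            if not results:
                raise OptimizerError("first stage cannot freeze from a previous one")
            prev_best = results[-1].best.theta.as_dict()
            prev_frozen = results[-1].frozen
            for name in stage.freeze_from_previous:
                if name in prev_best:
                    frozen[name] = prev_best[name]
                elif name in prev_frozen:
                    frozen[name] = prev_frozen[name]
                else:
                    raise OptimizerError(f"cannot freeze unknown parameter {name}")
        results.append(run_stage(stage, seed + k, frozen))
    return CampaignResult(results)


# -- archive IO and reporting ----------------------------------------------


def write_archive(archive: list[EvaluatedSample], path) -> None:
    """Append-only JSON-lines archive, one evaluated sample per line."""
    with open(path, "w") as fh:
        for s in archive:
            fh.write(json.dumps({
                "names": s.theta.names,
                "values": list(map(float, s.theta.values)),
                "bounds": [list(b) for b in s.theta.bounds],
                "properties": s.properties,
                "cost": None if math.isinf(s.cost) else s.cost,
                "provenance": s.provenance,
                "seed": s.seed,
                "failed": s.failed,
            }) + "\n")


def read_archive(path) -> list[EvaluatedSample]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(EvaluatedSample(
                theta=ParameterVector(d["names"], np.array(d["values"]),
                                      [tuple(b) for b in d["bounds"]]),
                properties=d["properties"],
                cost=math.inf if d["cost"] is None else d["cost"],
                provenance=d["provenance"],
                seed=d["seed"],
                failed=d["failed"],
            ))
    return out


def scaling_factor_histogram(
    archive: list[EvaluatedSample],
    parameter: str = "s",
    top_n: int | None = 25,
    bin_width: float = 0.01,
) -> dict[str, np.ndarray]:
    """Histogram of a parameter (by default the charge scaling factor) over
    the top-N archive samples ranked by cost."""
    ok = sorted((s for s in archive if not s.failed), key=lambda s: s.cost)
    if top_n is not None:
        ok = ok[:top_n]
    if not ok:
        raise OptimizerError("no successful samples in archive")
    vals = np.array([s.theta.as_dict()[parameter] for s in ok])
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return {"bin_edges": edges, "counts": counts, "values": vals}
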