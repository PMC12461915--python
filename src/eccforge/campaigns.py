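"""Prebuilt optimization campaigns: benchmarks and self-consistency harnesses.

Three standard experiments exercise the surrogate-assisted optimizer
end-to-end:

* :func:`rosenbrock_stage` — the classic 2-D valley test function behind
  the evaluator interface; convergence benchmark for DE + LGP + MH gate.
* :func:`planted_quadratic_stage` — a mock evaluator whose properties
  are analytic functions of θ with a known optimum; fast recovery check.
* :func:`toy_recovery_experiment` — the full self-consistent loop: the
  toy electrolyte simulator generates "experimental" targets at known
  (σ, ϵ, s), and a blind campaign must recover them.

The toy-recovery study conditions (composition, dielectric screening,
sampling length, target variances) are fixed here as the package's
standard desk-scale experiment; the target variances are the generator's
own property noise levels, measured once across independent seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import IonSpecies, ScaledForceField
from .optimizer import (
    PropertyTarget,
    PropertyTargetSet,
    StageConfig,
    StageResult,
    run_stage,
)
from .toysim import ToySystemSpec, ToyEvaluator

# -- analytic benchmarks ---------------------------------------------------


def rosenbrock_evaluator(theta: dict, seed: int) -> dict:
    """f(x, y) = (1−x)² + 100(y−x²)², reported as the single property "f"."""
    x, y = theta["x"], theta["y"]
    return {"f": (1.0 - x) ** 2 + 100.0 * (y - x * x) ** 2}


def rosenbrock_stage(max_evaluations: int = 5000, n_seed: int = 100) -> StageConfig:
    """DE+LGP benchmark stage on the 2-D Rosenbrock valley."""
    return StageConfig(
        name="rosenbrock",
        parameter_names=["x", "y"],
        bounds=[(-2.0, 2.0), (-1.0, 3.0)],
        start=[0.0, 1.0],
        targets=PropertyTargetSet([PropertyTarget("f", 0.0, 1.0)]),
        evaluator=rosenbrock_evaluator,
        n_seed=n_seed,
        n_generations=10 * max_evaluations,
        max_evaluations=max_evaluations,
    )


PLANTED_OPTIMUM = {"a": 0.3, "b": -0.7}


def planted_quadratic_evaluator(theta: dict, seed: int) -> dict:
    """Two analytic properties minimized-residual at the planted optimum."""
    a, b = theta["a"], theta["b"]
    a0, b0 = PLANTED_OPTIMUM["a"], PLANTED_OPTIMUM["b"]
    return {"p1": (a - a0) ** 2 + (b - b0) ** 2, "p2": a + b}


def planted_quadratic_stage(max_evaluations: int = 600) -> StageConfig:
    a0, b0 = PLANTED_OPTIMUM["a"], PLANTED_OPTIMUM["b"]
    targets = PropertyTargetSet(
        [PropertyTarget("p1", 0.0, 1e-4), PropertyTarget("p2", a0 + b0, 1e-4)]
    )
    return StageConfig(
        name="planted-quadratic",
        parameter_names=["a", "b"],
        bounds=[(-1.0, 1.0), (-1.0, 1.0)],
        start=[0.0, 0.0],
        targets=targets,
        evaluator=planted_quadratic_evaluator,
        n_seed=60,
        n_generations=10 * max_evaluations,
        max_evaluations=max_evaluations,
    )


# -- toy-electrolyte self-consistent recovery ------------------------------

#: True parameters planted in the recovery experiment (nm, kJ/mol, unitless).
RECOVERY_TRUTH = {"sigma_cation": 0.25, "epsilon_cation": 3.0, "s": 0.81}

#: Per-property target variances σ_i²: the square of the generator's
#: property noise measured across independent simulation seeds at the truth.
RECOVERY_SIGMA2 = {
    "pm_peak_r": 0.004**2,
    "pm_peak_g": 0.25**2,
    "ms_peak_r": 0.006**2,
    "ms_peak_g": 0.04**2,
    "cip": 0.03**2,
    "hn": 0.05**2,
    "u_mean": 0.014**2,
    "g_pm_0.30": 0.06**2,
    "g_ms_0.30": 0.05**2,
    "g_pm_0.34": 0.15**2,
    "g_ms_0.34": 0.07**2,
    "g_pm_0.38": 0.12**2,
    "g_ms_0.38": 0.07**2,
}


def recovery_forcefield(
    sigma_cation: float = RECOVERY_TRUTH["sigma_cation"],
    epsilon_cation: float = RECOVERY_TRUTH["epsilon_cation"],
    s: float = RECOVERY_TRUTH["s"],
) -> ScaledForceField:
    """The toy 1:1 electrolyte force field (cation M, anion X, LJ solvent W)."""
    return ScaledForceField(
        s,
        [
            IonSpecies("M", 1, sigma_cation, epsilon_cation),
            IonSpecies("X", -1, 0.38, 1.0),
            IonSpecies("W", 0, 0.30, 2.0),
        ],
    )


def recovery_template(mc_seed: int = 11) -> ToySystemSpec:
    """Standard desk-scale study conditions for the recovery experiment.

    A 1:1 electrolyte (5 ion pairs, 22 solvent particles) in a 1.3 nm box
    at 300 K with background dielectric 20 — concentrated enough that ion
    pairing responds to the charge scaling factor, dense enough that the
    cation–solvent shell pins σ and ϵ.
    """
    return ToySystemSpec(
        n_cations=5,
        n_anions=5,
        n_solvent=22,
        box_edge=1.3,
        temperature=300.0,
        forcefield=recovery_forcefield(),
        dielectric=20.0,
        mc_steps=12000,
        equilibration_steps=1000,
        sample_stride=40,
        seed=mc_seed,
    )


@dataclass
class RecoveryOutcome:
    truth: dict[str, float]
    recovered: dict[str, float]
    stage: StageResult

    @property
    def relative_errors(self) -> dict[str, float]:
        out = {}
        for k, v in self.truth.items():
            if k == "s":
                out[k] = abs(self.recovered[k] - v)  # absolute, per convention
            else:
                out[k] = abs(self.recovered[k] - v) / abs(v)
        return out


def toy_recovery_experiment(
    seed: int,
    max_evaluations: int = 320,
    mc_seed: int = 11,
) -> RecoveryOutcome:
    """Blind re-optimization of planted toy-electrolyte parameters.

    "Experimental" target values are generated by the toy simulator at
    the planted truth; the campaign then searches (σ_M, ϵ_M, s) from a
    deliberately wrong start.  The evaluator's internal simulation seed
    is fixed, so the cost has its exact global minimum at the truth up to
    the generator's frozen sampling noise.
    """
    evaluator = ToyEvaluator(template=recovery_template(mc_seed))
    mu = evaluator(RECOVERY_TRUTH, 0)
    targets = PropertyTargetSet(
        [PropertyTarget(k, mu[k], RECOVERY_SIGMA2[k]) for k in mu]
    )
    stage = StageConfig(
        name="toy-recovery",
        parameter_names=["sigma_cation", "epsilon_cation", "s"],
        bounds=[(0.20, 0.32), (1.5, 4.5), (0.70, 0.95)],
        start=[0.28, 2.2, 0.75],
        targets=targets,
        evaluator=evaluator,
        F=0.7,
        n_seed=24,
        n_generations=10 * max_evaluations,
        max_evaluations=max_evaluations,
        locality=40,
    )
    result = run_stage(stage, seed=seed)
    return RecoveryOutcome(
        truth=dict(RECOVERY_TRUTH),
        recovered=result.best.theta.as_dict(),
        stage=result,
    )
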