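"""Neutron diffraction with isotopic substitution (NDIS) difference functions.

A first-order difference isolates the correlations of one substituted
species M by subtracting total scattering patterns of two isotopically
distinct but chemically identical solutions.  In terms of partial RDFs,

    ΔG_M(r) = Σ_{α≠M} 2 c_M Δb_M c_α b_α (g_Mα(r) − 1)
              + c_M² (b_M² − b'_M²) (g_MM(r) − 1)

where c are atomic concentrations, b coherent scattering lengths (fm)
and Δb_M = b_M − b'_M the isotope contrast of the substituted species.
"Null water" is realized by an effective hydrogen scattering length of
zero (the H/D mixture whose average coherent b vanishes).

The reciprocal-space observable follows by the standard sine transform

    ΔS(Q) = 4πρ ∫ r² ΔG(r) sin(Qr)/(Qr) dr,

optionally damped by a Lorch window against truncation ripple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import RDFCurve

#: Coherent neutron scattering lengths (fm), Sears (1992) compilation,
#: natural abundance unless an isotope is named.  "Hnull" is the effective
#: zero-b hydrogen of a null-water mixture.
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "Hnull": 0.0,
    "O": 5.803,
    "Li": -1.90,
    "6Li": 2.00,
    "7Li": -2.22,
    "Na": 3.63,
    "K": 3.67,
    "39K": 3.74,
    "41K": 2.69,
    "Mg": 5.375,
    "25Mg": 3.62,
    "Ca": 4.70,
    "44Ca": 1.42,
    "Cl": 9.5770,
    "35Cl": 11.65,
    "37Cl": 3.08,
    "Br": 6.795,
    "I": 5.28,
}


class NeutronError(ValueError):
    pass


@dataclass(frozen=True)
class ScatteringSpec:
    """One species in the scattering composition."""

    species: str
    coherent_b: float  # fm
    concentration: float  # atoms per unit of composition

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise NeutronError(f"{self.species}: concentration must be >= 0")


@dataclass
class DifferenceFunction:
    """A weighted NDIS observable on an r- or Q-grid."""

    grid: np.ndarray  # nm (r) or nm⁻¹ (Q)
    values: np.ndarray
    space: str  # "r" or "Q"
    component_weights: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in ("r", "Q"):
            raise NeutronError("space must be 'r' or 'Q'")
        if self.grid.shape != self.values.shape:
            raise NeutronError("grid/values shape mismatch")

    @property
    def weight_sum(self) -> float:
        return float(sum(self.component_weights.values()))

    def _require_same_grid(self, other: "DifferenceFunction") -> None:
        if self.space != other.space or self.grid.shape != other.grid.shape or not np.allclose(
            self.grid, other.grid
        ):
            raise NeutronError("grid mismatch between difference functions")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def first_order_difference(
    partials: dict[tuple[str, str], RDFCurve],
    spec: list[ScatteringSpec],
    substituted: str,
    contrast_b: float | None = None,
    normalization: str = "per-substituted-atom",
) -> DifferenceFunction:
    """Build ΔG_M(r) for substituted species M from partial RDFs.

    ``contrast_b`` is Δb_M = b_M − b'_M (fm); when omitted it defaults to
    the species' own b (full substitution against a zero-b isotope mix).
    Weights are w_α = 2 c_M Δb_M c_α b_α for α ≠ M and
    c_M² (b_M² − (b_M − Δb_M)²) for the self pair; all are recorded in
    ``component_weights``.  With ``normalization="per-substituted-atom"``
    the weighted sum is divided by c_M.
    """
    by_name = {s.species: s for s in spec}
    if substituted not in by_name:
        raise NeutronError(f"substituted species {substituted} absent from spec")
    sub = by_name[substituted]
    db = contrast_b if contrast_b is not None else sub.coherent_b
    lookup = {_pair_key(*k): v for k, v in partials.items()}

    grid = None
    total = None
    weights: dict[str, float] = {}
    for other in spec:
        key = _pair_key(substituted, other.species)
        if other.species == substituted:
            b_prime = sub.coherent_b - db
            w = sub.concentration**2 * (sub.coherent_b**2 - b_prime**2)
        else:
            w = 2.0 * sub.concentration * db * other.concentration * other.coherent_b
        if w == 0.0:
            continue
        if key not in lookup:
            raise NeutronError(f"missing partial RDF for pair {key}")
        curve = lookup[key]
        r = curve.r
        if grid is None:
            grid = r
            total = np.zeros_like(r)
        elif r.shape != grid.shape or not np.allclose(r, grid):
            raise NeutronError(f"partial {key} is on a different r-grid")
        total += w * (curve.g - 1.0)
        weights["-".join(key)] = w
    if grid is None:
        raise NeutronError("no nonzero-weight partials")
    if normalization == "per-substituted-atom":
        total = total / sub.concentration
        weights = {k: w / sub.concentration for k, w in weights.items()}
    elif normalization != "raw":
        raise NeutronError(f"unknown normalization {normalization}")
    return DifferenceFunction(
        grid=grid,
        values=total,
        space="r",
        component_weights=weights,
        metadata={
            "substituted": substituted,
            "contrast_b_fm": db,
            "normalization": normalization,
        },
    )


def lorch_window(r: np.ndarray, r_max: float) -> np.ndarray:
    """Lorch modification function sin(πr/r_max)/(πr/r_max)."""
    x = np.pi * r / r_max
    return np.where(x == 0, 1.0, np.sin(np.where(x == 0, 1.0, x)) / np.where(x == 0, 1.0, x))


def to_q_space(
    dG: DifferenceFunction,
    rho: float,
    q_grid: np.ndarray,
    window: str = "none",
) -> DifferenceFunction:
    """ΔS(Q) = 4πρ ∫ r² ΔG(r) sinc(Qr) dr on a uniform r-grid (trapezoid rule).

    ``rho`` is the reference number density (nm⁻³); Q in nm⁻¹.  The Q = 0
    limit uses sinc → 1.  ``window="lorch"`` applies the Lorch window.
    """
    if dG.space != "r":
        raise NeutronError("input must be an r-space difference function")
    r = dG.grid
    dr = np.diff(r)
    if not np.allclose(dr, dr[0]):
        raise NeutronError("non-uniform r-grid")
    vals = dG.values.copy()
    if window == "lorch":
        vals = vals * lorch_window(r, r[-1])
    elif window != "none":
        raise NeutronError(f"unknown window {window}")
    q = np.asarray(q_grid, dtype=float)
    qr = np.outer(q, r)
    sinc = np.where(qr == 0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
    integrand = (r**2 * vals)[None, :] * sinc
    s = 4.0 * np.pi * rho * np.trapezoid(integrand, r, axis=1)
    return DifferenceFunction(
        grid=q,
        values=s,
        space="Q",
        component_weights=dict(dG.component_weights),
        metadata={**dG.metadata, "window": window, "rho": rho},
    )


def to_r_space(
    dS: DifferenceFunction,
    rho: float,
    r_grid: np.ndarray,
) -> DifferenceFunction:
    """Inverse sine transform ΔG(r) = (1/(2π²ρ)) ∫ Q² ΔS(Q) sinc(Qr) dQ."""
    if dS.space != "Q":
        raise NeutronError("input must be a Q-space difference function")
    q = dS.grid
    dq = np.diff(q)
    if not np.allclose(dq, dq[0]):
        raise NeutronError("non-uniform Q-grid")
    r = np.asarray(r_grid, dtype=float)
    qr = np.outer(r, q)
    sinc = np.where(qr == 0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
    integrand = (q**2 * dS.values)[None, :] * sinc
    g = np.trapezoid(integrand, q, axis=1) / (2.0 * np.pi**2 * rho)
    return DifferenceFunction(
        grid=r,
        values=g,
        space="r",
        component_weights=dict(dS.component_weights),
        metadata={**dS.metadata, "inverse": True},
    )


def cation_difference(
    dG_a: DifferenceFunction, dG_b: DifferenceFunction
) -> DifferenceFunction:
    """Pointwise difference dG_a − dG_b (e.g. ΔG_NaK = G_K − G_Na with a=K).

    Metadata records minuend and subtrahend; order swap negates the result.
    """
    dG_a._require_same_grid(dG_b)
    return DifferenceFunction(
        grid=dG_a.grid.copy(),
        values=dG_a.values - dG_b.values,
        space=dG_a.space,
        component_weights={
            **{f"+{k}": v for k, v in dG_a.component_weights.items()},
            **{f"-{k}": v for k, v in dG_b.component_weights.items()},
        },
        metadata={
            "minuend": dG_a.metadata.get("substituted"),
            "subtrahend": dG_b.metadata.get("substituted"),
        },
    )


def null_water_adjust(
    dG: DifferenceFunction, oo_partial: RDFCurve, weight: float
) -> DifferenceFunction:
    """Subtract weight·(g_OO(r) − 1), the pure null-water O–O correlation."""
    if dG.space != "r":
        raise NeutronError("null-water adjustment applies in r-space")
    r = oo_partial.r
    if r.shape != dG.grid.shape or not np.allclose(r, dG.grid):
        raise NeutronError("grid mismatch between difference function and O-O partial")
    return DifferenceFunction(
        grid=dG.grid.copy(),
        values=dG.values - weight * (oo_partial.g - 1.0),
        space="r",
        component_weights={**dG.component_weights, "OO-adjustment": -weight},
        metadata={**dG.metadata, "null_water_weight": weight},
    )
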