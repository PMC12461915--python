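"""Scaled-charge ion force fields.

A :class:`ScaledForceField` is a set of ionic species with formal charges
and Lennard-Jones self terms, plus a global charge scaling factor ``s``
implementing the electronic continuum correction (ECC): every effective
charge is ``s`` times the formal charge.  Cross LJ terms follow the
Lorentz–Berthelot combination rules unless an explicit pair override is
registered (used for anion–water-oxygen pairs).

Serialization targets a GROMACS ``.itp``-style nonbonded dialect
(``[ atomtypes ]`` / ``[ nonbond_params ]``, combination rule 2) and a
canonical JSON form; write→read round-trips are bit-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping


class ForceFieldError(ValueError):
    """Invalid force-field configuration (duplicate overrides, bad bounds...)."""


@dataclass(frozen=True)
class IonSpecies:
    """One atomic species: formal charge (e) and LJ self terms (nm, kJ/mol)."""

    name: str
    formal_charge: int
    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ForceFieldError(f"{self.name}: sigma must be > 0, got {self.sigma}")
        if self.epsilon < 0:
            raise ForceFieldError(f"{self.name}: epsilon must be >= 0, got {self.epsilon}")


@dataclass(frozen=True)
class PairOverride:
    """Explicit cross LJ term for one unordered species pair (nm, kJ/mol).

    The pair is stored order-normalized (lexicographically), so overrides
    are symmetric under (a, b) swap by construction.
    """

    species_a: str
    species_b: str
    sigma_ab: float
    epsilon_ab: float

    def __post_init__(self) -> None:
        if self.species_a > self.species_b:
            a, b = self.species_b, self.species_a
            object.__setattr__(self, "species_a", a)
            object.__setattr__(self, "species_b", b)

    @property
    def key(self) -> tuple[str, str]:
        """Order-normalized pair key."""
        return (self.species_a, self.species_b)


@dataclass
class ScaledForceField:
    """A charge-scaled ion force field (ECC semantics).

    Parameters
    ----------
    scaling_factor
        Dimensionless charge scaling s in (0, 1]; effective charge of every
        species is ``s * formal_charge``.
    species
        Species list; names must be unique.
    overrides
        Explicit pair LJ terms; at most one per unordered pair.
    """

    scaling_factor: float
    species: list[IonSpecies] = field(default_factory=list)
    overrides: list[PairOverride] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.scaling_factor <= 1.0):
            raise ForceFieldError(
                f"scaling factor must be in (0, 1], got {self.scaling_factor}"
            )
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ForceFieldError("duplicate species names")
        seen: dict[tuple[str, str], PairOverride] = {}
        for ov in self.overrides:
            if ov.key in seen:
                prev = seen[ov.key]
                if (prev.sigma_ab, prev.epsilon_ab) != (ov.sigma_ab, ov.epsilon_ab):
                    raise ForceFieldError(f"conflicting overrides for pair {ov.key}")
                raise ForceFieldError(f"duplicate override for pair {ov.key}")
            seen[ov.key] = ov
        self.overrides = sorted(self.overrides, key=lambda o: o.key)

    # -- queries ---------------------------------------------------------

    def species_by_name(self, name: str) -> IonSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def scaled_charges(self) -> dict[str, float]:
        """Effective charge (e) per species: ``s * formal_charge`` exactly."""
        return {sp.name: self.scaling_factor * sp.formal_charge for sp in self.species}

    def lj_pair(self, a: str, b: str) -> tuple[float, float]:
        """(σ_ab, ϵ_ab) for a named pair, honouring overrides."""
        return combine_lj(self.species_by_name(a), self.species_by_name(b), self.overrides)

    def residual_charge(self, composition: Mapping[str, int]) -> float:
        """Total effective charge (e) of a composition {species: count}."""
        q = self.scaled_charges()
        return sum(q[name] * count for name, count in composition.items())


def combine_lj(
    a: IonSpecies, b: IonSpecies, overrides: Iterable[PairOverride] = ()
) -> tuple[float, float]:
    """Cross LJ parameters by Lorentz–Berthelot rules, overrides taking precedence.

    σ_ab = (σ_aa + σ_bb)/2 and ϵ_ab = sqrt(ϵ_aa·ϵ_bb) unless the unordered
    pair (a, b) has an explicit override.
    """
    key = tuple(sorted((a.name, b.name)))
    matches = [ov for ov in overrides if ov.key == key]
    if len(matches) > 1:
        vals = {(ov.sigma_ab, ov.epsilon_ab) for ov in matches}
        if len(vals) > 1:
            raise ForceFieldError(f"conflicting overrides for pair {key}")
    if matches:
        ov = matches[0]
        return ov.sigma_ab, ov.epsilon_ab
    return 0.5 * (a.sigma + b.sigma), math.sqrt(a.epsilon * b.epsilon)


def scaled_charges(ff: ScaledForceField) -> dict[str, float]:
    """Functional alias for :meth:`ScaledForceField.scaled_charges`."""
    return ff.scaled_charges()


# -- JSON canonical form ---------------------------------------------------


def to_json_dict(ff: ScaledForceField) -> dict:
    return {
        "scaling_factor": ff.scaling_factor,
        "species": [
            {
                "name": sp.name,
                "formal_charge": sp.formal_charge,
                "sigma": sp.sigma,
                "epsilon": sp.epsilon,
            }
            for sp in ff.species
        ],
        "overrides": [
            {
                "species_a": ov.species_a,
                "species_b": ov.species_b,
                "sigma_ab": ov.sigma_ab,
                "epsilon_ab": ov.epsilon_ab,
            }
            for ov in ff.overrides
        ],
    }


def from_json_dict(d: Mapping) -> ScaledForceField:
    return ScaledForceField(
        scaling_factor=d["scaling_factor"],
        species=[IonSpecies(**sp) for sp in d["species"]],
        overrides=[PairOverride(**ov) for ov in d.get("overrides", [])],
    )


def load_json(path) -> ScaledForceField:
    with open(path) as fh:
        return from_json_dict(json.load(fh))


def save_json(ff: ScaledForceField, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_json_dict(ff), fh, indent=1)
        fh.write("\n")


def load_eccions81() -> ScaledForceField:
    """Bundled ECCions81-like fixture (synthetic stand-in).

    The charge row is the published one (s = 0.81: monovalents ±0.81 e,
    divalents +1.62 e); the LJ σ/ϵ values are synthetic, literature-plausible
    placeholders, since the typeset parameter table is not redistributed here.
    """
    ref = resources.files("eccforge.data").joinpath("eccions81_synthetic.json")
    return from_json_dict(json.loads(ref.read_text()))


# -- GROMACS-dialect writer / reader ---------------------------------------

_F = "{:.17g}".format  # bit-exact float round-trip


def write_nonbonded(ff: ScaledForceField, composition: Mapping[str, int] | None = None) -> str:
    """Emit a GROMACS-dialect nonbonded block for the force field.

    ``composition`` {species: count}, when given, is validated to be
    charge-neutral under the *effective* (scaled) charges; a non-neutral
    composition raises naming the residual charge.  Pairs with overrides are
    emitted explicitly in ``[ nonbond_params ]`` so downstream engines never
    re-derive them; everything else is left to combination rule 2
    (Lorentz–Berthelot).
    """
    if composition is not None:
        residual = ff.residual_charge(composition)
        if abs(residual) > 1e-12:
            raise ForceFieldError(
                f"composition is not charge-neutral: residual {residual:+.6g} e"
            )
    lines = [
        "; eccforge nonbonded parameters (charges scaled by "
        f"{_F(ff.scaling_factor)})",
        "[ defaults ]",
        "; nbfunc comb-rule gen-pairs",
        "1 2 no",
        "",
        "[ atomtypes ]",
        "; name charge sigma epsilon",
    ]
    charges = ff.scaled_charges()
    for sp in ff.species:
        lines.append(
            f"{sp.name} {_F(charges[sp.name])} {_F(sp.sigma)} {_F(sp.epsilon)} "
            f"; formal {sp.formal_charge:+d}"
        )
    if ff.overrides:
        lines += ["", "[ nonbond_params ]", "; ai aj func sigma epsilon"]
        for ov in sorted(ff.overrides, key=lambda o: o.key):
            a, b = ov.key
            lines.append(f"{a} {b} 1 {_F(ov.sigma_ab)} {_F(ov.epsilon_ab)}")
    return "\n".join(lines) + "\n"


def read_nonbonded(text: str) -> ScaledForceField:
    """Parse the dialect emitted by :func:`write_nonbonded` (round-trip inverse)."""
    scaling = None
    species: list[IonSpecies] = []
    overrides: list[PairOverride] = []
    section = None
    for raw in text.splitlines():
        if raw.startswith("; eccforge nonbonded parameters"):
            scaling = float(raw.split("scaled by")[1].strip(" )"))
            continue
        line = raw.split(";")[0].strip()
        comment = raw.split(";", 1)[1] if ";" in raw else ""
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        fields = line.split()
        if section == "atomtypes":
            name, charge, sigma, epsilon = fields[:4]
            formal = int(comment.split("formal")[1]) if "formal" in comment else 0
            species.append(
                IonSpecies(name=name, formal_charge=formal, sigma=float(sigma), epsilon=float(epsilon))
            )
            # consistency: charge column must equal s * formal
        elif section == "nonbond_params":
            a, b, _func, sigma, epsilon = fields[:5]
            overrides.append(
                PairOverride(species_a=a, species_b=b, sigma_ab=float(sigma), epsilon_ab=float(epsilon))
            )
    if scaling is None:
        raise ForceFieldError("missing scaling-factor header line")
    return ScaledForceField(scaling_factor=scaling, species=species, overrides=overrides)


# -- ECC closed-form identities --------------------------------------------


def ecc_scaling_factor(epsilon_electronic: float) -> float:
    """ECC charge scaling factor 1/sqrt(ε_el).

    For water's high-frequency dielectric constant ε_el ≈ 1.78 this gives
    ≈ 0.75, the fully consistent ECC scaling.
    """
    if epsilon_electronic <= 0:
        raise ValueError("electronic dielectric constant must be positive")
    return 1.0 / math.sqrt(epsilon_electronic)


def effective_dielectric(epsilon_water: float, scaling_factor: float) -> float:
    """Effective dielectric constant ε_water / s² implied by scaling s.

    A scaling of 0.81 on top of a water model with ε = 45 corresponds to an
    effective dielectric constant of ≈ 70.
    """
    if scaling_factor <= 0:
        raise ValueError("scaling factor must be positive")
    return epsilon_water / scaling_factor**2
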