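"""Desk-scale toy electrolyte simulator and synthetic-data generators.

The Monte-Carlo engine samples an NVT Lennard-Jones + scaled-Coulomb
fluid (solvent as a neutral LJ site) with reaction-field or
truncated-shifted electrostatics under the Metropolis criterion.  It is
a few hundred lines of deterministic, seedable code meant to exercise
the analysis and optimization machinery at desk scale — it makes no
physics claims about production PME molecular dynamics.

Also here: Brownian trajectories (known diffusion coefficient),
cosine-flow velocity frames (known viscosity) and analytic RDF curves
(closed-form shell integrals), each carrying its generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numba import njit
from scipy.special import erf

from .constants import KB_KJ_PER_MOL_K
from .forcefield import ScaledForceField
from .structure import RDFCurve, compute_rdf
from .trajectory import Frame, Trajectory

KE_KJ_NM = 138.935458  # Coulomb constant, kJ/mol · nm / e²
DESK_SCALE_LIMIT = 1000


class ToySimError(RuntimeError):
    pass


@dataclass
class SyntheticTruth:
    """Provenance record for generated data: generator name, true parameters, seed."""

    generator: str
    parameters: dict
    seed: int


# -- Metropolis Monte-Carlo engine -----------------------------------------


@dataclass
class ToySystemSpec:
    """Composition and sampling settings for one toy electrolyte run."""

    n_cations: int
    n_anions: int
    n_solvent: int
    box_edge: float  # nm
    temperature: float  # K
    forcefield: ScaledForceField
    cation: str = "M"
    anion: str = "X"
    solvent: str = "W"
    electrostatics: str = "reaction-field"  # or "truncated-shifted"
    dielectric: float = 40.0  # background screening (primitive-model solvent continuum)
    cutoff: float | None = None  # nm, default min(1.0, L/2)
    mc_steps: int = 2000  # production sweeps
    equilibration_steps: int = 500
    sample_stride: int = 20  # sweeps between stored frames
    max_displacement: float = 0.04  # nm, starting value; auto-tuned
    seed: int = 0
    allow_large: bool = False

    def __post_init__(self) -> None:
        n = self.n_cations + self.n_anions + self.n_solvent
        if n > DESK_SCALE_LIMIT and not self.allow_large:
            raise ToySimError(
                f"{n} particles exceeds the desk-scale guard of {DESK_SCALE_LIMIT}"
            )
        if self.electrostatics not in ("reaction-field", "truncated-shifted"):
            raise ToySimError(f"unknown electrostatics {self.electrostatics}")
        if self.dielectric <= 0:
            raise ToySimError("background dielectric must be positive")
        q = self.forcefield.scaled_charges()
        residual = (
            self.n_cations * q[self.cation]
            + self.n_anions * q[self.anion]
            + self.n_solvent * q.get(self.solvent, 0.0)
        )
        if abs(residual) > 1e-9:
            raise ToySimError(f"composition not charge-neutral: residual {residual:+.4g} e")

    @property
    def species_labels(self) -> list[str]:
        return (
            [self.cation] * self.n_cations
            + [self.anion] * self.n_anions
            + [self.solvent] * self.n_solvent
        )


@njit(cache=True, fastmath=True)
def _pair_energy(dx, dy, dz, box, s2, e4, qq, rc2, krf, crf, use_rf, ushift):
    # coordinates live in [0, box), so one box shift suffices
    hbox = 0.5 * box
    if dx > hbox:
        dx -= box
    elif dx < -hbox:
        dx += box
    if dy > hbox:
        dy -= box
    elif dy < -hbox:
        dy += box
    if dz > hbox:
        dz -= box
    elif dz < -hbox:
        dz += box
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc2 or r2 == 0.0:
        return 0.0
    sr2 = s2 / r2
    sr6 = sr2 * sr2 * sr2
    u = e4 * (sr6 * sr6 - sr6) - ushift
    if qq != 0.0:
        r = math.sqrt(r2)
        if use_rf:
            u += qq * (1.0 / r + krf * r2 - crf)
        else:
            u += qq * (1.0 / r - 1.0 / math.sqrt(rc2))
    return u


@njit(cache=True, fastmath=True)
def _site_energy(coords, i, xi, yi, zi, sp, sig2, eps4, qprod, box, rc2, krf, crf, use_rf, ushift):
    e = 0.0
    si = sp[i]
    for j in range(coords.shape[0]):
        if j == i:
            continue
        sj = sp[j]
        e += _pair_energy(
            xi - coords[j, 0], yi - coords[j, 1], zi - coords[j, 2], box,
            sig2[si, sj], eps4[si, sj], qprod[si, sj], rc2, krf, crf, use_rf,
            ushift[si, sj],
        )
    return e


@njit(cache=True, fastmath=True)
def _mc_block(coords, sp, sig2, eps4, qprod, box, beta, rc2, krf, crf, use_rf,
              ushift, pidx, disp, urand, frames, stride_moves, store, e_total):
    n_acc = 0
    fcount = 0
    e_sum = 0.0
    for m in range(pidx.size):
        i = pidx[m]
        xo, yo, zo = coords[i, 0], coords[i, 1], coords[i, 2]
        xn = (xo + disp[m, 0]) % box
        yn = (yo + disp[m, 1]) % box
        zn = (zo + disp[m, 2]) % box
        e_old = _site_energy(coords, i, xo, yo, zo, sp, sig2, eps4, qprod, box,
                             rc2, krf, crf, use_rf, ushift)
        e_new = _site_energy(coords, i, xn, yn, zn, sp, sig2, eps4, qprod, box,
                             rc2, krf, crf, use_rf, ushift)
        dE = e_new - e_old
        if dE <= 0.0 or urand[m] < math.exp(-beta * dE):
            coords[i, 0] = xn
            coords[i, 1] = yn
            coords[i, 2] = zn
            n_acc += 1
            e_total += dE
        e_sum += e_total
        if store and (m + 1) % stride_moves == 0 and fcount < frames.shape[0]:
            frames[fcount] = coords
            fcount += 1
    return n_acc, fcount, e_total, e_sum / pidx.size


@njit(cache=True, fastmath=True)
def _total_energy(coords, sp, sig2, eps4, qprod, box, rc2, krf, crf, use_rf, ushift):
    e = 0.0
    n = coords.shape[0]
    for i in range(n - 1):
        si = sp[i]
        for j in range(i + 1, n):
            sj = sp[j]
            e += _pair_energy(
                coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1],
                coords[i, 2] - coords[j, 2], box, sig2[si, sj], eps4[si, sj],
                qprod[si, sj], rc2, krf, crf, use_rf, ushift[si, sj],
            )
    return e


def potential_energy(traj: Trajectory, spec: ToySystemSpec) -> float:
    """Mean potential energy per particle (kJ/mol) over the trajectory frames."""
    _labels, sig2, eps4, qprod = _build_tables(spec)
    sp = np.array(
        [0] * spec.n_cations + [1] * spec.n_anions + [2] * spec.n_solvent, dtype=np.int64
    )
    rc = spec.cutoff if spec.cutoff is not None else min(1.0, spec.box_edge / 2)
    use_rf = spec.electrostatics == "reaction-field"
    krf = 1.0 / (2.0 * rc**3)
    crf = 3.0 / (2.0 * rc)
    sr6 = (sig2 / rc**2) ** 3
    ushift = eps4 * (sr6**2 - sr6)
    total = 0.0
    for fr in traj.frames:
        total += _total_energy(
            np.ascontiguousarray(fr.coordinates), sp, sig2, eps4, qprod,
            fr.box_edge, rc**2, krf, crf, use_rf, ushift,
        )
    return total / (len(traj.frames) * sp.size)


def _build_tables(spec: ToySystemSpec):
    ff = spec.forcefield
    labels = [spec.cation, spec.anion, spec.solvent]
    n_sp = len(labels)
    q = ff.scaled_charges()
    sig2 = np.zeros((n_sp, n_sp))
    eps4 = np.zeros((n_sp, n_sp))
    qprod = np.zeros((n_sp, n_sp))
    for a in range(n_sp):
        for b in range(n_sp):
            s_ab, e_ab = ff.lj_pair(labels[a], labels[b])
            sig2[a, b] = s_ab**2
            eps4[a, b] = 4.0 * e_ab
            qprod[a, b] = (
                KE_KJ_NM * q.get(labels[a], 0.0) * q.get(labels[b], 0.0) / spec.dielectric
            )
    return labels, sig2, eps4, qprod


def mc_sample(spec: ToySystemSpec) -> tuple[Trajectory, dict]:
    """Metropolis NVT sampling of the toy electrolyte.

    Returns decorrelated frames (one per ``sample_stride`` sweeps) and an
    info dict with acceptance ratio and the tuned step size.  Raises when
    the acceptance ratio stays below 1% after step-size auto-tuning.
    Bit-reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels, sig2, eps4, qprod = _build_tables(spec)
    sp = np.array(
        [0] * spec.n_cations + [1] * spec.n_anions + [2] * spec.n_solvent, dtype=np.int64
    )
    n = sp.size
    L = spec.box_edge
    rc = spec.cutoff if spec.cutoff is not None else min(1.0, L / 2)
    if rc > L / 2 + 1e-12:
        raise ToySimError("cutoff exceeds L/2")
    use_rf = spec.electrostatics == "reaction-field"
    krf = 1.0 / (2.0 * rc**3)  # conducting reaction field
    crf = 3.0 / (2.0 * rc)
    # LJ truncated-and-shifted: subtract u_LJ(rc) per pair type
    sr2 = sig2 / rc**2
    sr6 = sr2**3
    ushift = eps4 * (sr6**2 - sr6)
    beta = 1.0 / (KB_KJ_PER_MOL_K * spec.temperature)

    # initial configuration: jittered cubic lattice, shuffled species assignment
    m_side = int(math.ceil(n ** (1.0 / 3.0)))
    grid = (np.indices((m_side,) * 3).reshape(3, -1).T + 0.5) * (L / m_side)
    order = rng.permutation(grid.shape[0])[:n]
    coords = np.ascontiguousarray(grid[order]) + rng.normal(0, 0.01 * L / m_side, (n, 3))
    coords %= L

    step = spec.max_displacement
    moves_per_sweep = n
    e_state = [
        float(
            _total_energy(coords, sp, sig2, eps4, qprod, L, rc**2, krf, crf,
                          use_rf, ushift)
        )
    ]

    def run_block(n_sweeps: int, step: float, store: bool, n_frames: int):
        n_moves = n_sweeps * moves_per_sweep
        pidx = rng.integers(0, n, size=n_moves)
        disp = rng.uniform(-step, step, size=(n_moves, 3))
        urand = rng.random(n_moves)
        frames = np.empty((n_frames if store else 1, n, 3))
        stride_moves = spec.sample_stride * moves_per_sweep
        n_acc, fcount, e_total, e_mean = _mc_block(
            coords, sp, sig2, eps4, qprod, L, beta, rc**2, krf, crf, use_rf,
            ushift, pidx, disp, urand, frames, stride_moves, store, e_state[0],
        )
        e_state[0] = e_total
        return n_acc / n_moves, frames[:fcount], e_mean

    # equilibration with step-size tuning toward ~40% acceptance
    n_tune = 8
    eq_block = max(1, spec.equilibration_steps // n_tune)
    acc = 0.0
    for _ in range(n_tune):
        acc, _f, _e = run_block(eq_block, step, False, 0)
        if acc > 0.5:
            step = min(step * 1.25, L / 4)
        elif acc < 0.3:
            step *= 0.8
    if acc < 0.01:
        raise ToySimError(f"acceptance ratio {acc:.3%} below 1% after auto-tuning")

    n_frames = spec.mc_steps // spec.sample_stride
    acc, stored, e_mean = run_block(spec.mc_steps, step, True, n_frames)
    if acc < 0.01:
        raise ToySimError(f"acceptance ratio {acc:.3%} below 1% in production")
    frames = [Frame(stored[k].copy(), L) for k in range(stored.shape[0])]
    traj = Trajectory(frames=frames, species=spec.species_labels)
    return traj, {
        "acceptance": acc,
        "step": step,
        "n_frames": len(frames),
        "u_mean_per_particle": e_mean / n,
    }


# -- toy evaluator for the optimizer ---------------------------------------


def _interp_peak(curve: RDFCurve, r_lo: float = 0.0) -> tuple[float, float]:
    """Position and height of the highest peak, parabolic sub-bin interpolation."""
    r, g = curve.r, curve.g
    mask = r >= r_lo
    ri, gi = r[mask], g[mask]
    k = int(np.argmax(gi))
    if 0 < k < gi.size - 1:
        y0, y1, y2 = gi[k - 1], gi[k], gi[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        dr = ri[1] - ri[0]
        return float(ri[k] + delta * dr), float(y1 - 0.25 * (y0 - y2) * delta)
    return float(ri[k]), float(gi[k])


@dataclass
class ToyEvaluator:
    """Maps optimizer parameter vectors onto toy-electrolyte properties.

    Recognized parameter names: ``sigma_cation``, ``epsilon_cation``,
    ``sigma_anion``, ``epsilon_anion``, ``s`` (charge scaling factor);
    unrecognized names raise.  Properties returned: first-peak position
    and height of the cation–anion and cation–solvent RDFs, the
    contact-ion-pair count (cation–anion shell integral), and the mean
    potential energy per particle (a pressure-like thermodynamic target
    standing in for NPT densities, which are out of scope for the NVT toy
    engine).  The internal simulation seed is fixed by the template spec,
    so the map θ → properties is deterministic and the planted-truth cost
    has its global minimum exactly at the generating parameters.
    """

    template: ToySystemSpec
    #: optional second state point (e.g. a dilute, solvent-dominated system)
    #: whose properties are emitted with a ``d_`` prefix; a two-system target
    #: set breaks parameter trade-offs a single composition cannot resolve,
    #: mirroring multi-solution staged optimization protocols
    dilute_template: ToySystemSpec | None = None
    bin_width: float = 0.01  # nm; toy-scale RDF resolution
    cip_radius: float = 0.40  # nm; fixed shell radius keeps CIP smooth in θ
    hn_radius: float = 0.42  # nm; cation-solvent first-shell radius
    #: fixed radii (nm) where RDF values are reported as shape targets
    probe_radii: tuple[float, ...] = (0.30, 0.34, 0.38)
    _known = ("sigma_cation", "epsilon_cation", "sigma_anion", "epsilon_anion", "s")

    def forcefield_for(self, theta: Mapping[str, float]) -> ScaledForceField:
        from .forcefield import IonSpecies, PairOverride

        base = self.template.forcefield
        unknown = set(theta) - set(self._known)
        if unknown:
            raise ToySimError(f"unknown parameters {sorted(unknown)}")
        by_name = {sp.name: sp for sp in base.species}
        cat = by_name[self.template.cation]
        an = by_name[self.template.anion]
        species = []
        for sp in base.species:
            sigma, epsilon = sp.sigma, sp.epsilon
            if sp.name == cat.name:
                sigma = float(theta.get("sigma_cation", sigma))
                epsilon = float(theta.get("epsilon_cation", epsilon))
            elif sp.name == an.name:
                sigma = float(theta.get("sigma_anion", sigma))
                epsilon = float(theta.get("epsilon_anion", epsilon))
            species.append(IonSpecies(sp.name, sp.formal_charge, sigma, epsilon))
        return ScaledForceField(
            scaling_factor=float(theta.get("s", base.scaling_factor)),
            species=species,
            overrides=list(base.overrides),
        )

    def __call__(self, theta: Mapping[str, float], seed: int) -> dict[str, float]:
        props = self._evaluate_system(self.template, theta)
        if self.dilute_template is not None:
            dilute = self._evaluate_system(self.dilute_template, theta, skip_pm=True)
            props.update({f"d_{k}": v for k, v in dilute.items()})
        return props

    def _evaluate_system(
        self, template: ToySystemSpec, theta: Mapping[str, float], skip_pm: bool = False
    ) -> dict[str, float]:
        from dataclasses import replace

        spec = replace(template, forcefield=self.forcefield_for(theta),
                       seed=template.seed)
        traj, info = mc_sample(spec)
        r_max = spec.box_edge / 2
        g_pm = compute_rdf(traj, (spec.cation, spec.anion), self.bin_width, r_max)
        g_ms = compute_rdf(traj, (spec.cation, spec.solvent), self.bin_width, r_max)
        pm_r, pm_g = _interp_peak(g_pm)
        ms_r, ms_g = _interp_peak(g_ms)
        from .structure import shell_integral

        cip = shell_integral(g_pm, g_pm.rho_beta, min(self.cip_radius, r_max))
        hn = shell_integral(g_ms, g_ms.rho_beta, min(self.hn_radius, r_max))
        props = {
            "ms_peak_r": ms_r,
            "ms_peak_g": ms_g,
            "hn": hn,
            # sweep-averaged running energy from the engine: lower variance
            # than re-summing the stored (decorrelated) frames
            "u_mean": info["u_mean_per_particle"],
        }
        if not skip_pm:
            props.update({"pm_peak_r": pm_r, "pm_peak_g": pm_g, "cip": cip})
        for rr in self.probe_radii:
            if not skip_pm:
                props[f"g_pm_{rr:.2f}"] = float(np.interp(rr, g_pm.r, g_pm.g))
            props[f"g_ms_{rr:.2f}"] = float(np.interp(rr, g_ms.r, g_ms.g))
        return props


# -- Brownian trajectories -------------------------------------------------


def brownian_trajectory(
    n_particles: int,
    D_true: float,
    dt: float,
    n_steps: int,
    box: float,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticTruth]:
    """Unwrapped independent Brownian paths with per-step variance 2·D·dt per dimension."""
    if D_true < 0:
        raise ToySimError("D_true must be non-negative")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, box, size=(n_particles, 3))
    steps = rng.normal(0.0, math.sqrt(2.0 * D_true * dt), size=(n_steps - 1, n_particles, 3))
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    traj = Trajectory(
        frames=[Frame(pos[k], box) for k in range(n_steps)],
        species=["B"] * n_particles,
    )
    truth = SyntheticTruth("brownian", {"D_true": D_true, "dt": dt}, seed)
    return traj, truth


# -- cosine-flow frames ----------------------------------------------------


def cosine_flow_frames(
    L: float,
    v_amp: float,
    rho: float,
    noise_sigma: float,
    n_frames: int,
    n_particles: int = 200,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticTruth]:
    """Velocity-bearing frames with v_x = v_amp·cos(2πz/L) plus Gaussian noise.

    ``rho`` (kg/m³) is recorded in the truth for the closed-form
    viscosity η = ρ·a·(L/2π)²/v_amp.
    """
    if v_amp <= 0:
        raise ToySimError("v_amp must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        coords = rng.uniform(0, L, size=(n_particles, 3))
        vel = rng.normal(0.0, noise_sigma, size=(n_particles, 3))
        vel[:, 0] += v_amp * np.cos(2.0 * np.pi * coords[:, 2] / L)
        frames.append(Frame(coords, L, velocities=vel))
    traj = Trajectory(frames=frames, species=["W"] * n_particles)
    truth = SyntheticTruth(
        "cosine-flow", {"v_amp": v_amp, "rho": rho, "noise_sigma": noise_sigma}, seed
    )
    return traj, truth


# -- analytic RDF curves ---------------------------------------------------


@dataclass
class GaussianPeak:
    amplitude: float
    center: float  # nm
    width: float  # nm


def analytic_rdf(
    form: str,
    grid: np.ndarray,
    rho: float,
    peaks: list[GaussianPeak] = (),
    step_height: float = 1.0,
    step_r: float = 0.3,
    species_pair: tuple[str, str] = ("A", "B"),
    baseline: float = 1.0,
) -> tuple[RDFCurve, SyntheticTruth]:
    """Exact RDF curves with closed-form shell integrals.

    ``form="step"``: g = step_height on [0, step_r], 0 beyond (shell
    integral to step_r: (4/3)π ρ h r³).  ``form="gaussian-peaks"``:
    g = baseline + Σ A·exp(−(r−μ)²/2s²), shell integrals via erf.
    ``grid`` is the bin-edge array (nm).
    """
    edges = np.asarray(grid, dtype=float)
    r = 0.5 * (edges[:-1] + edges[1:])
    if form == "step":
        g = np.where(r <= step_r, step_height, 0.0)
        truth_params = {
            "shell_integral": lambda r_min: 4.0 / 3.0 * np.pi * rho * step_height
            * min(r_min, step_r) ** 3,
            "step_r": step_r,
        }
    elif form == "gaussian-peaks":
        g = np.full_like(r, float(baseline))
        for p in peaks:
            g = g + p.amplitude * np.exp(-((r - p.center) ** 2) / (2.0 * p.width**2))

        def shell_integral(r_min: float) -> float:
            total = 4.0 / 3.0 * np.pi * rho * baseline * r_min**3
            for p in peaks:
                total += 4.0 * np.pi * rho * _gaussian_r2_integral(
                    p.amplitude, p.center, p.width, r_min
                )
            return total

        truth_params = {"shell_integral": shell_integral, "peaks": peaks}
    else:
        raise ToySimError(f"unknown analytic RDF form {form}")
    curve = RDFCurve(
        species_pair=species_pair, bin_edges=edges, g=np.clip(g, 0.0, None),
        rho_alpha=rho, rho_beta=rho,
    )
    return curve, SyntheticTruth(f"analytic-rdf-{form}", truth_params, 0)


def _gaussian_r2_integral(A: float, mu: float, s: float, R: float) -> float:
    """∫₀^R A·exp(−(r−μ)²/2s²)·r² dr in closed form."""
    a, b = -mu, R - mu
    sq2 = s * math.sqrt(2.0)
    e_int = s * math.sqrt(math.pi / 2.0) * (erf(b / sq2) - erf(a / sq2))
    exp_a, exp_b = math.exp(-(a**2) / (2 * s**2)), math.exp(-(b**2) / (2 * s**2))
    t1 = s**2 * (a * exp_a - b * exp_b) + s**2 * e_int  # ∫ t² e dt
    t2 = -(s**2) * (exp_b - exp_a)  # ∫ t e dt
    return A * (t1 + 2.0 * mu * t2 + mu**2 * e_int)
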