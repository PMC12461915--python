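"""Transport and thermodynamic-response observables.

* Self-diffusion by the Einstein relation: D = slope(MSD)/6 from a
  least-squares fit over a lag-time window, MSD averaged over particles
  and all time origins (FFT algorithm).
* Finite-size (Yeh–Hummer) correction for cubic periodic boxes:
  D_∞ = D(L) + k_B·T·ξ/(6π·η·L), with ξ = 2.837298 the dimensionless
  simple-cubic lattice constant, computed here from scratch by Ewald
  summation rather than hard-coded.
* Shear viscosity from cosine-acceleration nonequilibrium trajectories:
  a spatially periodic acceleration a·cos(2πz/L) on the x velocities
  develops a steady cosine velocity profile of amplitude v, and
  η = ρ a / (v k²) with k = 2π/L.
* Temperature of maximum density from a cubic polynomial fit of ρ(T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .constants import KB_J_PER_K, M2_PER_S_TO_NM2_PER_PS, PA_S_TO_MPA_S
from .trajectory import Trajectory, detect_wrapping, unwrap

XI_TOLERANCE_FLOOR = 1e-7
R2_DIFFUSIVE = 0.98  # minimum R² for an MSD fit to count as diffusive


class TransportError(ValueError):
    pass


# -- mean squared displacement / diffusion ---------------------------------


@dataclass
class MSDSeries:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # nm²
    n_particles: int

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if abs(self.msd[0]) > 1e-12:
            raise TransportError("MSD at zero lag must vanish")
        if np.any(np.diff(self.lag_times) <= 0):
            raise TransportError("lag times must be strictly increasing")


@dataclass
class DiffusionResult:
    D_box: float  # nm²/ps
    D_inf: float | None  # nm²/ps, after finite-size correction
    correction: float  # nm²/ps
    fit_window: tuple[float, float]  # ps
    r_squared: float = 1.0
    diffusive: bool = True


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Time autocorrelation sum_k x(k)·x(k+m) for each column, via FFT."""
    T = x.shape[0]
    F = np.fft.rfft(x, n=2 * T, axis=0)
    res = np.fft.irfft(F * F.conj(), n=2 * T, axis=0)[:T]
    return res.real


def msd_all_origins(positions: np.ndarray, dt: float) -> MSDSeries:
    """MSD over all time origins for an unwrapped (T, N, 3) position stack.

    Uses the standard O(T log T) FFT decomposition of
    ⟨|r(t+m)−r(t)|²⟩ into a running sum and an autocorrelation.
    """
    T, N, _ = positions.shape
    x = positions.reshape(T, N * 3)
    sq = (x**2).sum(axis=1) / N  # per-frame |r|² summed over particles+dims
    s2 = _autocorr_fft(x).sum(axis=1) / N
    cs = np.concatenate([[0.0], np.cumsum(sq)])
    m = np.arange(T)
    # S1(m) = mean over origins t of |r(t+m)|² + |r(t)|²
    tail = cs[T] - cs[m]  # sum_{k=m}^{T-1} sq[k]
    head = cs[T - m]  # sum_{k=0}^{T-1-m} sq[k]
    norm = T - m
    msd = (tail + head) / norm - 2 * s2 / norm
    msd[0] = 0.0
    return MSDSeries(lag_times=m * dt, msd=msd, n_particles=N)


def einstein_diffusion(
    traj: Trajectory,
    species: str | None = None,
    fit_window_frac: tuple[float, float] = (0.1, 0.5),
    dt: float = 1.0,
    unwrap_trajectory: bool = False,
) -> tuple[MSDSeries, DiffusionResult]:
    """Einstein diffusion coefficient D = slope/6 (nm²/ps) from the MSD.

    The trajectory must be continuous (no periodic jumps); pass
    ``unwrap_trajectory=True`` to remove wrap events first.  The MSD is
    fitted over lag times in ``[f1, f2] × t_max``; fits with R² below
    0.98 are flagged non-diffusive.
    """
    if traj.n_frames < 100:
        raise TransportError("need at least 100 frames for a diffusion estimate")
    if detect_wrapping(traj):
        if not unwrap_trajectory:
            raise TransportError(
                "trajectory appears wrapped (jumps > L/2); pass unwrap_trajectory=True"
            )
        traj = unwrap(traj)
    pos = traj.positions(species)
    if pos.shape[1] == 0:
        raise TransportError(f"no particles of species {species}")
    series = msd_all_origins(pos, dt)
    f1, f2 = fit_window_frac
    t_max = series.lag_times[-1]
    mask = (series.lag_times >= f1 * t_max) & (series.lag_times <= f2 * t_max)
    t_fit, m_fit = series.lag_times[mask], series.msd[mask]
    slope, intercept = np.polyfit(t_fit, m_fit, 1)
    pred = slope * t_fit + intercept
    ss_res = float(((m_fit - pred) ** 2).sum())
    ss_tot = float(((m_fit - m_fit.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = max(slope / 6.0, 0.0)
    if np.allclose(series.msd, 0.0):
        D, r2 = 0.0, 1.0
    return series, DiffusionResult(
        D_box=D,
        D_inf=None,
        correction=0.0,
        fit_window=(f1 * t_max, f2 * t_max),
        r_squared=r2,
        diffusive=r2 >= R2_DIFFUSIVE,
    )


# -- Yeh–Hummer finite-size correction -------------------------------------


def xi_cubic_lattice(tolerance: float = 1e-6, kappa: float | None = None) -> float:
    """Simple-cubic lattice constant ξ ≈ 2.837298 by Ewald summation.

    Evaluates the periodic Coulomb self-interaction of a unit point charge
    with its images and a uniform neutralizing background, split into a
    complementary-error-function real-space sum and a Gaussian
    reciprocal-space sum with the self term subtracted.  Shell cutoffs are
    grown until successive values change by less than ``tolerance``.  The
    result is independent of the splitting parameter ``kappa``.
    """
    if tolerance < XI_TOLERANCE_FLOOR:
        raise TransportError(f"tolerance below floor {XI_TOLERANCE_FLOOR}")
    k = kappa if kappa is not None else math.sqrt(math.pi)
    prev = None
    for n_max in range(3, 40):
        rng = np.arange(-n_max, n_max + 1)
        nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
        n2 = (nx**2 + ny**2 + nz**2).astype(float).ravel()
        n2 = n2[n2 > 0]
        n = np.sqrt(n2)
        real = float((erfc(k * n) / n).sum())
        recip = float((np.exp(-(math.pi**2) * n2 / k**2) / (math.pi * n2)).sum())
        psi = real + recip - 2.0 * k / math.sqrt(math.pi) - math.pi / k**2
        xi = -psi
        if prev is not None and abs(xi - prev) < tolerance:
            return xi
        prev = xi
    raise TransportError("Ewald summation for xi did not converge")


def yeh_hummer_correct(
    D_box: float,
    T: float,
    eta: float,
    L: float,
    fit_window: tuple[float, float] = (0.0, 0.0),
    xi: float | None = None,
) -> DiffusionResult:
    """Apply the finite-size correction D_∞ = D(L) + k_B·T·ξ/(6π·η·L).

    Units: ``D_box`` nm²/ps, ``T`` K, ``eta`` mPa·s, ``L`` nm; the
    correction is converted from SI internally and returned in nm²/ps.
    """
    if T <= 0 or L <= 0:
        raise TransportError("temperature and box length must be positive")
    if eta <= 0:
        raise TransportError("viscosity must be positive")
    if xi is None:
        xi = xi_cubic_lattice(1e-6)
    eta_si = eta / PA_S_TO_MPA_S  # Pa·s
    L_si = L * 1e-9  # m
    corr_si = KB_J_PER_K * T * xi / (6.0 * math.pi * eta_si * L_si)  # m²/s
    correction = corr_si * M2_PER_S_TO_NM2_PER_PS
    return DiffusionResult(
        D_box=D_box,
        D_inf=D_box + correction,
        correction=correction,
        fit_window=fit_window,
    )


# -- cosine-acceleration viscosity -----------------------------------------


@dataclass
class ViscosityResult:
    eta: float  # mPa·s
    eta_se: float  # mPa·s, over steady-state frames (or replicas)
    amplitude_a: float  # nm/ps²
    wavevector: float  # 2π/L, nm⁻¹
    velocity_amplitude: float  # nm/ps
    steady: bool = True

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise TransportError("viscosity must be positive")


def _profile_amplitude(frame_coords, frame_vels, L: float) -> float:
    """Least-squares amplitude of v_x on cos(2π z / L); exact for noise-free profiles."""
    c = np.cos(2.0 * np.pi * frame_coords[:, 2] / L)
    denom = float((c**2).sum())
    if denom == 0.0:
        raise TransportError("degenerate z distribution")
    return float((frame_vels[:, 0] * c).sum() / denom)


def cosine_viscosity(
    traj: Trajectory,
    amplitude_a: float,
    mass_density: float,
    steady_state_skip: float = 0.25,
    drift_tolerance: float = 0.05,
) -> ViscosityResult:
    """Shear viscosity (mPa·s) from a cosine-acceleration trajectory.

    Per-frame x-velocities are projected onto cos(2πz/L); after
    discarding the initial ``steady_state_skip`` fraction as transient,
    η = ρ·a/(v̄·k²) with k = 2π/L, converted to mPa·s.  ``mass_density``
    is in kg/m³ and ``amplitude_a`` in nm/ps².  If the amplitude still
    drifts by more than ``drift_tolerance`` between the two halves of the
    production window the result is flagged not steady.
    """
    if not traj.has_velocities():
        raise TransportError("trajectory carries no velocities")
    amps = np.array(
        [_profile_amplitude(fr.coordinates, fr.velocities, fr.box_edge) for fr in traj.frames]
    )
    start = int(round(steady_state_skip * len(amps)))
    prod = amps[start:]
    if prod.size == 0 or np.all(prod == 0):
        raise TransportError("zero velocity-profile amplitude")
    v = float(prod.mean())
    if v == 0.0:
        raise TransportError("zero velocity-profile amplitude")
    steady = True
    if prod.size >= 4:
        h1, h2 = prod[: prod.size // 2].mean(), prod[prod.size // 2 :].mean()
        if abs(h2 - h1) > drift_tolerance * abs(v):
            steady = False
    L = float(traj.box_edges().mean())
    kvec = 2.0 * np.pi / L
    # kg/m³ · nm/ps² / (nm/ps · nm⁻²) = 1e-6 Pa·s = 1e-3 mPa·s
    factor = 1e-3
    eta = factor * mass_density * amplitude_a / (v * kvec**2)
    if prod.size > 1:
        per_frame = factor * mass_density * amplitude_a / (prod * kvec**2)
        se = float(per_frame.std(ddof=1) / np.sqrt(prod.size))
    else:
        se = 0.0
    return ViscosityResult(
        eta=eta, eta_se=se, amplitude_a=amplitude_a, wavevector=kvec,
        velocity_amplitude=v, steady=steady,
    )


def viscosity_replicas(results: list[ViscosityResult]) -> tuple[float, float]:
    """Mean and standard error of η across independent replicas."""
    etas = np.array([r.eta for r in results])
    if etas.size < 2:
        raise TransportError("need at least 2 replicas")
    return float(etas.mean()), float(etas.std(ddof=1) / np.sqrt(etas.size))


# -- temperature of maximum density ----------------------------------------


@dataclass
class TMDFit:
    temperatures: np.ndarray  # K
    densities: np.ndarray  # kg/m³
    cubic_coeffs: np.ndarray  # highest power first (np.polyfit order)
    tmd: float  # K
    rho_max: float  # kg/m³


def fit_tmd(temperatures, densities) -> TMDFit:
    """Temperature of maximum density from an unweighted cubic fit of ρ(T).

    The TMD is the root of the fitted cubic's derivative inside the data
    range where the second derivative is negative; data without an
    interior maximum raise.
    """
    T = np.asarray(temperatures, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if T.size < 5:
        raise TransportError("need at least 5 temperature points")
    coeffs = np.polyfit(T, rho, 3)
    deriv = np.polyder(coeffs)
    roots = np.roots(deriv)
    candidates = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9
        and T.min() <= r.real <= T.max()
        and np.polyval(np.polyder(deriv), r.real) < 0
    ]
    if not candidates:
        raise TransportError("no interior density maximum in the fitted range")
    tmd = candidates[0]
    return TMDFit(
        temperatures=T,
        densities=rho,
        cubic_coeffs=coeffs,
        tmd=tmd,
        rho_max=float(np.polyval(coeffs, tmd)),
    )
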