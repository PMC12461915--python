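"""Structural target properties from trajectories.

Radial distribution functions g_αβ(r) are computed as minimum-image pair
histograms normalized per frame by the ideal-gas shell count, so a
homogeneous fluid yields g ≈ 1.  First-shell analysis integrates the RDF
up to its first minimum:

* CIP (contact ion pairs)  = 4π ρ_∓ ∫₀^rmin g_+−(r) r² dr, with the
  counter-ion number density (the anion density for 1:2 salts, so the
  value counts anions in contact with the cation),
* HN (hydration number)    = 4π ρ_w ∫₀^rmin g_MO(r) r² dr,
* CN = HN + CIP.

When the cation–anion RDF shows no distinct first-shell peak, CIP is
taken to be zero.  A dilute-reference r_min may be supplied to override
the self-detected minimum of the ion–oxygen RDF, the convention used for
anion hydration numbers in strongly paired concentrated solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASS_KG, NM_PER_M
from .trajectory import Trajectory, minimum_image

DEFAULT_BIN_WIDTH = 0.002  # nm; NDIS r-resolution scale
PEAK_PROMINENCE = 1.1  # a peak is "distinct" if smoothed g exceeds bulk by >=10%


class StructureError(ValueError):
    pass


@dataclass
class RDFCurve:
    """Binned radial distribution function for one species pair."""

    species_pair: tuple[str, str]
    bin_edges: np.ndarray  # (n_bins+1,) nm
    g: np.ndarray  # (n_bins,)
    rho_alpha: float  # nm^-3, frame-averaged
    rho_beta: float  # nm^-3
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise StructureError("bin edges must be strictly increasing")
        if self.g.shape[0] != self.bin_edges.shape[0] - 1:
            raise StructureError("g / bin_edges length mismatch")
        if np.any(self.g < -1e-12):
            raise StructureError("g(r) must be non-negative")

    @property
    def r(self) -> np.ndarray:
        """Bin midpoints (nm)."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ShellAnalysis:
    """First-shell integrals: contact ion pairs, hydration and coordination numbers."""

    r_min_pm: float | None  # first minimum of g_+- (nm); None when no distinct peak
    r_min_mo: float  # first minimum of g_MO (nm)
    cip: float
    hn: float
    r_min_source: str = "self"  # or "dilute-reference"
    cn: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cip < 0 or self.hn < 0:
            raise StructureError("negative shell integral")
        self.cn = self.hn + self.cip


def pair_distance_histogram(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    box: float,
    bin_edges: np.ndarray,
    same_species: bool,
) -> np.ndarray:
    """Histogram of minimum-image pair distances for one frame.

    Counts ordered pairs (i from a, j from b), excluding self pairs when
    the two selections are the same species.
    """
    d = coords_a[:, None, :] - coords_b[None, :, :]
    d = minimum_image(d, box)
    r = np.sqrt((d**2).sum(axis=-1))
    if same_species:
        np.fill_diagonal(r, np.inf)
    counts, _ = np.histogram(r, bins=bin_edges)
    return counts.astype(float)


def compute_rdf(
    traj: Trajectory,
    pair: tuple[str, str],
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RDFCurve:
    """g_αβ(r) by minimum-image pair binning with ideal-gas normalization.

    Normalization uses each frame's instantaneous box volume (NPT
    compatible): per-frame shell counts are averaged first, then divided
    by the frame-averaged ideal count.  r_max must not exceed L/2.
    """
    if bin_width <= 0:
        raise StructureError("bin width must be positive")
    alpha, beta = pair
    ia = traj.indices_of(alpha)
    ib = traj.indices_of(beta)
    if ia.size == 0 or ib.size == 0:
        raise StructureError(f"no particles of species {alpha if ia.size == 0 else beta}")
    L_min = traj.box_edges().min()
    if r_max is None:
        r_max = L_min / 2
    if r_max > L_min / 2 + 1e-12:
        raise StructureError(
            f"r_max={r_max} exceeds L/2={L_min / 2}: minimum-image convention invalid"
        )
    n_bins = max(1, int(round(r_max / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    same = alpha == beta

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = np.zeros(n_bins)
    ideal = np.zeros(n_bins)
    rho_a = rho_b = 0.0
    boxes = traj.box_edges()
    n_pairs = ia.size * (ib.size - 1) if same else ia.size * ib.size
    if np.all(boxes == boxes[0]):
        # constant-volume fast path: batch frames through one histogram call
        L = float(boxes[0])
        V = L**3
        A = traj.positions()[:, ia, :]
        B = traj.positions()[:, ib, :]
        block = max(1, int(2_000_000 // max(ia.size * ib.size, 1)))
        for k in range(0, traj.n_frames, block):
            d = A[k : k + block, :, None, :] - B[k : k + block, None, :, :]
            d = minimum_image(d, L)
            r = np.sqrt((d**2).sum(axis=-1))
            if same:
                r[:, np.arange(ia.size), np.arange(ia.size)] = np.inf
            c, _ = np.histogram(r, bins=edges)
            counts += c
        ideal = traj.n_frames * n_pairs / V * shell_vol
        rho_a = traj.n_frames * ia.size / V
        rho_b = traj.n_frames * ib.size / V
    else:
        for fr in traj.frames:
            V = fr.box_edge**3
            counts += pair_distance_histogram(
                fr.coordinates[ia], fr.coordinates[ib], fr.box_edge, edges, same
            )
            ideal += n_pairs / V * shell_vol
            rho_a += ia.size / V
            rho_b += ib.size / V
    nf = traj.n_frames
    g = np.where(ideal > 0, counts / ideal, 0.0)
    return RDFCurve(
        species_pair=(alpha, beta),
        bin_edges=edges,
        g=g,
        rho_alpha=rho_a / nf,
        rho_beta=rho_b / nf,
        n_frames=nf,
    )


def _boxcar(y: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_first_minimum(
    rdf: RDFCurve,
    search_window: tuple[float, float] | None = None,
    smooth_width: int = 5,
    peak_threshold: float = PEAK_PROMINENCE,
) -> float | None:
    """Abscissa of the first local minimum after the first distinct peak.

    The curve is boxcar-smoothed; a peak counts as distinct only if the
    smoothed g exceeds ``peak_threshold`` (default: 10% above the bulk
    level of 1).  Returns None when no distinct peak lies in the window,
    in which case callers treat the shell population (e.g. CIP) as zero.
    """
    if np.all(rdf.g == 0):
        raise StructureError("empty RDF curve")
    r = rdf.r
    lo, hi = search_window if search_window else (r[0], r[-1])
    if lo < rdf.bin_edges[0] - 1e-12 or hi > rdf.bin_edges[-1] + 1e-12:
        raise StructureError("search window outside curve support")
    gs = _boxcar(rdf.g, smooth_width)
    mask = (r >= lo) & (r <= hi)
    idx = np.flatnonzero(mask)
    # first distinct peak: local max of the smoothed curve above threshold
    peak = None
    for k in idx[1:-1]:
        if gs[k] >= peak_threshold and gs[k] >= gs[k - 1] and gs[k] >= gs[k + 1]:
            peak = k
            break
    if peak is None:
        return None
    for k in range(peak + 1, idx[-1]):
        if gs[k] <= gs[k - 1] and gs[k] <= gs[k + 1]:
            return float(r[k])
    return None


def shell_integral(rdf: RDFCurve, rho: float, r_min: float) -> float:
    """4π ρ ∫₀^rmin g(r) r² dr by trapezoid rule on bin midpoints."""
    r = rdf.r
    mask = r <= r_min
    if not mask.any():
        return 0.0
    rr = r[mask]
    integrand = rdf.g[mask] * rr**2
    # close the integral at exactly r_min by linear interpolation
    if rr[-1] < r_min and mask.sum() < r.size:
        g_at = np.interp(r_min, r, rdf.g)
        rr = np.append(rr, r_min)
        integrand = np.append(integrand, g_at * r_min**2)
    return float(4.0 * np.pi * rho * np.trapezoid(integrand, rr))


def coordination_numbers(
    rdf_pm: RDFCurve | None,
    rdf_mo: RDFCurve,
    stoichiometry: str = "1:1",
    r_min_override: float | None = None,
    pm_window: tuple[float, float] | None = None,
    mo_window: tuple[float, float] | None = None,
) -> ShellAnalysis:
    """CIP, HN and CN from the ion–counterion and ion–oxygen RDFs.

    ``stoichiometry`` selects the density used in the CIP prefactor: for
    1:1 salts the counter-ion density (rho_beta of ``rdf_pm``); for 1:2
    salts likewise the anion density — both resolve to the density of the
    second species of the +− pair, which must be the counter-ion.
    ``r_min_override`` applies the dilute-reference convention to the
    ion–oxygen shell boundary.
    """
    if stoichiometry not in ("1:1", "1:2"):
        raise StructureError(f"unsupported stoichiometry {stoichiometry}")
    if r_min_override is not None:
        r_min_mo = float(r_min_override)
        source = "dilute-reference"
    else:
        found = find_first_minimum(rdf_mo, mo_window)
        if found is None:
            raise StructureError(
                "no distinct first peak in the ion-oxygen RDF; supply an explicit window"
            )
        r_min_mo = found
        source = "self"
    hn = shell_integral(rdf_mo, rdf_mo.rho_beta, r_min_mo)

    if rdf_pm is None:
        cip = 0.0
        r_min_pm = None
    else:
        # first hydration shell (from the ion-water RDF) bounds the search
        window = pm_window if pm_window is not None else (rdf_pm.r[0], r_min_mo)
        r_min_pm = find_first_minimum(rdf_pm, window)
        if r_min_pm is None:
            cip = 0.0
        else:
            cip = shell_integral(rdf_pm, rdf_pm.rho_beta, r_min_pm)
    return ShellAnalysis(r_min_pm=r_min_pm, r_min_mo=r_min_mo, cip=cip, hn=hn,
                         r_min_source=source)


def density(
    traj: Trajectory,
    masses: dict[str, float],
    n_blocks: int = 5,
) -> tuple[float, float]:
    """Mass density (kg/m³) with a block-averaged standard error.

    ``masses`` maps species to atomic masses in daltons; every species in
    the trajectory must be present.  Requires at least 2 frames.
    """
    if not masses:
        raise StructureError("empty species-mass map")
    if traj.n_frames < 2:
        raise StructureError("need at least 2 frames for an error estimate")
    missing = set(traj.species) - set(masses)
    if missing:
        raise StructureError(f"missing masses for species: {sorted(missing)}")
    total_mass_kg = sum(masses[s] for s in traj.species) * ATOMIC_MASS_KG
    per_frame = []
    for fr in traj.frames:
        V = (fr.box_edge / NM_PER_M) ** 3  # m^3
        if V <= 0:
            raise StructureError("zero-volume frame")
        per_frame.append(total_mass_kg / V)
    per_frame = np.array(per_frame)
    mean = float(per_frame.mean())
    blocks = np.array_split(per_frame, min(n_blocks, traj.n_frames))
    block_means = np.array([b.mean() for b in blocks])
    se = float(block_means.std(ddof=1) / np.sqrt(len(block_means))) if len(block_means) > 1 else 0.0
    return mean, se
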