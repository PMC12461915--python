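# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `eccforge`. Units are GROMACS conventions throughout:
lengths in nm, times in ps, energies in kJ/mol, charges in elementary
charges e; viscosities are reported in mPa·s, mass densities in kg/m³,
scattering lengths in fm.

## Charge-scaled force fields

The electronic continuum correction (ECC) represents electronic
polarization implicitly by immersing point charges in a background with
the electronic dielectric constant ε_el, equivalent to scaling all ionic
charges by s = 1/√ε_el. For water ε_el ≈ 1.78, giving the "fully
consistent" s ≈ 0.75; empirical optimization of ion models on top of a
reduced-dielectric water model tends to favour slightly larger factors
(s ≈ 0.81, implying an effective solution dielectric ε/s² ≈ 70 for a
water model with ε = 45). `ScaledForceField` stores formal charges and a
single scaling factor; effective charges are always s × formal, so any
stoichiometric salt remains exactly neutral for every s.

Cross Lennard-Jones terms follow Lorentz–Berthelot combination rules,
σ_ab = (σ_aa+σ_bb)/2, ϵ_ab = √(ϵ_aa·ϵ_bb), except where an explicit pair
override is registered (used for anion–water-oxygen pairs). Overrides
are stored once per unordered pair, order-normalized at construction.
The GROMACS-dialect writer declares combination rule 2 and emits every
override explicitly in `[ nonbond_params ]` so a downstream engine never
re-derives an overridden pair; floats are printed at 17 significant
digits so write→read round-trips are bit-exact.

The bundled `eccions81_synthetic.json` fixture carries the published
scaled charges of the ECCions81 set (±0.81 e monovalent, +1.62 e
divalent, s = 0.81) with *synthetic placeholder* σ/ϵ values of typical
aqueous-ion magnitude; it exists so serialization, validation and
neutrality checks run against a realistic composition, not as a
redistribution of the published parameter table.

## Structural observables

`compute_rdf` histograms minimum-image pair distances on half-open bins
[r, r+Δr), normalizing per frame by the ideal-gas shell count computed
from the instantaneous box volume (NPT-compatible: shell counts are
accumulated across frames before dividing by the accumulated ideal
count). Default bin width 0.002 nm — the scale of the r-resolution of
neutron-diffraction difference functions. Self pairs are excluded for
like-species RDFs; r_max > L/2 is rejected because the cubic
minimum-image convention breaks beyond the half box. Only cubic cells
are supported.

First-minimum detection smooths g(r) with a 5-point boxcar, requires a
"distinct" first peak — the smoothed curve must exceed the bulk level by
at least 10% (configurable; the threshold is our choice, the criterion
that an indistinct cation–anion peak yields zero contact ion pairs is
the field convention) — and returns the first local minimum after that
peak.

Shell populations integrate 4πρ∫g(r)r²dr by the trapezoid rule on bin
midpoints (second-order accurate, matching histogram support), closing
the integral at exactly r_min by linear interpolation:

- CIP (contact ion pairs): cation–anion RDF up to its first minimum,
  with the *counter-ion* number density in the prefactor (for 1:2 salts
  the anion density, so the value counts anions around a cation);
  no distinct peak ⇒ CIP = 0.
- HN (hydration number): ion–oxygen RDF up to its first minimum, water
  oxygen density in the prefactor. A dilute-reference r_min may be
  passed to override the self-detected minimum — the convention used
  for anion hydration numbers in strongly ion-paired concentrated
  solutions, where the first g_XO minimum drifts outward.
- CN = HN + CIP, exactly, by construction.

Densities ρ in the prefactors are NPT-average number densities of the
relevant species. Mass density is the frame average of total mass over
box volume, with a block-averaged (5 blocks) standard error.

## Transport observables

**Diffusion.** The mean squared displacement is averaged over particles
and all time origins using the standard FFT decomposition (O(T log T));
D = slope/6 from an unweighted least-squares fit of the MSD over lag
times in 10–50% of the maximum lag (defaults; the window is a knob).
Fits with R² < 0.98 are flagged non-diffusive — this cleanly rejects
ballistic motion, whose MSD ∝ t² yields R² ≈ 0.97 on this window.
Trajectories must be continuous; frame-to-frame jumps above L/2 are
treated as wrap events and either rejected or unwrapped on request
(valid when physical per-step motion is well below L/2).

**Finite-size correction.** D_∞ = D(L) + k_B·T·ξ/(6πηL) for a cubic box
of edge L, with η the shear viscosity. The dimensionless constant ξ is
*computed*, not hard-coded: the self-interaction of a unit point charge
with its periodic images and a neutralizing background is evaluated by
Ewald summation (complementary-error-function real-space sum plus
Gaussian reciprocal-space sum, self-term 2κ/√π and background π/κ²
removed), growing shell cutoffs until successive values differ by less
than the tolerance. The result, 2.8372975 at 1e-6, is independent of the
splitting parameter κ over at least a factor of 2 and agrees with the
spherically-truncated direct lattice sum, which oscillates around it as
expected for a conditionally convergent series. k_B is CODATA 2018.

**Viscosity.** Cosine-acceleration nonequilibrium estimator: a body
acceleration a·cos(2πz/L) on the x-direction develops a steady velocity
profile v·cos(2πz/L), and η = ρ·a/(v·k²) with k = 2π/L (unit factor:
kg/m³·nm²/ps = 1e-3 mPa·s). The per-frame amplitude v is the
least-squares projection of particle x-velocities on cos(2πz/L) — exact
for noise-free profiles at any particle placement, which is what makes
the closed-form fixture test meaningful to machine precision. The first
25% of each trajectory is discarded as transient (the production
simulations it models discard a separate equilibration run; a toy
trajectory must do this explicitly); a residual drift above 5% between
the halves of the production window sets a not-steady flag. Replicas
(the production protocol uses 25 independent runs) are combined by mean
and standard error.

**Temperature of maximum density.** ρ(T) is fitted by an unweighted
cubic polynomial (no per-point errors are available in the modelled
workflow); the TMD is the root of the derivative inside the data range
with negative curvature. At least 5 points spanning the maximum are
required; monotone data raise.

## Neutron difference functions

First-order NDIS differences isolate the correlations of a substituted
species M. In terms of partial RDFs,

    ΔG_M(r) = Σ_{α≠M} 2 c_M Δb_M c_α b_α (g_Mα − 1)
              + c_M² (b_M² − b'^2_M)(g_MM − 1),

with concentrations c, coherent scattering lengths b and isotope
contrast Δb_M = b_M − b'_M. This is the standard weighting convention;
all coefficients are recorded in the result so an alternative convention
is a configuration change, not a code change. Normalization defaults to
per-substituted-atom (division by c_M), recorded in metadata. The
bundled scattering-length table is the Sears (1992) compilation; "null
water" is realized as an effective hydrogen entry with b = 0.

Q-space: ΔS(Q) = 4πρ∫r²ΔG(r)·sin(Qr)/(Qr)dr by trapezoid quadrature on
the uniform r-grid, with the sinc limit at Q = 0 and an optional Lorch
window sin(πr/r_max)/(πr/r_max) against truncation ripple. The inverse
transform (1/2π²ρ)∫Q²ΔS·sinc(Qr)dQ closes the round trip; on
band-limited inputs the r→Q→r round trip is accurate to <1% RMS, and the
Gaussian transform pair ΔG = exp(−r²/2s²) ⟷ ρ(2πs²)^{3/2}exp(−Q²s²/2)
is the closed-form oracle. Cation differences (e.g. ΔG_NaK = G_K − G_Na)
are pointwise subtractions with minuend/subtrahend recorded; null-water
adjustment subtracts a weighted pure-water O–O term.

## Surrogate-assisted global optimization

The cost is the negative log-likelihood

    J(θ) = Σ_{i=1..n} [ (n/2)·log(2πσ_i²) + (y_i(θ) − μ_i)²/(2σ_i²) ],

with the (n/2)·log factor inside the per-target sum and n the total
target count — implemented exactly as the modelled workflow defines it
(the constant offset is irrelevant to ranking; only cost differences
enter the acceptance rule).

A campaign stage runs: (1) a reflective Gaussian random walk from the
start point (default 200 samples, step 5% of each bound span), all fully
evaluated; (2) differential evolution rand/1/bin (defaults F = 0.8,
CR = 0.9, at least one mutant gene forced, offspring clipped to bounds)
where each offspring is first *predicted* by the surrogate and gated by
the Metropolis–Hastings rule A = min(1, exp(J_parent − J_offspring_pred)).
The comparison is deliberately asymmetric — evaluated parent cost
against predicted offspring cost — matching the modelled protocol.
Rejected offspring are discarded without evaluation; accepted offspring
are fully evaluated and appended to the training archive. Parent
replacement uses the *fully evaluated* offspring cost (the conservative
reading; using the predicted cost is the alternative). Failed
evaluations get cost +∞, are flagged, and are excluded from surrogate
training; the campaign continues.

The surrogate is a local Gaussian process: per property, an independent
GP restricted at query time to the k = 50 nearest training points
(scaled-Euclidean distance in the unit hypercube of the bounds — σ in nm
and ϵ in kJ/mol differ by orders of magnitude unscaled). Kernel:
constant × anisotropic squared-exponential + white noise.
Hyperparameters are re-fitted by marginal-likelihood maximization at
every retrain event — after every 50 accepted samples, on a subsample
capped at 150 points for speed — then frozen for the per-query local
fits, which are direct Cholesky solves with escalating jitter
(0, 1e-10, 1e-8, 1e-6) on numerically degenerate local matrices.
With k ≥ the training-set size the construction reduces to a global GP,
which is tested.

Stages chain: later stages can freeze parameters at an earlier stage's
optimum (e.g. a shared anion model and scaling factor), reproducing the
staged ion-group protocol. The archive is append-only JSON-lines with
seeds stored for replay, and a histogram of the scaling factor over the
top-N samples is available as a campaign report.

All stochastic operations draw from explicitly seeded generators;
identical seeds give bit-identical campaigns.

## Toy simulator and synthetic data

The toy engine is a Metropolis NVT Monte-Carlo sampler of a
Lennard-Jones + scaled-Coulomb fluid with a neutral LJ solvent site and
either reaction-field (conducting boundary) or truncated-shifted
electrostatics, LJ truncated and shifted at the cutoff (default
min(1 nm, L/2)). A background dielectric constant divides all charge
products — the primitive-model representation of solvent screening.
This matters: with bare scaled charges an ion-pair contact well is
~100 k_BT and the sampler freezes into whatever pairing configuration
it first finds; with screening of order 20 the well is a few k_BT and
pairing equilibrates reversibly. The engine is a desk-scale test fluid
for exercising the analysis and optimization machinery; it makes no
quantitative claims about production particle-mesh-Ewald molecular
dynamics of real electrolytes, and passing tests say nothing about real
water beyond the estimator algebra being correct.

Single-particle moves are uniform displacements auto-tuned toward ~40%
acceptance during equilibration (8 tuning blocks; an acceptance ratio
below 1% after tuning is an error). All random numbers are pre-drawn
from a seeded numpy Generator outside the compiled kernel, so runs are
bit-reproducible; the inner loop is numba-compiled. A running total
energy is maintained incrementally from accepted-move ΔE and averaged
over every production move, giving a lower-variance mean energy than
recomputing over stored frames (the two agree; this is tested).
Detailed balance is verified on a two-particle system against Boltzmann
reweighting of the uniform distance distribution.

The toy evaluator maps optimizer parameters (cation σ/ϵ, anion σ/ϵ,
scaling factor s) onto the template force field, runs the engine at a
*fixed internal seed*, and reports: cation–anion and cation–solvent
first-peak position and height (parabolic sub-bin interpolation),
contact-ion-pair and solvent-coordination shell integrals at fixed radii
(fixed, rather than self-detected, so the property map is smooth in θ),
RDF values at three fixed probe radii (shape information), and the mean
potential energy per particle (a pressure-like thermodynamic surrogate
for the NPT densities that an NVT toy cannot target). Because the
internal seed is fixed, θ → properties is deterministic and the planted
recovery cost has its global minimum at the generating parameters, up to
the generator's frozen sampling noise.

**Recovery study conditions** (fixed in `campaigns.py`): 5 cation + 5
anion + 22 solvent particles in a 1.3 nm box at 300 K, dielectric 20,
12000 production sweeps sampled every 40. These were chosen by an
identifiability analysis — finite-difference property sensitivities
against seed-to-seed generator noise — so that each parameter has a
distinct signature: peak positions pin σ, the cation–solvent shell and
its shape pin ϵ (the true ϵ = 3 kJ/mol ≈ 1.2 k_BT is deep enough to be
visible), and ion pairing plus mean energy pin s. The per-property
target variances σ_i² are the measured generator noise levels at the
truth. A campaign of 24 seed samples and a 320-evaluation budget
(F = 0.7, locality 40) recovers σ and ϵ within 5% and s within 0.02
across seeds; the accuracy floor is set by the frozen sampling noise of
the generator, not by the optimizer budget.

Other generators: Brownian trajectories (independent Gaussian steps of
variance 2·D·dt per dimension, unwrapped) — the generator *is* the
oracle for the Einstein estimator; cosine-flow frames (exact or noisy
velocity profiles with known ρ, a, v, hence known η); analytic RDF
curves (step and Gaussian-peak forms) carrying closed-form shell
integrals (Gaussian moments via erf) as their truth records.

## Numerical and scale choices

- Problem sizes in the test suite are desk scale by design: ≤60-particle
  fluids for engine physics checks, 500 × 2000 Brownian paths for the
  diffusion recovery, 320-evaluation optimization campaigns. The
  Rosenbrock benchmark uses the full 5000-evaluation budget.
- RDF batch path: when all frames share a box, frames are blocked
  through a single vectorized histogram call (block size capped near
  2·10⁶ pair distances to bound memory); otherwise a per-frame loop
  handles NPT-style varying volumes. Both paths are equivalent to the
  brute-force double loop, which is asserted property-style.
- Degenerate inputs raise typed errors (`ForceFieldError`,
  `StructureError`, `TransportError`, `NeutronError`, `ToySimError`,
  `OptimizerError`, `SurrogateError`) with messages naming the offending
  quantity (e.g. the residual charge of a non-neutral composition, the
  missing partial of a difference function).

## Known limitations

- Cubic boxes only; no triclinic minimum image.
- The toy engine has no barostat: density-type targets are replaced by
  energy/structure targets in recovery experiments.
- The NDIS weighting convention is the standard one; experimental
  normalization conventions vary between datasets and instruments, so
  coefficients are exposed rather than asserted universal.
- The GROMACS-dialect writer covers nonbonded parameters only (no
  bonded terms, no virtual sites, no water internal geometry).
- The LGP surrogate assumes independent outputs per property; correlated
  property errors are not modelled.
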