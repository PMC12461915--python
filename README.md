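# eccforge

Tools for building and testing **charge-scaled (ECC) ion force fields**:
the surrogate-assisted global optimizer used to fit them, every target
property it optimizes against — radial distribution functions, contact
ion pairs and hydration numbers, densities, shear viscosity,
finite-size-corrected diffusion, temperature of maximum density — and
the neutron-diffraction difference functions used to compare models with
isotopic-substitution experiments. A bundled toy electrolyte simulator
and synthetic-data generators make the whole pipeline runnable and
testable on a laptop, with no external simulation engine.

**Who it is for.** People developing or validating scaled-charge ion
models for aqueous electrolytes (Li⁺, Na⁺, K⁺, Mg²⁺, Ca²⁺, Cl⁻, Br⁻,
I⁻ and friends), and anyone who needs the component estimators —
NDIS first-order differences, Yeh–Hummer corrections, cosine-acceleration
viscosity — as standalone, tested building blocks.

## The science in brief

The electronic continuum correction treats electronic polarization
implicitly by scaling ionic charges, q → s·q with s = 1/√ε_el ≈ 0.75 for
water; empirically optimal models sit near s ≈ 0.81. Fitting the
remaining Lennard-Jones parameters is a noisy, expensive global
optimization: each candidate parameter set θ must be simulated to
evaluate a negative log-likelihood cost over n property targets

    J(θ) = Σᵢ [ (n/2)·log(2πσᵢ²) + (yᵢ(θ) − μᵢ)²/(2σᵢ²) ],

with μᵢ experimental references and σᵢ² predefined variances. `eccforge`
implements the accelerated loop: random-walk seeding, differential
evolution (rand/1/bin), and a **local Gaussian-process surrogate** that
predicts properties of each offspring so a Metropolis–Hastings gate

    A(θ, θ′) = min(1, exp(J(θ′) − J(θ)))

can discard unpromising candidates before paying for a simulation.
Accepted offspring are fully evaluated, archived, and fold back into the
surrogate (retrained every 50 new samples — active learning). Staged
campaigns freeze shared parameters (an anion model, the scaling factor)
between ion groups.

Observables follow the field's standard definitions: g_αβ(r) from
minimum-image pair histograms; CIP/HN as 4πρ∫g r²dr up to the first RDF
minimum (CN = HN + CIP); D from the Einstein relation with the cubic-box
finite-size correction D_∞ = D(L) + k_BTξ/(6πηL), where ξ = 2.837297 is
recomputed from scratch by Ewald lattice summation; η from the
steady-state amplitude of a cosine-modulated velocity profile; ΔG_M(r)
and ΔS_M(Q) as scattering-length-weighted sums of partial RDFs and their
sine transforms. See `docs/methods.md` for conventions, defaults and
limitations.

## Worked example

```python
from eccforge import (xi_cubic_lattice, yeh_hummer_correct,
                      cosine_flow_frames, cosine_viscosity,
                      mc_sample, compute_rdf, coordination_numbers)
from eccforge.campaigns import recovery_template

# 1. Finite-size constant and diffusion correction for a water-like box
xi = xi_cubic_lattice(tolerance=1e-6)
res = yeh_hummer_correct(D_box=2.00e-3, T=298.0, eta=0.896, L=4.36)
print(f"xi = {xi:.6f}")
print(f"finite-size correction = {res.correction:.3e} nm^2/ps")
print(f"D_inf = {res.D_inf:.3e} nm^2/ps")

# 2. Viscosity from a synthetic cosine-flow trajectory
traj, _ = cosine_flow_frames(L=4.0, v_amp=0.0107, rho=997.0,
                             noise_sigma=0.0, n_frames=20, seed=1)
visc = cosine_viscosity(traj, amplitude_a=0.020, mass_density=997.0)
print(f"eta = {visc.eta:.4f} mPa*s (steady={visc.steady})")

# 3. Shell analysis of a toy electrolyte sampled by the bundled MC engine
traj, info = mc_sample(recovery_template())
g_pm = compute_rdf(traj, ("M", "X"), bin_width=0.01, r_max=0.65)
g_ms = compute_rdf(traj, ("M", "W"), bin_width=0.01, r_max=0.65)
shells = coordination_numbers(g_pm, g_ms, pm_window=(0.2, 0.6))
print(f"CIP = {shells.cip:.2f}, HN = {shells.hn:.2f}, CN = {shells.cn:.2f}")
```

prints

```
xi = 2.837297
finite-size correction = 1.585e-04 nm^2/ps
D_inf = 2.159e-03 nm^2/ps
eta = 0.7553 mPa*s (steady=True)
CIP = 1.88, HN = 4.39, CN = 6.27
```

Reading the numbers: the Ewald summation reproduces the cubic-lattice
constant to six decimals; for a 4.36 nm water box at 298 K the
finite-size correction is ~8% of D itself — why the correction matters;
the noise-free cosine profile returns exactly η = ρ·a·(L/2π)²/v; and in
the deliberately concentrated toy melt roughly two counter-ions sit in
the cation's first shell alongside ~4.4 solvent particles, and
CN = HN + CIP holds by construction.

A blind parameter-recovery campaign (the optimizer re-finding the toy
generator's own parameters from its observables) runs in a few minutes:

```bash
eccforge optimize run --campaign toy-recovery --seed 1 --max-evaluations 320
```

The CLI also exposes the individual estimators (`eccforge analyze
rdf|shells|density|diffusion|viscosity|tmd`), force-field serialization
(`eccforge ff write|validate`), neutron tools (`eccforge neutron
diff|toq|cation-diff`) and the generators (`eccforge simulate
toy|brownian|flow`).

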