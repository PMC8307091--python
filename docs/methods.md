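# Methods

## Model

`hardnem` computes isotropic–nematic phase behavior of fluids of hard
prolate spheroids (ellipsoids of revolution, minor semi-axis *a*, major
semi-axis *c* ≥ *a*, both in nm). Interactions are pure hard-core exclusion,
so all phase behavior is entropic: the orientational entropy of the
single-particle distribution f(Ω) competes with the packing (excess)
entropy controlled by the pair excluded volume v_ex(γ), which depends on
the relative orientation only through cos γ = û₁·û₂ and is even in it.

The pure-component Helmholtz free energy density (β = 1/k_BT, thermal
wavelength λ = 1, densities in nm⁻³) is the Onsager functional with the
Parsons–Lee resummation:

    βF/V = ρ(ln ρ − 1) + ρ⟨f ln f⟩ + ½ ρ² G(η) ⟨⟨f f v_ex⟩⟩,
    G(η) = (4 − 3η) / (z (1 − η)²),       η = ρ v_lc,

where ⟨·⟩ is the normalized solid-angle average, ⟨⟨··⟩⟩ the double one, and
v_lc = (4/3)πa²c. G(η) rescales the second-virial excess term by the
Carnahan–Starling density dependence so that higher virial coefficients are
emulated. The divisor z normalizes the excluded-volume scale: z = 4 divides
the aligned excluded volume 8 v_lc down to one particle volume and is the
standard pairing with the Gaussian-overlap (Berne–Pechukas) excluded
volume; z = 3 is the pairing appropriate to the rigorous excluded volume.
Since the rigorous v_ex is smaller than the Gaussian-overlap one at every
non-parallel orientation, keeping z = 4 with the rigorous kernel pushes the
transition to markedly higher packing; dividing by six instead restores
agreement with simulation benchmarks. Exposing (method, z) as required,
unpaired settings is deliberate — their interplay is the scientific point.

Functional minimization of βF/V under the normalization constraint gives
the self-consistency condition

    f(θ) = exp(−ρ G(η) ⟨f v_ex⟩(θ)) / q,

with q fixing normalization. The chemical potential follows by density
differentiation (the f-dependence drops by the envelope theorem at the
minimizer) and the pressure from βP = ρβμ − βF/V; both are implemented in
the closed forms whose mutual consistency (Gibbs–Duhem, μ = ∂(βF/V)/∂ρ by
finite differences) is asserted by tests rather than assumed. Orientational
order is measured by S = ⟨P₂(cos θ)⟩ with the director along θ = 0.

## Excluded volume

Three evaluations of v_ex are provided:

* **Gaussian overlap**: 8 v_lc √((1 − χ²cos²γ)/(1 − χ²)) with
  χ = ((c/a)² − 1)/((c/a)² + 1); identical pairs only.
* **Rigorous apse-frame integral**: a surface integral over the apse
  direction k̂ (the common-tangent normal at contact), valid for arbitrary
  pairs. The cross-product term λ_ee = (û₁×û₂)·k̂ makes the integrand a
  scalar and vanishes for parallel axes; the implementation is pinned by
  exact limits (sphere pair → Minkowski volume (4/3)π(a₁+a₂)³ at machine
  precision; identical aligned pair → 8 v_lc).
* **Monte Carlo**: uniform sampling of center separations in a bounding
  cuboid of half-width c₁+c₂, with overlap decided by the Perram–Wertheim
  contact function (maximum over its scalar parameter of a quadratic-form
  expression; overlap iff the maximum is below 1). The maximization is
  vectorized over samples on a dense parameter grid with parabolic
  refinement, which is valid because the contact function is concave in the
  parameter. This estimator is an independent oracle for the rigorous
  integral, not a production path.

v_ex(cos γ) is tabulated on 201 uniform nodes in [0, 1] (head–tail symmetry
supplies the rest) and interpolated by a cubic spline with an even
(zero-slope) boundary at cos γ = 0; interpolation error is below 1e-8
relative.

## Angular quadrature

All orientational integrals use n_θ evenly spaced midpoint polar angles
θ_j = (2j+1)π/(2n_θ) (defaults n_θ = 100, n_φ = 50). The weights attached
to these nodes are the Fejér first-rule weights for integration in
x = cos θ: the midpoint angles are exactly the Fejér-1 Chebyshev nodes, so
the rule is interpolatory and integrates polynomials in cos θ of degree
< n_θ exactly. Uniform rectangle weights at the same nodes would leave
O(3·10⁻⁵) errors in ⟨cos²θ⟩ at n_θ = 100; the Fejér weights make the
normalization and low moments exact to machine precision while keeping the
evenly spaced polar discretization. Azimuthal integrals use uniform
midpoints (spectrally accurate for periodic integrands).

Equilibrium distributions are azimuthally symmetric (director along θ = 0),
so solvers work with f(θ) vectors and the azimuthally pre-averaged kernel
K(θ,θ′) = (1/2π)∫ v_ex(cos γ) dΔφ, evaluated with the grid's n_φ uniform
offsets — identical to the full discrete double azimuthal sum for such
distributions (asserted to 1e-10 against the full (θ,φ) matrix on a small
grid). Known resolution limits: the discrete row average of the kernel
against f ≡ 1 is θ-independent only to quadrature accuracy (≲1e-9 at
defaults), and very sharp distributions (κ ≳ 10³ in exp(κcos²θ)) are
resolved by only a few polar nodes; at the packing fractions studied here
the equilibrium distributions have κ ≲ 10², which the default grid resolves
to better than 1e-6.

## Solvers

**Self-consistency** is solved by damped Picard iteration (default mixing
0.3, residual = max-norm of the normalized update, tolerance 1e-9, cap 10⁴
iterations), with exponent shifts to avoid overflow. f ≡ 1 is always a
fixed point; nematic solutions are seeded with f ∝ exp(20 cos²θ) or by
continuation from a neighboring solved state. A converged solution with
S < 10⁻³ is classified isotropic.

**Metastability limits.** The nematic limit is the lowest η at which a
nematic fixed point survives, located by bisection with branch
continuation. The isotropic limit (spinodal) is where the isotropic fixed
point loses linear stability: the Picard map linearized at f ≡ 1 is a small
matrix whose leading eigenvalue crosses 1 exactly where the free-energy
Hessian of the P₂ mode changes sign, so eigenvalue bisection locates the
spinodal without solving anything nonlinear.

**Pure coexistence** equates βP and βμ between branches. The nematic
branch is scanned downward from η = 0.70 in steps of 0.01 (with recursive
step refinement if the branch collapses mid-scan, since the μ-crossing can
sit just above the metastability limit); the isotropic density at matched
pressure is found by Brent on the monotone isotropic equation of state;
the sign change of Δμ is refined by Brent in η_nem and polished by a
two-variable Newton on (ρ_iso, ρ_nem). Residuals at the reported solutions
are below 1e-7 in reduced units. Spheres (or any system with no nematic
fixed point) raise a dedicated error.

## Binary mixtures

The mixture excess free energy is a pair sum
½ Σ_ij ρ_i ρ_j g_ij ⟨⟨f_i f_j v_ex,ij⟩⟩ whose coefficients g_ij(ρ_A, ρ_B)
derive from the BMCSL hard-sphere-mixture equation of state through the
total packing fraction n₃ = η_A + η_B and the equal-volume-sphere diameters
σ_i = (8c_i a_i²)^(1/3). The diagonal coefficients reduce exactly to the
pure Parsons–Lee prefactor when the other species vanishes; the cross
coefficients carry the dimensionless ratio 4σ_Aσ_B/(σ_A+σ_B)² — the unique
normalization that reproduces BMCSL's 3ξ₁ξ₂/(1−ξ₃) mixing term for hard
spheres and equals 1 for identical species (0.998 for the benchmark
mixture, so the asymmetry it encodes is mild). Cross pair excluded volumes
always use the rigorous integral (the Gaussian model has no heterogeneous
form). The 1/η_i singular pieces of g_AA, g_BB and their derivatives are
stored alongside the finite products (ρ_i g_ii, ρ_iρ_j ∂g_ij/∂ρ_k) that
the thermodynamics actually consumes, so vanishing-density limits are
evaluated without cancellation; near n₃ = 0 the common bracket
ln(1−n₃)/n₃² + 1/(n₃(1−n₃)²) switches to its series.

Design notes on this closure, established algebraically and enforced by
tests: the quadratic form Σ ρ_iρ_j g_ij collapses to the pure prefactor for
identical species at any composition split, and solved states collapse onto
the pure theory exactly in the isotropic phase and at a 50/50 nematic
split (up to the ideal entropy of mixing of the two labels). At unequal
nematic splits of identical species the two single-particle fields differ
at first order in η_A − η_B — the pair decomposition of the BMCSL cubic
term is not exactly a quadratic form — so the collapse there is approximate
(~10⁻⁴ relative for the benchmark geometry). Chemical potentials use the
dummy-index reading Σ_kl ½ρ_kρ_l (∂g_kl/∂ρ_i)⟨⟨f_k f_l v_ex,kl⟩⟩; both μ_i
and the pressure line are validated against finite differences of βF/V and
the mixture Gibbs–Duhem identity at solved states.

**Binary coexistence** solves four equations (equal pressure to the target
in both phases, equal μ_A and μ_B across phases) for the four packing
fractions by damped Newton in log space, with warm-started distributions
and graded penalty residuals outside the physical domain. The
pressure–composition band is traced by continuation from the pure-A
endpoint, anchored by the two pure-component transition pressures (both
expressed in species-A reduced units βP(8a_A²c_A)). Demixing is probed by
scanning the Gibbs free energy per particle βG/N at fixed pressure over
composition within each phase: convexity in x_A excludes a common-tangent
construction of two phases of the same character.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| n_θ × n_φ | 100 × 50 | polar × azimuthal nodes, both for the apse-sphere integral and the orientational grid |
| v_ex table | 201 nodes | uniform in cos γ ∈ [0,1], cubic interpolation |
| mixing | 0.3 | Picard under-relaxation |
| tol | 1e-9 | Picard max-norm residual |
| S threshold | 1e-3 | isotropic/nematic classification |
| z | required | 4 with the Gaussian kernel, 3 with the rigorous kernel |

Benchmark geometries used throughout tests and the acceptance script:
a = 3 nm with c = 8.25, 9, 12, 15 nm (aspect ratios 2.75–5), packing
fractions 0.3–0.7 — the regime where lyotropic nematics of short rods are
found. Coexistence solves at these defaults take 0.1–1 s each; the full
binary band takes a few seconds.

## Limitations

* Spatially homogeneous bulk phases only: no smectic or crystalline order,
  interfaces, confinement or external fields.
* Uniaxial prolate particles only (no oblate, biaxial, or spherocylinder
  geometries), binary mixtures at most.
* The theory is a second-virial functional with a density resummation:
  quantitatively reliable at moderate aspect ratios by construction of the
  resummation, not exact; mixture coefficients inherit the approximate
  pair decomposition of BMCSL discussed above.
* The demixing scan certifies convexity only on the composition grid
  probed; it is a falsification test, not a proof of global stability.
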