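# Methods

## The model

`memphase` treats a two-component fluid membrane (species *a* and *b*, one
molecule per site of a square lattice, equal molecular areas) as a lattice
binary mixture in the semi-grand canonical ensemble: the total number of
sites is fixed by the membrane area, and the species identity of each site
fluctuates under the relative chemical potential Δμ = μ_a − μ_b.  Through
the spin mapping σ_i = 2n_i − 1 the mixture is the 2D Ising model with

- coupling J = (2U_ab − U_aa − U_bb)/4, built from the nearest-neighbor
  pair energies, J > 0 required for demixing;
- reduced temperature T̄ = k_BT/J;
- reduced ordering field H̄ = [Δμ/2 − (U_aa − U_bb)]/k_BT.

Demixing into an a-rich (liquid-ordered, α) and a b-rich (liquid-disordered,
β) phase occurs along H̄ = 0, i.e. at Δμ = μ_αβ ≡ 2(U_aa − U_bb), for
T̄ < T̄_c.  All temperatures inside the package are carried as T̄ (or as
T/T_c with each backend's own T_c); all energies as multiples of k_BT.

An adhering membrane consists of two segments S[1], S[2] (area fractions
q1, 1 − q1) whose environments attract the two species with potentials
U_a[m], U_b[m] (attractive = negative, enforced, never auto-flipped).  Only
the relative affinities ΔU[m] = U_a[m] − U_b[m] matter, and of those only
the affinity contrast ΔU21 = ΔU[2] − ΔU[1], which shifts segment m's
transition to Δμ = μ_αβ + ΔU[m].  The CLI accepts the contrast in the
temperature-independent units ΔU21/(k_B T_c) and converts internally to
per-k_BT values by the factor T_c/T wherever the equilibrium relations need
them.

## Thermodynamic backends

Two interchangeable equations of state provide the binodals and (where
possible) the shifted chemical potential ΔG(X) = G(X) − μ_αβ in units of
k_BT:

**Exact-limit backend.**  T̄_c = 2/ln(1 + √2) ≈ 2.2692 and the spontaneous
order parameter ϒ(T̄) = [1 − sinh(2/T̄)^−4]^{1/8} (0 at and above T̄_c)
give the exact binodals X_β = ½ − ϒ/2, X_α = ½ + ϒ/2.  No closed form
exists off coexistence, so this backend cannot evaluate ΔG at finite field;
spectator compositions are available only as asymptotic limits (below).
Near T̄_c the bracket 1 − sinh(2/T̄)^−4 is evaluated as
−expm1(−4 ln sinh(2/T̄)) to avoid cancellation; the target of relative
error < 1e−10 for T̄ < T̄_c − 1e−8 is met.

**Mean-field backend.**  The Bragg–Williams per-site free energy of the
same interaction energy,

    f(X)/k_BT = X ln X + (1−X) ln(1−X)
                + (z/2)[U_aa X² + 2U_ab X(1−X) + U_bb (1−X)²]/k_BT,

differentiated in X and shifted by μ_αβ (which the derivative reproduces
exactly at X = ½, fixing the integration anchor), collapses every
interaction parameter into T̄:

    ΔG(X)/k_BT = ln(X/(1−X)) − (2z/T̄)(2X − 1),   z = 4.

The critical temperature is T̄_c^mf = z = 4.  Below it the raw curve has a
van der Waals loop; the physical branch replaces it by 0 on the coexistence
interval.  Because the curve is odd about X = ½, the equal-area (Maxwell)
construction and the common-tangent construction coincide with the
symmetric root construction — the test suite asserts the equal-area
integral vanishes numerically.

Mean-field binodals: for T̄ ≤ 3.9 the lower binodal is a bracketed root of
the raw ΔG on (0, ½), with lower bracket ½·exp(−2z/T̄) (the root's known
leading behavior).  For 3.9 < T̄ < 4 the equivalent self-consistency
m = tanh(zm/T̄) for the gap width m = X_α − X_β conditions better and is
solved in m; within 1e−8 of T̄_c^mf (relative) even that sits below the
tanh noise floor and the Landau expansion m² = 3(r−1)/r³ + (2/5)r²m⁴,
r = 4/T̄, is used (relative error O(δ²) ≤ 1e−16).  Root tolerances are
1e−13…1e−14 absolute in composition; interval endpoints carry a 1e−9
margin.

## Segment equilibrium

At overall composition X_a the two segment compositions solve

    q1·X_a[1] + (1−q1)·X_a[2] = X_a          (partitioning / lever rule)
    ΔG(X_a[1]) = ΔG(X_a[2]) + ΔU21/k_BT      (chemical equilibrium)

If segment 1 phase separates, ΔG(X_a[1]) = 0 and the other segment is a
uniform *spectator* at the root of ΔG(x) = −ΔU21 (sign +ΔU21 when segment 2
separates).  Monotonicity of ΔG places the spectator below X_β for a
negative right-hand side and above X_α for a positive one; it decreases
monotonically with the contrast on each branch and jumps across the
miscibility gap at zero contrast.  Roots are bracketed on the relevant
monotone branch; for strongly negative targets the root sits near
exp(target), which fixes the lower bracket at ¼·exp(target − 2z/T̄).  The
positive branch is solved by the odd symmetry x → 1 − x.

For the exact-limit backend the spectator takes its asymptotic values — the
adjacent binodal for "small" contrast, full saturation (0 or 1) for
"large" contrast — selected by an explicit caller flag, because only
asymptotic statements exist there, not a crossover value.

Classification proceeds in fixed order: (i) ΔU21 = 0 → whole-membrane
coexistence iff X_β ≤ X_a ≤ X_α (reported with a dedicated
`whole_membrane` flag rather than attributed to a segment); (ii) the
segment-1 window [q1·X_β + (1−q1)·X*₂, q1·X_α + (1−q1)·X*₂] in overall
composition; (iii) the symmetric segment-2 window; (iv) otherwise one
phase.  Windows are closed intervals (boundary points classify as
coexisting) and are asserted disjoint for nonzero contrast — they may touch
only in the small-contrast asymptotic limit.  q1 ∈ {0, 1} and X_a ∈ {0, 1}
reduce to the uniform-environment problem.

One-phase compositions: with the mean-field backend the two-equation system
is solved by an outer bracketed root search on X_a[1] (the residual is
monotone because ΔG is non-decreasing and X_a[2] decreases with X_a[1]),
inner closed-form X_a[2] from the lever rule, tolerance 1e−14; the lever
rule is restated exactly at output.  The exact-limit backend has no
off-coexistence ΔG, so its one-phase compositions are the corresponding
asymptotic rules: at large contrast the preferred segment fills (or
empties) completely before the other moves; at small contrast both
segments share the overall composition.

## Phase diagrams

Diagrams are tabulated on a T/T_c grid (default 200 points on
[0.05, 1.05], each backend normalized by its own T_c so the two backends'
axes align), with the two lever-projected segment windows and the uni-env
binodal interval per row.  Empty windows keep NaN sentinels so the CSV
schema is stable; numbers are written with 17 significant digits.
Consistency between window membership and pointwise classification is
tested on random (X_a, T) draws.

## Vesicle cap geometry

The appendix-level closed forms are re-derived from the spherical-cap
formulas: with c = cos θ_eff, A1 = 2πR²(1−c), A2 = πR²(1−c²),
h = R(1−c), V = (π/3)h²(3R−h), giving the scale-free

    q1 = 2/(3 + cos θ_eff),
    v  = V / [(4π/3)(A/4π)^{3/2}].

These reproduce every limiting value the theory pins down: q1 = ½
(pancake, θ→0), 2/3 (hemisphere), 1 (point contact, θ = π), and v = 1 for
the free sphere.  v(θ) is strictly increasing, so q1(v) follows by
bracketed inversion (round-trip verified to 1e−10).  Angles below 1e−7 rad
are rejected in the inversion: there the cap area underflows and such flat
shapes are outside the adhering-vesicle range ½ ≤ q1 < 1 anyway.

Strong adhesion: R_co = √(κ/2|W|) with W < 0 required;
|W|* = κ/(2L*²) with L* = 0.5 μm by default (optical resolution);
`in_strong_regime` additionally requires |W| to exceed the closure-tension
scale 2πκ/A by a factor of 10 — a documented, configurable margin standing
in for the asymptotic "much greater than".  k_BT conversions use
T_o = 298.15 K.

## Monte Carlo

Geometry: an L×L torus split by a column cut into two strips, q1 = c/L
(multiples of 1/L) — the simplest layout with both segments simply
connected and minimal boundary length.  Bonds crossing the two segment
interfaces are *included* by default (the membrane is physically
contiguous); they are the finite-size domain-boundary energy that the
thermodynamic limit drops, and a flag removes them to mimic fully
decoupled segments.

Moves are single-site species flips accepted with min(1, e^{−ΔE/k_BT})
(ΔE ≤ 0 short-circuits the exponential, so no overflow).  Unless raw
couplings are supplied, the symmetric convention u_aa = u_bb = −1/T̄,
u_ab = +1/T̄ is used, which puts μ_αβ = 0 and H̄ = Δμ/(2k_BT).  Randomness
comes from a single NumPy `default_rng` (PCG64) stream per run, consumed in
fixed-size blocks of site indices and uniforms: identical seed and
parameters reproduce the trajectory bit for bit.  The sweep kernel is
JIT-compiled with numba when available and falls back to the same pure
Python code otherwise.  Burn-in sweeps are discarded; observables are
recorded every `stride` sweeps and summarized with blocked standard errors
(16 blocks), a crude but standard decorrelation.

An exact-enumeration oracle sums all 2^N states (N ≤ 16) of the identical
energy function with log-sum-exp stabilization, giving exact per-segment
occupations and mean energies for cross-validation.

**Ergodicity limits and validation conditions.**  Local Metropolis
dynamics crosses between the two ordered basins at a rate that collapses
exponentially as the temperature drops below T̄_c.  On tiny lattices both
basins carry comparable statistical weight, so sampler-vs-enumeration
comparisons are only meaningful where the chain actually mixes: the
validation grid uses T̄ ∈ {2.0, 2.6, 3.2} with finite ordering fields
(12 parameter points, 60 000 measurement sweeps, checked on every
two-segment lattice up to 3×3 at three blocked standard errors).  At
T̄ = 1.5 the basin-crossing time on a 3×3 lattice already exceeds 10^5
sweeps and the comparison is not attempted.

**Spontaneous-order recovery.**  A uniform 64×64 lattice at T̄ = 2.0,
started from the all-a state under a weak positive field, reproduces the
exact ϒ(2.0) = 0.9113.  The field must break symmetry without biasing the
magnetization: linear response shifts ⟨m⟩ by χH̄ with χ ≈ 1 at this
temperature, so the check uses H̄ = 0.001, which keeps the shift at the
level of one statistical standard error (≈ 7×10⁻⁴ for 6 000 measurement
sweeps).  At H̄ = 0.01 the shift (≈ 6×10⁻³) is visible and the
corresponding example test carries a 0.025 allowance for it.  Run lengths
(5 000–7 000 sweeps of 4 096 sites) were chosen so each check completes in
seconds while the blocked errors stay well below the physical scales being
compared.

## Known limitations

- Equal molecular areas for both species (one lattice constant); no
  triangular or other lattices (z = 4 is a constant, not a parameter).
- No metastability, spinodals, interfacial tension, or finite-size shifts
  of the coexistence windows in the analytic modules.
- The mean-field backend's functional form of ΔG is a closure, not exact;
  only its anchors (value at X = ½, monotonicity, flatness on coexistence,
  T̄_c^mf = z) are guaranteed, so mean-field diagrams reproduce the
  topology of the exact ones, not their coordinates.
- The exact-limit backend interpolates nothing between its "small" and
  "large" contrast regimes; finite-contrast spectator values exist only in
  mean field.
- The Monte Carlo module demonstrates, but does not quantify, domain
  coarsening; conserved-composition (Kawasaki) dynamics and cluster
  updates are out of scope.
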