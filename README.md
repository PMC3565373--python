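# memphase

Phase behavior of adhering two-component membranes and vesicles.

Multi-component lipid membranes can demix into coexisting liquid-ordered
(α, cholesterol-rich) and liquid-disordered (β) fluid phases.  Adhesion —
of a vesicle to a substrate, of a membrane spanning holes or pores, or to a
chemically patterned surface — splits such a membrane into two segments
S[1], S[2] that sit in different environments.  `memphase` implements the
lattice-model thermodynamics of this situation for researchers in membrane
biophysics: it predicts which segment phase separates, at which overall
composition and temperature, and how the familiar single coexistence region
of a uniform-environment membrane splits into **two** coexistence regions
separated by an intermediate one-phase region whenever the two environments
recruit the lipid species differently.

## Model in brief

The membrane is a lattice binary mixture (occupation n_i = 1 for an
a-molecule) in the semi-grand canonical ensemble, equivalent to the 2D
Ising model with reduced temperature T̄ = k_BT/J,
J = (2U_ab − U_aa − U_bb)/4, and ordering field
H̄ = [Δμ/2 − (U_aa − U_bb)]/k_BT.  On the square lattice the critical
temperature T̄_c = 2/ln(1+√2) ≈ 2.269 and the spontaneous order parameter
ϒ(T̄) = [1 − sinh(2/T̄)⁻⁴]^{1/8} give the exact binodals
X_{a,β/α} = ½ ∓ ϒ/2.

Each segment m feels its environment through the relative affinity
ΔU[m] = U_a[m] − U_b[m]; only the affinity contrast ΔU21 = ΔU[2] − ΔU[1]
enters the phase behavior, alongside the segment area fraction q1, the
overall mole fraction X_a and T̄.  Segment compositions obey the lever rule
q1·X_a[1] + (1−q1)·X_a[2] = X_a and chemical equilibrium
ΔG(X_a[1]) = ΔG(X_a[2]) + ΔU21, where ΔG is the shifted chemical potential
of either the exact Ising backend or a Bragg–Williams mean-field backend.
While one segment phase separates the other is a uniform "spectator"
phase.  For adhering vesicles, a spherical-cap module maps contact angle ↔
area fraction q1 = 2/(3 + cos θ_eff) ↔ reduced volume, and a Metropolis
Monte Carlo module samples the exact two-segment lattice energy for
validation.

Full derivations and numerical choices are in `docs/methods.md`.

## Worked example

Classify a membrane at overall cholesterol-like fraction X_a = 0.3,
temperature T/T_c = 0.88, with 70 % of its area unbound (q1 = 0.7) and a
positive affinity contrast of 0.5 k_BT_c:

```sh
$ memphase classify --xa 0.3 --t-over-tc 0.88 --q1 0.7 --du21 0.5 --backend meanfield
{
 "Xa1": 0.39588815551395407,
 "Xa2": 0.07626097046744057,
 "Xa": 0.3,
 "q1": 0.7,
 "t_bar": 3.52,
 "du21": 0.5681818181818182,
 "phase": "coex_segment_1",
 "whole_membrane": false,
 "spectator_segment": 2,
 "spectator_x": 0.07626097046744057
}
```

Segment 1 phase separates (`coex_segment_1`): its composition 0.396 lies
inside the mean-field miscibility gap at this temperature, while the bound
segment is a uniform spectator phase at X_a[2] = 0.076, depleted of
a-molecules because the positive contrast makes them prefer segment 1.
The lever rule 0.7·0.396 + 0.3·0.076 = 0.300 is satisfied exactly.

The same library calls are available in Python:

```python
from memphase import get_eos, solve_state, contrast_per_kBT

eos = get_eos("meanfield")
state = solve_state(0.3, 0.88 * eos.tc, 0.7, contrast_per_kBT(0.5, 0.88), eos)
print(state.phase, state.Xa1, state.Xa2)
# coex_segment_1 0.39588815551395407 0.07626097046744057
```

Vesicle geometry and adhesion strength:

```sh
$ memphase geometry --theta-deg 90
{"theta_eff_deg": 90.0, "q1": 0.6666666666666666, "v": 0.7698003589195008, ...}
$ memphase adhesion --kappa-j 1e-19 --w-mj-per-m2 -0.01
{"Rco_m": 7.07e-08, "W_star_mJ_per_m2": 2e-04, "kappa_in_kBT_room": 24.29, "strong_adhesion": true}
```

A hemisphere has unbound area fraction 2/3 and reduced volume 0.770; a
typical lipid bilayer (κ = 10⁻¹⁹ J ≈ 24 k_BT) adheres strongly once
|W| exceeds 2×10⁻⁴ mJ/m².

Other subcommands: `binodal` (coexistence curves of either backend),
`diagram` (full two-segment phase diagram as CSV/JSON), `mc` (seeded
Metropolis runs), `fixtures` (deterministic test fixtures).

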