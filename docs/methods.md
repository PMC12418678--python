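# Methods

This note records the model conventions, numerical choices and known
limitations of `mmfit`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Pseudo-atom model

Each atom contributes

ρ_atom(**r**) = P_c ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_l κ′³ R_l(κ′r) Σ_m P_lm d_lm(Ω),

with **r** measured from the nucleus and the angular functions oriented in
the atom's local frame.

* **Radial databank.** Core and valence *densities* (not orbitals) are
  stored as Slater sums Σ cᵢ r^{nᵢ} e^{−ζᵢ r}; published orbital tables can
  be pre-squared into this schema offline.  The embedded "synthetic" bank
  (H, C, N, O, Mg, Cl) uses node-less single-ζ Slater shells with plausible
  effective exponents — H 1s and all 1s² cores keep their physical cusps
  (n = 0), second-row valence shells are squared 2s/2p STOs and therefore
  pure r² e^{−2ζr} terms with *no* density cusp at the nucleus, third-row
  valence r⁴ terms.  These are not Clementi–Roetti or Su–Coppens–Macchi
  values; any element can be supplied through the documented text schema.
  Deformation radials are single-exponential, R_l = N r^{n_l} e^{−ζ_l r}
  with N = ζ^{n+3}/(n+2)! and the conventional powers n_l = (2,2,3,4) for
  l = 1..4 on heavy atoms and (1,2) on hydrogen; one ζ_l (= the element's
  deformation exponent) serves all l.
* **Angular functions.** d_lm are density-normalized real spherical
  harmonics: d_00 = 1/4π and ∫|d_lm| dΩ = 2 for l ≥ 1, so P_lm carries the
  conventional meaning of transferred electrons.  The normalization
  constants are computed at import by piecewise Gauss–Legendre quadrature
  between the zeros of the associated Legendre functions (reproducing e.g.
  d_10 = cosθ/π to machine precision) rather than hard-coded.
* **Population convention.** The stored valence density integrates to the
  neutral-atom electron count n_val (a load-time quadrature invariant);
  evaluation scales it to a per-electron density so that P_val = n_val is
  the neutral atom.  The analytic atom charge is P_c·n_core + P_val + P_00;
  all l ≥ 1 terms integrate to zero by orthogonality.
* **Constraints.** Hydrogens carry only bond-oriented m = 0 multipoles up
  to quadrupole (local z along H→X); heavy atoms go to hexadecapole.
  Chemically identical hydrogens share κ and κ′; symmetry-equivalent atoms
  may share all populations (the hexaaqua-magnesium built-in ties its six
  oxygens and twelve hydrogens).  P_core is fixed at 1 and never refined;
  an l = 0 deformation population is supported but off by default to avoid
  degeneracy with (P_val, κ) in least squares.  κ′ is one parameter per
  atom shared across l (a per-l variant is not offered; the per-atom
  reading is standard practice).

## Structure factors and refinement

* Fourier convention F(H) = ∫ρ e^{+2πi H·r_frac} dV on the integer lattice
  of a pseudo-cubic cell (default edge 30 Å), resolution s = |H|/2a with
  0 < s ≤ s_max (origin strictly excluded, upper bound inclusive — the
  boundary convention is harmless and deterministic).  A Friedel-unique
  hemisphere is available and is the default for synthetic cases (complex
  F of a real density carries no extra information in the other half).
* ⟨j_l⟩ transforms of Slater radials use the Rayleigh closed form for
  n ≥ l, switched below q < 0.6ζ to the Taylor series in q (the closed
  form loses digits there to cancellation); n < l falls back to 200-point
  Gauss–Legendre on [0, 60/ζ].  The two routes agree to 1e-10 (tested).
* Refinement is damped Gauss–Newton on the packed parameter vector (ties
  collapsed, fixed excluded): analytic Jacobian columns for the linear
  population parameters, central finite differences (step 1e-6) for κ/κ′,
  backtracking line search (so the accepted residual sequence is monotone),
  κ-type parameters clipped to (0.5, 2).  Residual modes: `complex`
  (default — theoretical phases are known) and `modulus` (amplitude
  fitting, the convention of experimental programs); both recover ground
  truth in the tests, and which one production refinement programs use is
  not knowable from their output, so both ship.  Unit weights; scale k
  fixed at 1.  Slots whose Jacobian column is structurally zero (κ′ of an
  atom whose multipoles are still all zero at the IAM start) are frozen for
  that iteration; a genuinely singular reduced normal matrix raises an
  error naming the null-space parameters.  No electroneutrality constraint
  by default (F(000) is excluded, so total charge is only weakly
  constrained); an optional Σ P_val constraint is available.

## Grids, ESP and comparison statistics

* Grids follow the Gaussian cube convention (isotropic step, z fastest).
  "270 steps" in the production grid recipe is read as 270 points per axis
  (269 intervals), which makes the printed point count (270³ = 19 683 000)
  and edge (269 × 0.094486 = 25.416734 bohr) hold simultaneously.  Grid
  origin defaults to the geometric centroid minus half the edge; it is
  recorded in the cube header and JSON sidecar.
* The ESP electron term is evaluated per atom and per radial component by
  the inside/outside multipole decomposition with incomplete-gamma closed
  forms.  On grids the radial potentials are tabulated on a 4000-point
  logarithmic mesh and linearly interpolated (observed error ≲ 1e-4 a.u.
  near nuclei, ~1e-6 relative elsewhere); `exact=True` evaluates closed
  forms pointwise and is used in the Poisson-equation test.  A grid point
  within 1e-6 bohr of a nucleus gets the nuclear term at a 1e-6 bohr
  offset — deterministic and affecting at most isolated points.
* Basins: on-grid near-grid steepest ascent, voxels processed in order of
  decreasing density, steepest (Δρ/distance) 26-neighbor ascent with
  lexicographic tie-break; boundary voxels are corrected by a vectorized
  gradient-trajectory pass.  Attractors are matched to the nearest nucleus
  (non-nuclear attractors > 1 bohr away are recorded as warnings; spurious
  secondary attractors of an atom are merged).  Voxels below 1e-10 e/bohr³
  are "escaped" but still counted to the nearest attractor so that basin
  populations sum to the grid integral exactly (up to float summation
  order, asserted at 1e-12 relative).
* Unified basins: basins are generated once on the reference density and
  both densities are integrated over them; ΔN of a field against itself is
  then identically zero, which is the point of the construction.
* Surfaces: marching-cubes level sets of the reference density with
  area-weighted ESP means at triangle centroids (trilinear interpolation);
  an unweighted point-sampled mode exists for cross-checking and agrees to
  ~1% on smooth cases.  ME/MAE/RMSE are computed pointwise over the surface
  between the system ESP and the reference ESP sampled at the same
  centroids.  ESP is atomic units internally; the kcal/mol/e conversion
  constant is exposed for reporting only.

## Synthetic reference generator

The generator emulates the inputs of a databank-building pipeline: a
seeded ground-truth multipole model (P_val = n_val + U(−0.2, 0.2) adjusted
per tie group so Σ(P_val − n_val) = −net_charge exactly; P_lm ~ U(−0.1,
0.1) under the hydrogen truncation rules, with each atom's largest |P_lm|
kept ≥ 0.03 so κ′ is always identifiable; κ, κ′ ~ U(0.85, 1.15)), plus an
optional non-representable deformation: per bond, a +0.05 e Gaussian
(σ = 0.35 bohr) at the midpoint compensated by −0.025 e Gaussians on the
two bonded atoms.  Bump structure factors and ESP use the exact closed
forms of the Gaussian (transform e^{−σ²k²/2}, potential erf(r/σ√2)/r), so
the target carries no grid error.  Built-in geometries (water, ammonia,
alanine, octahedral [Mg(H₂O)₆]²⁺) are idealized literature-typical
structures with X–H bonds normalized to average neutron-diffraction
lengths (C–H 1.089, N–H 1.015, O–H 0.967 Å); the magnesium complex is
built from one template water replicated by octahedral rotations so its
symmetry ties are exact.  All randomness flows through one seeded
generator; identical spec ⇒ bit-identical case.

What a green test does and does not establish: the generator spans the
multipole parameter space and a controlled non-representable residual, so
recovery and ordering tests validate the fitting machinery and the
comparison statistics; it does not emulate basis-set-specific wavefunction
differences, core polarization, or experimental noise, so it says nothing
about which quantum-chemical protocol best feeds a databank.

Known limitations of the synthetic world:

* An MM density with finite multipoles dips slightly negative in tail
  lobes (unlike a wavefunction density); basin analysis tolerates this by
  treating such voxels as escaped, and validation only rejects fields with
  min < −0.05·max or a non-density `kind`.
* Hydrogen density maxima of MM references are shallow and ~0.2 bohr wide
  (no core term, κ < 1 draws, negative atom-site bumps); on grids coarser
  than ~0.1 bohr the on-grid basin search may not resolve them, and the H
  basin then merges into its heavy-atom neighbor.  The acceptance script
  therefore uses a ~0.1 bohr step; desk-scale 96³ tests accept the merge.

## Acceptance properties

The production benchmark numbers (R factors, CC values, ΔN and surface-ESP
errors per quantum-chemical basis set) require external wavefunctions and
are out of scope.  The acceptance suite checks instead: the grid contract
(270³ points, 25.416734 bohr edge); exact parameter recovery from the IAM
start on all four built-ins (30 Å cell, s ≤ 0.7 Å⁻¹, recovery to 1e-6,
R < 1e-8); analytic-vs-FFT oracle agreement to 1e-3 e on 96³ grids;
conservation identities; closed-form limits (⟨j₀⟩(ζ) = ¼, point-charge
surface average q/r, Gaussian iso-surface radius √(ln 10)); and the
nested-model ordering R(MM) < R(IAM), MAE(MM) ≤ MAE(IAM) per level on
perturbed cases.

One acceptance case is genuinely unattainable and left red: the 96³
FFT-oracle bound of 1e-3 e for [Mg(H₂O)₆]²⁺.  By Poisson summation the
point-sampling error of the oracle is the sum of the molecular transform
at alias frequencies and is independent of grid alignment; the six oxygen
valence shells (density exponent 8.8 bohr⁻¹) would need a cell < 9.5 Å to
push that sum below 1e-3 e at 96³, while the twelve diffuse hydrogen tails
need ≥ 11 Å of cell to keep periodic wrap-around below the same bound.
The best achievable cell (11.5 Å) leaves a floor of ~1.4e-3 e.  The other
three geometries pass with 3–8× margin.
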