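# mmfit

Hansen–Coppens multipole models fitted to static structure factors, with a
charge-density comparison suite: crystallographic R factor, electrostatic
potential (ESP) correlation, unified QTAIM basin populations and
surface-averaged ESP statistics.

## The problem

Transferable pseudo-atom databanks are built by fitting the Hansen–Coppens
multipole model (MM) to simulated X-ray diffraction of model molecules in a
large pseudo-cubic cell: a reference electron density (in production work, a
DFT wavefunction) is converted to valence-only static structure factors,
and the MM parameters are refined against them by least squares.  Whether
the fitted MM actually *recreates* the reference charge density — not just
its structure-factor amplitudes — is then judged with density-space
statistics.  `mmfit` implements that whole loop as a reusable library, with
a seedable synthetic reference generator standing in for the wavefunction
stage so every step is testable offline.

The pseudo-atom density is

```
ρ_atom(r) = P_c ρ_core(r) + P_val κ³ ρ_val(κr)
          + Σ_{l=0}^{l_max} κ′³ R_l(κ′r) Σ_m P_lm d_lm(θ, φ)
```

with Slater-type radial functions (`R_l(r) = N r^{n_l} e^{-ζ_l r}`,
`∫R_l r² dr = 1`), density-normalized real spherical harmonics `d_lm`, and
refinable populations `P_val`, `P_lm` and radial screening parameters
`κ, κ′`.  Heavy atoms are expanded to hexadecapoles, hydrogens to
bond-oriented (m = 0) quadrupoles with shared κ/κ′ for chemically identical
hydrogens.  Structure factors are evaluated analytically
(`F(H) = Σ_A e^{2πi H·x_A} [P_c f_core + P_val f_val(q/κ) +
Σ_lm P_lm 4π i^l ⟨j_l⟩(q/κ′) d_lm(Ĥ)]`) with Fourier–Bessel transforms
`⟨j_l⟩` in closed form, and cross-checked against a grid-FFT oracle.  The
agreement statistic is `R = Σ||F_obs| − k|F_calc|| / Σ|F_obs|` with the
scale k fixed at 1.

The comparison suite mirrors production charge-density analysis:

* **Pearson correlation** of ESP grids;
* **unified QTAIM basins** — gradient-ascent basins are generated once on
  the *reference* density and both densities are integrated over the same
  basins, so the population differences ΔN per atom are free of
  basin-boundary ambiguity;
* **surface-averaged ESP** on iso-density surfaces (0.1, 0.05, 0.01,
  0.001, 0.0001 a.u. by default) with ME / MAE / RMSE error metrics.

## Worked example

```python
from mmfit import SyntheticSpec, generate_case, run_comparison

spec = SyntheticSpec(geometry_name="water", seed=1, nonrepresentable=True)
case = generate_case(spec, a=15.0, s_max=0.5)   # pseudo-cell 15 A, s <= 0.5 1/A
report = run_comparison(case)
print(report.r_factor, report.iam_baseline["r_factor"])
print(report.pearson_cc)
for s in report.surface_stats:
    print(s.level, s.v_mean, s.mae)
```

For this seed the pipeline prints (via `scripts/acceptance.py --seed 1`):

```
R(MM) = 8.635e-04   R(IAM) = 2.206e-01
ESP Pearson CC(MM) = 0.999959   CC(IAM) = 0.996468
level 0.1:    Vbar_S = +0.35765 a.u.  MAE = 6.10e-03
level 0.05:   Vbar_S = +0.19183 a.u.  MAE = 5.45e-03
level 0.01:   Vbar_S = +0.03941 a.u.  MAE = 5.42e-03
level 0.001:  Vbar_S = -0.00066 a.u.  MAE = 6.02e-03
level 0.0001: Vbar_S = -0.00454 a.u.  MAE = 5.22e-03
```

Reading: the reference here is a known ground-truth MM plus a small
charge-neutral bond-density feature the multipole form cannot represent, so
the fitted MM reaches R ≈ 9·10⁻⁴ (not zero) while the spherical-atom IAM
baseline stays at R ≈ 0.22; the MM's ESP correlates with the reference to
0.99996 and its surface-ESP error is a few mhartree/e on every iso-level —
an order of magnitude below the IAM's.  `Vbar_S` is the area-weighted mean
ESP of the surface; the sign flip between the 0.01 and 0.001 a.u. levels is
the usual crossover from the nuclear-dominated to the electron-dominated
region.

A command-line interface wraps the same stages:

```sh
mmfit generate --geometry water --seed 1 --out case/     # synthetic bundle
mmfit refine   --case case/ --out refined.txt
mmfit run      --case case/ --out report                 # end-to-end
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch — it generates a seeded synthetic water case (ground-truth model +
non-representable bond bumps), refines the MM from the IAM start against
the valence-only structure factors, rebuilds density and ESP grids at a
~0.1 bohr step, and prints the R factors, ESP correlation, unified-basin
populations and per-level surface statistics — then writes the results
object to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
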