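# fieldhb

Analysis pipeline for molecular-dynamics trajectories of solvated
proteins driven by an oscillating electric field: forced-oscillation
dielectric spectroscopy, hydrogen-bond detection and counting,
hydrogen-bond time-correlation functions, and reactive-flux rate
constants under both the Luzar–Chandler model and an extended
three-rate model.  A synthetic-data module generates every input with
known ground truth, so each stage is verifiable by parameter recovery
without running any MD.

## Who this is for

Simulators studying non-thermal microwave effects on protein solutions:
you have (or can generate) trajectories of a solvated protein under a
field **E**(t) = E₀·cos(ωt)·ẑ, or plain dipole time series, and want
the complex dielectric function per component and the field's effect on
hydrogen-bond kinetics in the first hydration shell.

## The models

**Forced-oscillation dielectric extraction.**  In the linear regime each
component k of the system (protein, water, …) responds harmonically,

    M_k(ω, t) = A_k(ω)·cos(ωt) + B_k(ω)·sin(ωt),

and the in-phase/quadrature amplitudes, obtained by closed-form
ordinary least squares on {cos ωt, sin ωt, 1}, give the complex
dielectric function

    ε′_k(ω) − 1 = A_k / (ε₀ V E₀),        ε″_k(ω) = B_k / (ε₀ V E₀),

with V the cell volume.  Replicate runs are averaged before fitting;
totals sum component contributions with the vacuum term counted once.

**Hydrogen-bond kinetics.**  Bonds are detected geometrically
(donor–acceptor distance ≤ 3.2 Å for protein–water, ≤ 3.5 Å for
water–water/protein–protein; D–H···A angle in 150–180°).  For each pair
the indicators h(t) (bonded), H′(t) (within the reformation cutoff) and
Q(t) (slightly beyond it, r ≤ R_max after the first break) define the
correlation functions S, C, N, F over all bonded time origins.  The
reactive flux k(t) = −dC/dt is regressed (non-negative least squares)
on

    k(t) = k₁·C(t) − k₂·N(t)              (Luzar–Chandler)
    k(t) = k₁·C(t) − k₂·N(t) − k₂′·F(t)   (extended, scheme QF′ ↔ B ↔ QF)

giving the total breaking rate k₁, the reformation rates k₂ and k₂′,
and the bond lifetime ζ = 1/k₁.  Multi-exponential fits of C, N, F
yield the amplitude-weighted relaxation times τ_C, τ_N, τ_F.

**Structure and shells.**  Cα RMSD after Kabsch superposition, per-residue
RMSF/ΔRMSF about the time-averaged structure, radius of gyration, and a
first-hydration-shell density estimate from an ellipsoid model of the
protein (gyration-tensor semi-axes aᵢ = √(5λᵢ), 3 Å shell).

## Worked example

Generate stochastic hydrogen-bond trajectories from the three-state
kinetic scheme (2000 pairs, breaking rates k₁ = 0.40, k₁′ = 0.05 ps⁻¹,
reformation k₂ = 0.70, k₂′ = 0.05 ps⁻¹, escape 0.02 ps⁻¹), estimate
the correlation functions, and fit both kinetic models:

```sh
fieldhb synth hbonds --n-pairs 2000 --t-total 150 --seed 42 --out sim
fieldhb hbond correlate --pairs-csv sim/pair_states.csv --max-lag 40 --out corr
fieldhb hbond fit --corr-csv corr/correlations.csv --model extended --out fit
fieldhb hbond fit --corr-csv corr/correlations.csv --model LC --out fit_lc
```

prints

```
wrote 2000 pair trajectories to sim/pair_states.csv
wrote 81 lags to corr/correlations.csv
extended: k1=0.472 k2=0.7369 k2p=0.0587 zeta=2.119 ps
LC: k1=0.4914 k2=0.8193 k2p=0 zeta=2.035 ps
```

The extended fit recovers the total breaking rate k₁ + k₁′ = 0.45 ps⁻¹
within ~5 % (the residual offset is the finite-difference error of
−ΔC/Δt at the 0.5 ps frame spacing) and fits the flux with a much
smaller residual than the two-rate model — the same behaviour seen on
real protein–water bond networks under field.  ζ is the mean bond
lifetime in ps.

The same stages run from Python (`fieldhb.gen_hb_trajectories`,
`fieldhb.correlate`, `fieldhb.fit_rates`), and the dielectric stages
likewise (`fieldhb synth dipole`, `fieldhb dielectric fit`, or
`fieldhb.gen_debye_dipole` → `fieldhb.fit_harmonic` →
`fieldhb.to_dielectric`).

## Layout

- `src/fieldhb/synthetic.py` — ground-truth generators (forced/Debye
  dipoles, Gillespie bond kinetics, toy trajectories)
- `src/fieldhb/io.py` — PDB/DCD/XTC reading, charges, selections, CSV/JSON
- `src/fieldhb/dielectric.py` — dipole series, harmonic fits, ε(ω)
- `src/fieldhb/hbonds.py` — geometric detection, shells, counts, density
- `src/fieldhb/kinetics.py` — S/C/N/F, reactive flux, rate and
  multi-exponential fits
- `src/fieldhb/structure.py` — RMSD/RMSF/Rg
- `src/fieldhb/cli.py` — the `fieldhb` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
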