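# Methods

## Scope and data model

The pipeline analyses MD trajectories of a solvated protein under a
homogeneous oscillating electric field, or tabular dipole/bond-state
series standing in for them.  Internal units are Å, ps, e, e·Å and
mV/Å throughout; SI constants enter only inside the dielectric
conversion (`fieldhb.units`), and the composed internal→SI→internal
round trip is the identity to 1e−12 relative.  Cells are orthorhombic
and all interatomic distances use the minimum-image convention.

## Forced-oscillation dielectric extraction

A field E(t) = E₀·cos(ωt) along ẑ drives each component's dipole
projection into the steady state M(t) = A·cos(ωt) + B·sin(ωt).  The
fit is ordinary least squares on the basis {cos ωt, sin ωt, 1} — a
linear problem solved in closed form, with standard errors from the
residual variance.  Design choices:

* **Offset term.**  The harmonic response model has no constant, but a
  protein carries a permanent dipole; the offset absorbs it and never
  enters the dielectric conversion.  Removing any static dipole before
  fitting is therefore implicit.
* **Replicates.**  Replicate runs sharing a time grid are averaged
  pointwise first, then fitted (maximises SNR); per-replicate fits
  remain available for variance estimation.
* **Span checks.**  Less than one field period is an error (the fit is
  ill-posed); less than three periods sets a `few_periods` flag rather
  than failing, since low-frequency runs may only cover one cycle.
* **Charged selections.**  A net-charged group's dipole is
  origin-dependent; it is computed about the selection's centre of
  charge (weights |q|), restoring translation invariance.  The
  convention is recorded in the series metadata and a warning is
  emitted.
* **Totals.**  ε of the mixture sums the per-component (ε′_k − 1)
  contributions and adds the vacuum 1 exactly once; the imaginary
  parts sum directly.  Ionic components are excluded from totals by
  default, mirroring the conductivity-removal practice of dielectric
  spectroscopy.
* **Confidence regions.**  `HarmonicFit.covers` uses the joint
  chi-square ellipse on (A, B) from the 2×2 fit covariance; two
  marginal intervals would undercover the pair.

The amplitudes map to one dielectric point via ε′ − 1 = A/(ε₀VE₀),
ε″ = B/(ε₀VE₀), with standard errors propagated linearly.

## Hydrogen-bond geometry

A bond is a (donor, hydrogen, acceptor) triple with minimum-image
donor–acceptor distance within the class cutoff — 3.2 Å protein–water,
3.5 Å water–water and protein–protein — and D–H···A angle (vertex at
H, 180° linear) in [150°, 180°].  All N/O atoms with a covalently
attached hydrogen (≤ 1.25 Å, same residue) donate; all N/O accept; the
element lists are configurable.  Each triple is evaluated
independently, so two hydrogens of one donor can form two bonds.
Detection is vectorised on MDAnalysis minimum-image kernels and is
validated against an exhaustive triple-scan oracle in the tests.

First-shell (S1) membership: a water belongs to S1 when its oxygen
lies within 3.5 Å (configurable) of any protein heavy atom — the
water–water cutoff reused as the natural contact distance, since no
standard definition pins this choice.  A water–water bond counts as a
"WS1" bond when both partners are S1 members.

**Count fluctuations** are the cumulative population variance of the
count series from the window start up to each time point; a
trailing-window variant sits behind the `rolling` mode.

**Shell density** approximates the protein as the uniform ellipsoid
sharing its gyration tensor: semi-axes aᵢ = √(5λᵢ) from the heavy-atom
gyration eigenvalues λᵢ, shell volume (4π/3)[Π(aᵢ+d) − Πaᵢ] at
thickness d = 3 Å (the experimentally supported shell width), density
= S1 water mass / shell volume, and the excess is quoted against bulk
water at 996.516 kg/m³ (27 °C).  The ellipsoid construction is a
modelling choice; the density is sensitive to both the membership
cutoff and d, so excess-density values should be compared only across
conditions analysed with identical settings.

## Hydrogen-bond kinetics

For each pair ever bonded in the window, three indicators are tracked:
h (bonded), H′ (donor–acceptor distance within the reformation cutoff
R_PW — the class cutoff: quasi-free, QF), and Q (broken and slightly
beyond the cutoff, R_PW < r ≤ R_max: the QF′ state).  R_max is the
distance recorded at the first frame after that pair's first breaking —
a per-pair quantity tied to the frame recording rate; a global-R_max
mode exists behind a flag.  For water–water bonds the 3.5 Å class
cutoff plays the role of R_PW, which keeps h = 1 ⟹ H′ = 1 exact per
class.

The estimators

    S(τ) = ⟨h(t₀)·H(t₀+τ)⟩/⟨h⟩      (H = continuously bonded since t₀)
    C(τ) = ⟨h(t₀)·h(t₀+τ)⟩/⟨h⟩
    N(τ) = ⟨h(t₀)·[1−h]·H′⟩/⟨h⟩
    F(τ) = ⟨h(t₀)·[1−h]·[1−H′]·Q⟩/⟨h⟩

average over every bonded origin t₀ with t₀+τ inside the window
(origin stride configurable).  Numerators and denominators are exact
integer counts, so the estimate equals exhaustive origin enumeration
bitwise.  F is computed at pair level, with the same ⟨h⟩ denominator
as C and N, which keeps the three regressors of the extended model on
one scale.  Hard invariants checked after every estimate: S(0)=C(0)=1,
N(0)=F(0)=0, 0 ≤ S ≤ C ≤ 1, and the origin-matched monotonicity bound
S(τ+Δ) ≤ S(τ)·n(τ)/n(τ+Δ) — with per-lag origin sets, plain
monotonicity of S can be broken by origin depletion at the window tail
even for a correct estimator, while this bound cannot.

**Reactive flux and rates.**  k(t) = −dC/dt by central finite
differences (one-sided at the ends; second-order accurate, which on
smooth fixtures dominates the error budget — at the standard 0.5 ps
frame spacing with ~0.5 ps⁻¹ rates it biases k₁ by ≈ 5 %).
Non-negative least squares fits k(t) against [C, −N] (Luzar–Chandler)
or [C, −N, −F] (extended); the fitted k₁ estimates the *total*
breaking rate of the three-state scheme, and ζ = 1/k₁ is the reported
lifetime.  Defaults: fit window 0.5–30 ps (excludes the less accurate
lag-0 derivative and the noise-dominated tail; always echoed in the
report), equal weights (no error model is imposed on the flux).  An
identically vanishing regressor (e.g. F ≡ 0 on data with no QF′
population) is dropped with its rate set to zero, so the extended
model nests Luzar–Chandler exactly; a genuinely collinear design
raises an error carrying the condition number.

**Relaxation times.**  C, N, F are fitted with Σaᵢ·exp(−t/τᵢ)
(1–4 terms) by separable nonlinear least squares: the time constants
are optimised in log space, the amplitudes are the exact non-negative
linear solution at every step, and eight deterministic multi-starts
guard against local minima.  τ_w = Σaᵢτᵢ/Σaᵢ (amplitude weighting,
the standard reading of a weighted relaxation time); the integral
weighting Σaᵢτᵢ²/Σaᵢτᵢ is available behind a flag.

## Synthetic ground truth

* **Forced dipole** — A·cos(ωt) + B·sin(ωt) + η(t) with η either white
  Gaussian or an exactly discretised Ornstein–Uhlenbeck process
  (thermal dipole noise in MD is autocorrelated; white is the τ→0
  limit).  Replicate r draws from seed + r: bitwise reproducible,
  independent replicates.
* **Debye fixture** — an overdamped dipole with one relaxation time τ
  driven in the linear regime.  The deterministic part is the exact
  steady-state response (A, B amplitudes on the closed-form Debye
  curves); the noise is OU with the same τ and the stationary variance
  the fluctuation–dissipation theorem assigns, ⟨δM²⟩ = Δε ε₀ V k_B T.
  Defaults emulate the study conditions: E₀ = 4.2 mV/Å, the
  48.10×52.40×66.65 Å³ cell, 20 replicates, 8 periods at 64
  samples/period.
* **Bond kinetics** — exact Gillespie sampling of QF′ ↔ B ↔ QF with an
  absorbing "lost" state reachable from QF and QF′ at one rate
  k_escape (the minimal mechanism giving C, N, F their long-time
  relaxation; whether QF′ can escape directly is exposed as a switch,
  default on).  Every pair starts in B, which defines t = 0.  States
  are read off the frame grid right-continuously; for a fixed seed the
  continuous-time paths are independent of the grid, which the
  dt-halving convergence test exploits.  The standard fixture
  (k₁ = 0.40, k₁′ = 0.05, k₂ = 0.70, k₂′ = 0.05, k_escape = 0.02 ps⁻¹;
  5000 pairs, 150 ps at 0.5 ps) mirrors protein–water bond kinetics
  scales.
* **Toy frames** — PDB+DCD+charge-sidecar micro-trajectories with
  donor–H–acceptor triplets placed at exact distance and angle, for
  the geometry and structure stages.

What the generators do *not* emulate: a real hydrogen-bond network's
spatial correlations, exchange between bonding partners, force-field
detail, or conformational coupling.  Passing recovery tests therefore
demonstrates the correctness of the estimators and fits under the
stated kinetic/response models, not the models' adequacy for any
particular protein.

## Structure metrics

Superposition is the SVD (Kabsch) solution with a determinant guard
against reflections; correspondence is by atom identity.  RMSF uses
the time-averaged structure as reference, refined by three
align-and-average passes.  Rg is mass-weighted by default.  RMSD
curves against a crystal reference assume superposition before the
deviation; a fixed-frame variant is available
(`superposition=False`).

## Numerical and testing notes

* Simulation sizes in tests and the acceptance script (100 harmonic
  trials, 13-frequency Debye sweep, 20 kinetic seeds at 5000 pairs)
  are chosen so the full battery completes in a couple of minutes on
  one CPU while leaving Monte-Carlo error well below the tolerances
  checked.
* Correlation estimators are compared bitwise against triple-loop
  enumeration; geometry against an O(N³) scan with hand-rolled
  minimum-image arithmetic; superposition against a random
  rotation-grid search; rate fits against analytic master-equation
  curves (dense matrix exponentials).
* DCD files cut mid-frame are detected by byte bookkeeping (the
  underlying reader would silently drop the partial frame) and
  reported with the index of the incomplete frame.
* Degenerate inputs fail loudly: empty selections, missing charges on
  a dipole computation, < 1 field period, no bonded origins, < 4 heavy
  atoms for a gyration tensor, zero shell thickness.

## Known limitations

* Orthorhombic cells only; no triclinic minimum image.
* The finite-difference flux biases rate constants at coarse frame
  spacing (quantified above); refine the grid when absolute rates
  matter.
* The ellipsoid shell-density model inherits the ambiguity of both the
  S1 membership cutoff and the shell thickness.
* No conductivity term, no Cole–Cole/Havriliak–Negami model fits, no
  fluctuation–dissipation (equilibrium) spectra: the dielectric route
  here is purely the driven, non-equilibrium one.
* No secondary-structure assignment and no per-residue kinetics maps.
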