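# Methods

## Scope and model

`permeus` computes membrane permeability coefficients from biased
sampling along the membrane normal *z* under the one-dimensional
inhomogeneous solubility–diffusion model (ISDM). The chain of estimators
is

    umbrella windows → WHAM → G(z)
    restrained runs  → ACF  → D(z)
    G, D             → R(z) = exp(β ΔG(z))/D(z) → P = 1/∫ R dz

with β = 1/k_BT and k_B fixed at 0.0019872041 kcal/(mol·K). All
energies are kcal/mol, lengths Å, times ps, temperatures K; permeability
is converted to cm/s (∫R dz in ps/Å × 10⁻⁴ = s/cm).

The package does not run molecular dynamics. Its synthetic module
generates data with exactly the statistical structure the estimators
assume, so every stage can be validated against closed-form ground
truth; applying the analysis to real MD output only requires the
umbrella time series in the supported text dialect.

### Modified ΔG reference

ΔG(z) is referenced to the *global PMF minimum*, not to bulk water. For
peptides that bind the membrane interface this counts escape from the
bound state as part of the permeation barrier. Two endpoint
permeabilities follow from the minimum position z_min:

* **P_flip**: integration from z = 0 (membrane center) to z_min — the
  rate of reaching the bilayer midplane from the bound state;
* **P_out**: integration from z_min to z_bulk (default 37.5 Å) — escape
  back into water.

When z_min > 30 Å there is no interfacial bound state and P_out is
undefined. The headline value combines the defined endpoints; the
default rule is the rate-limiting `min(P_flip, P_out)`, configurable
(`"flip"`, `"out"`), because a single reported permeability must pick
one convention and the conservative choice is the slower channel. Ties
in the PMF minimum break toward bulk (the longer, more conservative flip
path). The one-leaflet profile can be mirrored about z = 0
(`symmetrize`) under the assumption of a symmetric bilayer.

## WHAM

Standard self-consistent 1D WHAM on histogram counts, iterated in log
space (logsumexp) until the largest change in any window free energy is
below `tol` (default 10⁻⁷ kcal/mol, `max_iter` 10⁵). Defaults: 0.5 Å
bins spanning the sampled range; harmonic biases in the *half*
convention U = ½k(z−z₀)² (the `full` convention is converted on input
because umbrella tools disagree and data files rarely say which they
use). Burn-in is a fraction knob (default 0) rather than assumed —
equilibration may or may not have been discarded upstream.

Degenerate inputs are hard errors, never patched silently: adjacent
windows whose histograms share no occupied bin, or empty interior bins,
raise `InsufficientOverlapError` naming the gap (silent interpolation
would hide exactly the sampling failures WHAM exists to expose).
Non-convergence is flagged on the result object and warned about.

PMFs are reported min-zero (the reference the resistance integrand
needs); `Profile.anchored(z_bulk)` re-references to bulk for plotting.
Convergence error is the per-bin standard deviation of two WHAM solves
on the first and second halves of every series, each min-zero aligned;
`mae_between_profiles` compares profiles after min-zero (or explicit
anchor) alignment, making constant offsets invisible by construction.

The 2D PMF over (z, auxiliary observable) applies the converged 1D
per-frame unbiasing weights w_t ∝ [Σ_k N_k e^{f_k − βU_k(z_t)}]⁻¹ to a
2D histogram; unvisited bins are NaN, not zero. Because the 2D route
weights frames by the bias at their actual coordinate while the 1D route
bins first, the two agree to binning error (≲0.05 kcal/mol at 0.5 Å
bins), which the tests assert.

## Diffusion estimator

For a window restrained at z_i,

    D(z_i) = ⟨δz²⟩² / ∫₀^t_c C_zz(t) dt ,  C_zz(t) = ⟨δz(0) δz(t)⟩,

i.e. variance over integrated autocorrelation time. The ACF uses the
biased (1/N) normalization — integrable and monotone-variance — and the
integral is truncated at t_c, the first lag where the ACF either crosses
zero or falls below 1% of the variance, whichever comes first.
Truncating only at an actual zero crossing of a noisy ACF tail waits for
accumulated positive noise to dip negative and biases D low by ~10% on
realistic run lengths; the 1% cutoff removes that conditioning bias at
the price of a ~1% truncation error (e^{−4.6}). A cutoff at or before
one sampling interval (white-noise-like input) raises `EstimationError`
— the estimator needs resolved correlations.

D(z) profiles interpolate *log D* linearly between window centers
(diffusivity varies multiplicatively across the interface and must stay
positive) with constant extrapolation beyond the outermost centers.
Repeat estimates at one center — the protocol runs the restrained stage
twice from different snapshots — combine by geometric mean with the
spread of log₁₀D kept as the uncertainty.

Benchmark run lengths: at k = 2.5 kcal/mol/Å² and 300 K the restrained
relaxation time is τ = k_BT/(kD); 40 ns resolves D = 0.1 Å²/ps to
well within 10%, while D = 0.01 (τ ≈ 24 ps) needs 160 ns for the same
relative error. The recovery tests use exactly these lengths.

## Synthetic generator

Overdamped (Brownian) dynamics — not inertial Langevin — because only
the stationary density exp(−β(G+U)) and the local D(z) matter to the
estimators downstream. The Euler–Maruyama step is

    z ← z + [−βD(z)(G+U)′(z) + D′(z)]·dt + √(2D(z)dt)·ξ,

with the spurious-drift term D′(z) from the analytic derivative;
without it, position-dependent D would bias the recovered PMF by
k_BT ln D(z) (≈1 kcal/mol across the presets), and the stationarity test
certifies precisely this term. Boundaries reflect at z = 0 and z_bulk
(one leaflet is sampled; symmetry is handled downstream). A step larger
than 5 Å aborts with an integration error naming dt; a drift·dt check
warns before that.

Presets are sums of Gaussians plus a bulk plateau (smooth,
differentiable, controllable minima): `popc_like` has a 4 kcal/mol
central barrier, a −2.5 kcal/mol interfacial minimum at 12 Å and a
1 kcal/mol head-group peak at 25 Å, with D dropping log-sigmoidally from
0.1 Å²/ps in bulk to 0.02 inside; `chol50_like` is monotone toward the
center (no interfacial minimum, the high-cholesterol morphology);
`square_barrier` is a smoothed step (softness 0.5 Å); `flat` is free
diffusion. Amplitudes are on the scale of bare-membrane peptide PMFs;
D values are typical small-solute membrane diffusivities.

Replica exchange swaps configurations between adjacent windows with
Metropolis probability min(1, e^{−βΔU}), alternating even/odd pairs
each epoch (the standard neighbor scheme). Every attempt is logged
(ΔU, uniform draw, outcome) so detailed balance is auditable after the
fact. The two-segment production schedule (1.0 Å/1.5 kcal·mol⁻¹Å⁻²
then 1.5 Å/0.5) accepts ~30% of swaps on the presets; the documented
`exchange_band_schedule` (uniform 1.5 Å, k = 1.0) lands in the 10–20%
band. Solute tempering exists only as λ = T_sys/T_eff arithmetic and
replica-count bookkeeping — the toy sampler has no temperature
dimension, and which pairs would alternate across a joint
(window × temperature) grid is left outside its scope.

The two-state conformer generator emits, per frame, a state label
(closed with probability p(z), a sigmoid decreasing toward bulk),
von-Mises dihedrals about per-state means (closed carries one cis ω,
open is all-trans), and a 3D frame from the state's template plus 0.03 Å
jitter. The templates are *synthetic stand-ins*, not real molecules:
four N–H···O units on a 12 Å square, hydrogen-bonded and carbon-shielded
in the closed state (4 intramolecular H-bonds, lower polar surface
area), broken and exposed in the open state (0 H-bonds, higher PSA).
Ground-truth labels are retained so the metric estimators can be scored.

What the generator does **not** emulate: inertia and memory effects,
anisotropic/2D diffusion, orientation or conformation as slow degrees of
freedom orthogonal to z, solute-tempering exchange, and real molecular
geometry. Passing tests therefore certify the *estimators* under the
model's own assumptions, not the accuracy of the 1D ISDM for any real
peptide.

## Metrics

* **H-bonds**: geometric criterion, donor-heavy→acceptor distance
  ≤ 3.5 Å AND D–H···A angle at the hydrogen ≥ 135°, both configurable
  (the common trajectory-analysis defaults; the source protocols rarely
  state theirs). Brute-force over all role-assigned pairs; verified
  against an independently coded oracle on 1000 random frames.
* **SASA/PSA**: numeric Shrake–Rupley sphere sampling (deterministic
  golden-spiral points, default 960) rather than the analytic LCPO
  overlap formula — pluggable, simpler, and equally testable at this
  scale; exact on isolated spheres, within 0.5% of the two-sphere cap
  formula. PSA sums accessible area over N and O atoms (probe 1.4 Å).
* **Dihedral PCA**: frames embedded as (sin, cos) of every (φ, ψ, ω) —
  6 dimensions per residue, avoiding the ±180° wrap — centered,
  eigendecomposed; projections, orthonormality and explained-variance
  bookkeeping follow.
* **Closed fraction**: default classifier is the intramolecular H-bond
  count (≥3), which transfers across systems; a PC1-box classifier
  (bounds configurable, the historical [2, 3] box available) is provided
  but marked dataset-specific since the box must be read off each
  system's projection.
* **cis ω**: |ω| < 90°, with exactly 90° counted trans (declared
  boundary).
* **Short-axis tilt**: angle between the largest-eigenvalue principal
  inertia axis and z, folded to [0°, 90°]; unit masses by default
  (whether the original analysis mass-weighted is unstated — the option
  exists). Degenerate top eigenvalues raise.
* **Area per lipid**: lateral box area / lipids per leaflet.

## Numerical choices and benchmark budgets

* WHAM bins 0.5 Å, tol 10⁻⁷ kcal/mol, max_iter 10⁵ (unstated upstream;
  declared and configurable).
* Brownian benchmarks: PMF recovery uses the 28-window schedule with
  exchanges every 10 ps; the square-barrier benchmark runs 60 ns/window
  at dt = 0.025 ps (barrier height recovered to ≲0.1 kcal/mol,
  seed-spread ≈0.08), the membrane-like benchmark 40 ns/window at
  dt = 0.05 (PMF RMS ≈0.06 kcal/mol). dt is chosen so the
  Euler–Maruyama discretization bias at the steepest preset feature
  stays well below the statistical error.
* End-to-end log₁₀P agrees with fine-grid quadrature on the true
  closed-form G, D to ≈0.05–0.1, dominated by the D(z) estimates.
* Permeability integrals are trapezoidal on the profile grid with
  linearly interpolated endpoints; halving the grid step changes P by
  <1% on smooth profiles.

## Known limitations

One-dimensional reaction coordinate only (no multidimensional ISDM, no
orientation coupling); no unstirred-water-layer or solubility
corrections; no MBAR estimator (WHAM only); biases are 1D and harmonic;
the CLI's synthetic stages cover one leaflet and assume bilayer
symmetry. Uncertainties are two-point half-split standard deviations —
honest convergence indicators, not full posterior errors.
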