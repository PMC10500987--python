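# Methods

This note documents the models, estimators and numerical conventions
implemented in `evbkit`, the defaults and why they were chosen, and the
limits of what the built-in toy system can demonstrate.

## Two-state EVB energies

The reacting system is described by two diabatic states whose energies
ε₁ and ε₂ come from classical force fields; the product diagonal
carries a constant gas-phase shift Δα accounting for the difference in
formation free energy between the two bonding patterns, which force
fields do not describe.  The ground state is the lowest eigenvalue of
the 2×2 secular problem (`evbkit.core.ground_state_energy`), evaluated
in closed form with `hypot` for numerical robustness.  It satisfies
E_g ≤ min(H₁₁, H₂₂) with equality exactly when H₁₂ = 0; this bound, the
swap symmetry in (H₁₁, H₂₂), the sign-invariance in H₁₂, and covariance
under uniform energy shifts are enforced by property tests.

The coupling element H₁₂(r) = A·exp(−μ(r−r₀) − η(r−r₀)²) supports
exponential, Gaussian and constant forms.  **Default: constant**
(μ = η = 0).  Calibrated EVB couplings in the literature are single
constants per reaction, constants leave stored trajectories exactly
reanalyzable, and an r-dependent coupling requires choosing a coupling
coordinate (interatomic distance or the gap), which is a per-study
modelling decision.  The r-dependent forms are evaluable everywhere but
are not calibrated.

Δα is applied to the product diabat only — inside H₂₂, inside the
mapping potential and inside the gap coordinate.  A constant shift does
not change forces, so trajectories sampled at one Δα remain valid
Boltzmann samples at any other: this is what makes calibration pure
post-processing.

Units are kcal/mol and Å internally; kJ/mol and nm appear only in
files (conversion factor 4.184 exactly).  β uses
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹.

## Free-energy estimators

**Mapping FEP.**  ΔG along V(λ) is accumulated per adjacent window pair
by exponential averaging of −β·Δε·Δλ, where Δε = (ε₂+Δα) − ε₁ per
frame.  The per-step estimate is the arithmetic mean of the forward
average (over window n) and the backward average (over window n+1,
negated).  The mean of the two directions is the simplest estimator
that cancels the leading (Gaussian) hysteresis bias; acceptance-ratio
estimators would be more statistically efficient but are out of scope.
All exponential averages are evaluated by log-sum-exp, so finite inputs
can never overflow; "exact" algebraic identities (zero-variance
collapse, gas-shift additivity) hold to 10⁻¹⁰ relative and are tested
at that tolerance.

**Umbrella projection.**  Configurations are binned on
X_s = ε₁ − (ε₂+Δα), the generalized reaction coordinate, with the
reactant basin at negative X_s (it is sampled at λ = 0 where ε₁ is
low).  The per-window, per-bin contribution is

    ΔG_m(X_s) = ΔG(λ_m) − β⁻¹ ln ⟨ 1_s · e^{−β(E_g − V_m)} ⟩_m ,

where the indicator average runs over **all** frames of window m
(frames outside the bin contribute zero to the numerator but stay in
the normalization).  With this whole-window normalization every
window's contribution estimates −β⁻¹ln(ground-state Boltzmann mass of
bin s) up to one global constant, so the subsequent count-weighted
combination across windows is consistent: it converges to the exact
binned free energy.  A per-bin-conditional average would instead carry
a window-dependent β⁻¹ln P_m(s) term that does not fully cancel and
measurably biases the barrier (≈ 0.06 kcal/mol on the default toy
model — larger than the replicate standard error).

**Combination and normalization.**  Per bin, contributions are averaged
with weights p_m = n_{m,s}/Σ_m n_{m,s}.  Bins with fewer than
`min_count` total configurations are flagged invalid but kept; bins
with no contributing window are excluded with a warning.  The profile
is shifted so the reactant-side minimum (the lowest valid bin left of
the profile's global maximum) is zero.  ΔG‡ is the global maximum of
the valid profile minus the reactant minimum, ΔG0 the product-side
minimum minus the reactant minimum; ties break toward the smaller
|gap|, making the output deterministic.  A profile whose maximum sits
at an edge raises a no-barrier error rather than reporting a
meaningless number.

**Binning defaults: 50 uniform bins over the observed gap range,
minimum 30 configurations per valid bin.**  Published analyses do not
state their bin width or count cutoff, so these are declared package
defaults, exposed as parameters: 50 bins resolve the default model's
profile to ≈ 4 kcal/mol of gap per bin while keeping thousands of
counts per central bin; 30 counts keeps the log of a Monte-Carlo
average out of its heavy-tailed small-sample regime.

## The toy system

`evbkit.toy` provides a 1D two-diabat model: each diabat is a harmonic
or Morse well plus an optional soft exponential repulsion
C·e^{−βᵣr} and a constant offset.  Sampling is Metropolis — for
configurational averages on V(λ) nothing more is needed, and it
requires no force code.  Proposals are uniform of half-width
`step_size`; moves leaving the coordinate range are rejected, so the
stationary density is exp(−βV) restricted to the range, which is also
the oracle's integration domain.  Randomness comes from two
pre-generated numpy streams per window, keyed by a SeedSequence over
(seed, window index): identical seeds give bit-identical trajectories,
on any platform, independent of the compiled kernel.

Windows are chained — window m+1 starts at the final coordinate of
window m — mimicking consecutive simulations; replicas differ only by
seed, mimicking randomized initial velocities.

**Default model.**  Two harmonic diabats, k = 220 kcal mol⁻¹ Å⁻²,
minima at 0 and 1 Å, product offset 4.15 kcal/mol, constant coupling
A = 15 kcal/mol, coordinate range [−1, 2] Å, T = 300 K.  At these
values the quadrature oracle gives ΔG‡ = 16.52 and ΔG0 = 4.00 kcal/mol
— the scale of a slow enzymatic hydride/proton transfer.  The force
constant is deliberately stiff: with soft wells (k ≈ 100) the same
coupling leaves a barrier of only ≈ 3.8 kcal/mol, comparable to the
free-energy rise in the sampled basin tails, and barrier extraction by
global maximum becomes ill-posed.  The offset was fixed once from the
oracle so that ΔG0 ≈ +4 kcal/mol.  The model is illustrative: it has a
single coordinate, no solvent reorganization, no donor–acceptor
restraints shaping the sampling, and harmonic (not dissociative)
diabats, so agreement on it validates the estimator chain, not any
force field.

**Sampler defaults.**  10⁵ steps per window, step 0.15 Å (≈ 40–50%
acceptance for the default wells), 1000-step burn-in, stride 10 —
9900 frames per window, 51 windows, ≈ 0.5 M frames per replica, a few
seconds of compute.  Five replicas give a replicate SEM of
≈ 0.005–0.01 kcal/mol on ΔG‡.

**Oracle.**  `exact_gap_profile` integrates e^{−βE_g} on a dense
uniform grid (20 001 points by default; trapezoid end-point weights)
and bins the mass on X_s with the same edges as the estimator.
Doubling the grid changes ΔG‡ by < 10⁻³ kcal/mol on the default model
(asserted in the tests).  Reported per-bin counts are *expected*
counts under each window's mapping-potential density, so the oracle's
valid-bin mask matches the estimator's in expectation; without this
the oracle would report free energies in gap regions the windowed
sampler never visits, where the estimator has no data at all.  Note
the oracle is exact for the *binned* free energy: at a diabatic cusp
(A = 0) the binned barrier approaches the seam height from below as
bins refine, and the tests assert exactly that convergence.

## Calibration

`calibrate` finds the constant coupling A and shift Δα whose
reanalyzed profile reproduces reference (ΔG‡, ΔG0) — by pure
reanalysis of stored frames, as justified above.  The solver is a
damped Newton iteration on the two-component residual with
forward-difference Jacobian (step 0.5 kcal/mol in each parameter,
falling back to backward differences when a probe lands in a
barrier-free region), step halving when the residual norm fails to
decrease, and clamping of negative-A excursions.  If the starting
coupling is so strong that the profile has no barrier at all, A is
halved until one appears before iterating.  Defaults: tolerance
0.01 kcal/mol, 50 iterations maximum.  Every success is re-verified by
an independent evaluation before returning; non-convergence raises an
error carrying the best parameters and residuals seen.  Near a
solution the system is well conditioned — ∂ΔG0/∂Δα ≈ +1 and
∂ΔG‡/∂A < 0 — and round trips from guesses displaced by ±20 kcal/mol
in both parameters converge in ≈ 3 iterations.

When several replicas are available, calibration runs on the pooled
(replicate-averaged) data rather than per replica; the parameters are
then consistent with the averaged profile that is usually reported.

## Arrhenius decomposition and replicate statistics

ΔG‡(T)/T regressed on 1/T (ordinary least squares) gives ΔH‡ as the
slope and −ΔS‡ as the intercept; R² is the squared Pearson
correlation.  Results carry full precision — rounding to the 2–3
decimals conventional in publications is left to display.  One
consequence worth noting: for the five-temperature dehydrogenase
series used in the tests, TΔS‡ at 283 K is −5.22 kcal/mol from the
unrounded intercept but −5.09 from the 3-decimal-rounded ΔS‡ = −0.018;
the package reports the unrounded value.

Replicate spread uses the sample standard deviation (n−1 denominator)
and SEM = SD/√n.  These conventions reproduce, at two decimals, every
published SEM in the replicate tables that the test suite encodes
(n = 20 and n = 30 replicate sets).

## Topology emission

Per-window topologies realize V(λ) in an MD engine that only scales
parameters linearly in λ.  Two conventions, both stated in emitted
headers:

* interactions present in both end states (charges, harmonic bonds,
  angles, periodic dihedrals, shared Morse bonds) are interpolated
  parameter by parameter, p(λ) = (1−λ)p_RS + λp_PS;
* interactions present in one state only — breaking/forming Morse
  bonds and the soft repulsions replacing their 6–12 terms — are
  emitted as type-9 tabulated bonds referencing shared unit-scale
  table files, with the state weight (1−λ or λ) on the bond line, so
  their contribution to V(λ) is exact per window.  Angles/dihedrals
  present in one state have their force constants scaled by the state
  weight instead (a three/four-body term cannot be tabulated as a pair
  potential).

Zero-weight interactions are omitted, so the λ = 0 and λ = 1 files
reproduce the input topologies interaction for interaction (asserted
by re-parsing).  Only a constrained single-molecule dialect is
supported — harmonic bonds (funct 1), Morse (funct 3), tabulated
(funct 9), harmonic angles, periodic dihedrals, pairs, exclusions —
and anything else, including preprocessor directives, is rejected with
a line-numbered error.  Writers are deterministic byte for byte.
Table files hold r (nm), energy (kJ/mol) and −dE/dr (kJ/mol/nm) on a
uniform grid (default 0.002–1.0 nm, 0.002 nm spacing; the lower bound
drops to 0 for repulsions, which are finite at contact).

## Known limitations

* Two states only; no multi-state Hamiltonians, no analytic forces.
* The FEP/umbrella chain assumes adjacent-window overlap; calibrating
  far from the sampling parameters relies on reweighting and will
  degrade silently if Δα moves the gap range faster than the windows
  cover it (the binning is recomputed per evaluation to keep frames in
  range).
* The toy model's agreement with its oracle validates estimator
  algebra and statistics, not the physics of any condensed-phase
  system: no solvent, no restraints, no multidimensional reaction
  coordinate.
* Replicate SD/SEM is the only error model; block averaging and
  autocorrelation-aware estimators are not provided.
* The topology dialect is a deliberately small subset of the GROMACS
  grammar; it is meant for generated files, not for parsing arbitrary
  hand-written topologies.
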