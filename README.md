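# evbkit

Empirical valence bond (EVB) free-energy machinery for reaction
simulations: two-state ground-state energies, free-energy perturbation
(FEP) along a λ-mapping potential, umbrella projection onto the
energy-gap reaction coordinate, calibration of the coupling element and
gas-phase shift against reference free energies, and Arrhenius
decomposition of activation free energies into ΔH‡ and ΔS‡.

The package is aimed at people who run (or analyze) EVB simulations of
enzymatic and solution reactions — e.g. hydride/proton transfers in
dehydrogenases or isomerases — and want the post-processing chain from
windowed end-point energies to ΔG‡/ΔG0 in one tested place.  A built-in
one-dimensional two-diabat model with a seeded Metropolis sampler and an
exact quadrature oracle exercises every stage end to end, so no MD
engine is required to use, test or extend the machinery.

## The model

A reaction step is two valence-bond (diabatic) states with force-field
energies ε₁ (reactant) and ε₂ (product), coupled in a 2×2 Hamiltonian

    H = [[ε₁, H₁₂], [H₁₂, ε₂ + Δα]]

whose lowest eigenvalue

    E_g = ½(H₁₁ + H₂₂) − ½√((H₁₁ − H₂₂)² + 4H₁₂²)

is the adiabatic ground-state surface.  The coupling H₁₂ and the
gas-phase shift Δα are the two calibrated, phase-independent parameters;
H₁₂ = A·exp(−μ(r−r₀) − η(r−r₀)²) can be an exponential, a Gaussian, or a
flat constant (μ = η = 0, the default).

Sampling is driven by the mapping potential

    V(λ) = (1 − λ)ε₁ + λ(ε₂ + Δα),   λ: 0 → 1 in small increments,

(51 windows by default).  The free energy along the mapping potential is
accumulated by exponential (Zwanzig) averaging between adjacent windows,
averaged over the forward and backward directions to cancel hysteresis;
per frame, V_{n+1} − V_n = Δε·Δλ with Δε = (ε₂ + Δα) − ε₁.  Each
window's configurations are then binned on the generalized reaction
coordinate X_s = ε₁ − (ε₂ + Δα) and reweighted onto the ground state,

    ΔG_m(X_s) = ΔG(λ_m) − β⁻¹ ln ⟨1_s · e^{−β(E_g − V_m)}⟩_m ,

and bins are combined across windows with the normalized count weights
p_m.  ΔG‡ and ΔG0 are read off the resulting profile, and barriers
computed at several temperatures decompose through an Arrhenius plot of
ΔG‡/T vs 1/T (slope ΔH‡, intercept −ΔS‡).

## Worked example

Sample the built-in double-well model over 51 windows, analyze it, and
recalibrate the Hamiltonian to chosen reference values — all from the
shell:

```sh
$ evbkit simulate --out demo --seed 11
wrote 51 windows to demo

$ evbkit analyze --input demo --out demo/res
dG_act = 16.538 kcal/mol, dG_rxn = 3.989 kcal/mol (48 valid bins)

$ evbkit calibrate --input demo --dg-act 16.0 --dg-rxn 3.5 --out demo/cal.json
A = 15.4089, delta_alpha = -0.5000 (1 iterations)
```

The analyze step prints the activation barrier (profile maximum minus
reactant minimum) and reaction free energy (product minus reactant
minimum) of the sampled profile; for the default model the exact
quadrature values are ΔG‡ = 16.52, ΔG0 = 4.00 kcal/mol, and the sampled
numbers agree within the replicate standard error.  The calibrate step
reanalyzes the *same* stored trajectories (no resampling — a constant
coupling and gas shift do not change the mapping forces) and finds the
(A, Δα) pair whose profile reproduces the requested 16.0/3.5 within
0.01 kcal/mol.

Barriers measured at several temperatures decompose into enthalpy and
entropy:

```sh
$ evbkit arrhenius temperatures.tsv
{
  "dh_act_kcal_mol": 10.515419968507835,
  "ds_act_kcal_mol_K": -0.01843935293670408,
  "r_squared": 0.977341586666701
}
```

for a table of five (T, ΔG‡) rows — here a cold-adapted dehydrogenase
whose barrier rises from 15.46 kcal/mol at 273 K to 16.19 at 313 K,
giving ΔH‡ = 10.52 kcal/mol and a large entropic cost TΔS‡ ≈ −5.2
kcal/mol at 283 K, the signature thermodynamics of a psychrophilic
enzyme.

The same operations are available as a library (`evbkit.toy`,
`evbkit.fep`, `evbkit.calibrate`, `evbkit.thermo`), plus writers for
per-λ GROMACS-dialect topologies and type-9 tabulated bond files
(`evbkit.topology`) and an XVG energy-series reader/writer
(`evbkit.xvg`).  See `docs/methods.md` for the numerical conventions.

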