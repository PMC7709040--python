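# Methods

## Model

`stokesrad` estimates the translational diffusion coefficient of a small
molecule in solution from its 3-D structure alone. The chain of
approximations is:

1. **Conformer ensemble.** A flexible solute populates many conformations.
   Stable conformers are generated by stochastic distance-geometry
   embedding (RDKit ETKDGv3) followed by MMFF94 force-field optimization.
   Conformers with relative energy ΔE ≥ 3 kcal/mol above the minimum are
   discarded: at 298 K a conformer at the 3 kcal/mol boundary carries a
   Boltzmann population below 1 % of the minimum-energy conformer
   (exp(−3/RT) ≈ 0.0063), so the window loses essentially no population.
   Retained conformers receive weights w_i ∝ exp(−ΔE_i/RT),
   R = 1.98720425×10⁻³ kcal/(mol·K).

2. **Grid shape.** Each conformer's shape is the union of atomic van der
   Waals spheres (Bondi radii; hydrogens included), discretized as the set
   of cubic-grid points whose centers fall inside at least one sphere.
   From the n occupied points at spacing h:
   - van der Waals volume V_vdw = n·h³;
   - radius of gyration r_g = √(Σᵢ|pᵢ − centroid|²/n), mass uniform over
     the points.

3. **Two radii.**
   - simple radius: V_vdw = 4/3·π·r_s³, the equal-volume sphere;
   - effective radius: r_e = K·r_g with K = √(5/3) ≈ 1.29, the radius of
     the uniform sphere having the molecule's r_g (for a sphere of radius
     R, r_g = √(3/5)·R, so K closes the loop and r_e = r_s exactly for a
     sphere). Because the sphere minimizes r_g at fixed volume,
     r_e ≥ r_s for every real conformer; the gap measures anisometry.
     Empirically r_e tracks the hydrodynamic radius of strongly hydrated
     solutes (sugars), while r_s works better for amino acids and drugs.

4. **Averaging order.** Per-conformer radii are Boltzmann-averaged
   *before* the Stokes–Einstein conversion; averaging per-conformer D
   values instead would be systematically larger (1/r is convex; a test
   demonstrates the gap on a two-conformer fixture). Anomeric mixtures
   (d-glucose, α:β = 36:64 in water) combine the per-anomer ensemble
   averages by mole fraction, after each anomer's Boltzmann average.

5. **Physics.** D = k_B·T/(6π·r·η₀) with k_B = 1.380649×10⁻²³ J/K.
   Defaults: water at T = 298 K, η₀ = 0.8902 mPa·s. Radii in Å, D
   reported in 10⁻⁶ cm²/s. The one-dimensional mean-square displacement
   is 2·D·t.

## Ionization conventions

Carboxylic acids are kept neutral (–COOH) and basic amines protonated
(–NH₃⁺ etc.), applied as SMARTS-driven edits: carboxylates are
neutralized, aliphatic primary/secondary/tertiary amines gain a proton,
guanidines are protonated once on the imine nitrogen (guanidinium).
Amides, sulfonamides, anilines and aromatic nitrogens are untouched, as
are sulfonate charges as drawn (Fast Green FCF is modelled as the free
dye anion, net −2, without counterions — a choice, since counterion
handling in solution is not defined by the convention). This is a fixed
convention, not a pKa model; no tautomer or speciation logic is applied.
Arginine consequently carries +2 (α-ammonium plus guanidinium); the
extra proton is irrelevant at grid resolution.

## Empirical corrections (opt-in)

- **Concentration shift.** Literature infinite-dilution coefficients D₀
  exist only for sugars; for the other compounds D₀ is derived as
  D_c + 0.65×10⁻⁶ cm²/s, where 0.65 is the mean D₀ − D_c gap calibrated
  on the six sugars with both values (`benchmark.calibrate_shift`), not a
  hard-coded constant.
- **Bias correction.** The preferred-channel estimates (D_e for sugars,
  D_s otherwise) sit mostly below D₀; shifting them by +0.25×10⁻⁶ cm²/s
  toward D₀ reduces the mean absolute residual over the 18 reference
  compounds from 0.29 to 0.17×10⁻⁶ cm²/s. The direction is "toward D₀";
  it is exposed as a signed parameter because the correction is purely
  empirical.
- **Small-radius factor.** For solutes with r_s below ~3 Å the continuum
  Stokes picture underestimates D; a ×1.1 multiplier (alanine-calibrated)
  is available but off by default.

## Numerical choices

- **Grid spacing** defaults to 0.2 Å; at 0.1 Å the sphere/union oracles
  agree with closed forms to <1 %, and molecule-sized solids are
  converged to about the same level at 0.2 Å. Occupancy is tested at
  grid-point centers only (no partial-cell weighting) — refinement is by
  spacing, not by cell weights.
- **Radii set**: Bondi (1964), overridable via a config table validated
  to (0.5, 3.0) Å.
- **Embedding count** scales with flexibility: min(500, 60 + 40·n_rot)
  trials, seeded, so runs are deterministic per seed.
- **Deduplication**: conformers within 0.5 Å heavy-atom best-fit RMSD of
  a kept lower-energy conformer are dropped (symmetry-aware alignment,
  match cap 500). Survivorship is energy-ordered, so the global minimum
  always survives.
- **Energy window** boundary is strict (<); the minimum conformer is
  always retained, so the window can never empty an ensemble.
- **Display rounding** is half-up at 2 decimals (report tables);
  full precision is kept internally.

## What the reference table and statistics show

The packaged 18-compound table (8 sugars, 6 amino acids, 4 drugs —
Fast Green FCF classed as a drug by molecular-weight convention) stores
radii, both D channels, D₀/D_c and signed deviations; load-time
validation recomputes every deviation cell (within printed rounding,
0.005) and every derived D₀ (D_c + calibrated shift). The summary
statistics ("average deviation" = mean absolute deviation throughout)
are: sugars D_e vs D₀ 0.27; non-sugars D_s vs D₀ 0.30, 0.24 excluding
alanine; bias-corrected pooled residual 0.17 (all ×10⁻⁶ cm²/s). The
D_s/D_e ratio (= r_e/r_s) runs from ~1.1 (compact monosaccharides) to
~1.35 (the elongated Fast Green dye).

## Conformer engine caveat

The ensemble is generated by ETKDG + MMFF94, an open-source stand-in for
the commercial Low Mode MD + MMFF94x engine used when the reference
radii were produced. Conformer *counts* are therefore engine-dependent
and treated as indicative only (tests assert NoC ≥ 1, never exact
counts); ensemble-averaged radii are robust to the engine at roughly the
±0.1 Å level (recomputed sugar r_s values land within ~0.04–0.08 Å of
the reference column). Problem sizes used in the test suite — eight
sugars end-to-end at spacing 0.2 Å, seed 1 — were chosen as the smallest
set that exercises mixtures, mono- vs disaccharide trends and the radius
ordering invariant.

## Limitations

- No explicit solvent: hydration is folded into the K coefficient and the
  empirical channel rule (r_e for strong hydrators), not modelled.
- No entropy: populations use force-field potential energies, not free
  energies; no solvent-phase reoptimization.
- No pKa/tautomer logic; the ionization conventions are fixed.
- The Stokes–Einstein sphere picture itself degrades below r ≈ 3 Å
  (hence the opt-in small-radius factor) and for strongly non-spherical
  solutes (the single K cannot capture ellipsoidal friction).
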