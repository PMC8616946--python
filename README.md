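# sodscreen

Computational screening of nanomaterials for superoxide-dismutase-like
(SOD-like) catalytic activity.

Superoxide (O2•−) is a reactive oxygen species that cells clear with the
enzyme superoxide dismutase, which catalyses its dismutation into O2 and
H2O2. Some nanomaterials mimic this activity ("SOD nanozymes"), and two
descriptor-based principles predict which ones will:

1. **Energy-level principle.** The two dismutation half-reactions have
   reduction potentials φ₁ = −0.16 V (O2/O2⁻) and φ₂ = 0.94 V
   (O2⁻,H⁺/H2O2) vs the hydrogen electrode at pH 7. A material can
   shuttle electrons between them only if it owns a frontier level — VBM,
   CBM, mid-gap impurity level, or Fermi level — strictly inside the
   window: φ₁ < E_FMO < φ₂. Such a level is an *intermediate frontier
   molecular orbital* (iFMO). Occupied iFMOs drive a HOMO-mediated cycle
   (the material is oxidised first), unoccupied ones a LUMO-mediated cycle;
   activity is expected to peak for levels near the window midpoint
   (φ₁+φ₂)/2 = 0.39 V. Band structures are classified into eleven types
   (I–VIII gapped, IX–XI metallic) according to which levels fall inside.

2. **Adsorption-energy principle.** On a real surface the dismutation
   competes with four side reactions that strand HO•, H• or O•• adsorbates.
   At equilibrium the fraction of superoxide consumed by the target
   reaction is the Boltzmann partition fraction

   x₁ = exp(−Δ_rG₁/kT) / Σᵢ exp(−Δ_rGᵢ/kT),  i = 1…5,

   and the surface is selective when x₁ > 0.5. With the empirical scaling
   relation E_ads,O = 1.87 E_ads,HO + 1.42 the five free energies reduce to
   linear functions of E_ads,HO and E_ads,H, and the criterion becomes the
   closed-form rectangle **E_ads,HO > −2.7 eV and E_ads,H > −3.4 eV**
   (pH 7, 298.15 K).

A three-stage funnel combines both principles with stability filters
(≤ 2 elements, energy above the convex hull < 0.2 eV/atom, minimum
phonon-frequency-squared proxy > 10⁻⁵ eV/Å², nonzero HSE gap) to screen a
materials-property table end to end. The package is aimed at
computational materials chemists who already have band-edge positions and
adsorption energies (e.g. from DFT or a 2D-materials database) and want
the screening logic, selectivity model, threshold derivations and
reference-electrode conversions without re-deriving them.

## Worked example

```python
import sodscreen as s

ads = s.AdsorptionEnergies(e_ads_ho=-2.65, e_ads_h=-3.1)
g = s.reaction_free_energies(ads)            # eV, reactions i..v
# (-1.3, -1.25, -1.0, 0.9345, 3.389)
res = s.partition_fractions(g)
res.fractions  # (0.875, 0.125, 7.4e-06, 1.5e-38, 4.8e-80)
res.x1         # 0.8750  -> passes (x1 > 0.5)

s.criterion_thresholds()                     # (-2.7, -3.4)

fx = s.reference_fixture()
c = s.classify_band_structure(fx["V2C"].band_summary)
c.band_type.value, c.mechanism               # ('IX', 'both')
```

The free energies say: on this surface the dismutation (−1.3 eV) is nearly
tied with HO•-trapping (−1.25 eV), so only 87.5% of superoxide follows the
target reaction — still selective, because x₁ > 0.5. The metallic V2C
fixture has its Fermi level (−0.11 V) inside the window, so it is type IX
and can run both the HOMO- and LUMO-mediated cycles.

Running the funnel over a synthetic 500-material table:

```python
recs = s.generate_materials_table(s.FixtureSpec(n_materials=500, seed=42))
report = s.run_screen(recs)
report.input_count, report.stage_counts      # 500 -> (48, 20, 19)
```

48 materials survive the stability stage, 20 of those expose a single band
edge inside the window, and 19 also satisfy the adsorption criterion.

The same operations are exposed on the command line:

```bash
sodscreen simulate --n 500 --seed 42 --out table.csv
sodscreen screen --input table.csv --out report.json
sodscreen classify --input table.csv
sodscreen x1 --ho -2.65 --h -3.1
sodscreen thresholds --ph 7
sodscreen convert-potential --value 0.0 --ref sce --from-ph 4.5 --to-ph 7
```

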