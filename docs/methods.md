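# Methods

## The selectivity model

Superoxide reaching a catalyst surface is partitioned over five channels:
the target dismutation (i) and four side reactions (ii–v) that leave HO•,
H•, or O•• adsorbates on the surface. Treating the system as
thermodynamically controlled (the catalytic barriers involved are small,
well under 0.5 eV), the molar fraction routed through channel i at
equilibrium is the Boltzmann weight of its reaction free energy:

x₁ = exp(−Δ_rG₁/kT) / Σᵢ exp(−Δ_rGᵢ/kT).

Energies are handled per particle in eV, so the gas constant of the molar
formulation is realised as the Boltzmann constant kB = 8.617 × 10⁻⁵ eV/K.
The selectivity criterion x₁ > 0.5 is strict: a surface exactly at
x₁ = 0.5 fails.

The five free energies are linear in the adsorption energies of HO* and
H*. The canonical coefficients at pH 7 and 298.15 K are

| reaction | Δ_rG (eV) |
| --- | --- |
| i (dismutation) | −1.3 |
| ii (HO• trap) | E_ads,HO + 1.4 |
| iii (H• trap) | E_ads,H + 2.1 |
| iv (HO• + O••) | 2.87 E_ads,HO + 8.54 |
| v (H• + 2 O••) | 3.74 E_ads,HO + E_ads,H + 16.4 |

The O* adsorption energy has been eliminated through the cross-material
scaling relation E_ads,O = 1.87 E_ads,HO + 1.42 (both radicals prefer the
same sites, hence the linear correlation); the coefficients 2.87 = 1 + 1.87
and 3.74 = 2 × 1.87 are its footprint. These constants are stored at their
published precision and are overridable through the run configuration.

Setting Δ_rG₂ = Δ_rG₁ and Δ_rG₃ = Δ_rG₁ gives the closed-form selectivity
thresholds (−2.7, −3.4) eV. Two evaluation modes exist: `rectangle`
applies those strict inequalities; `full_x1` evaluates the partition
function itself. The two agree except in a thin band (≲ 0.1 eV) around the
rectangle corner where the three leading Boltzmann terms compete.

### pH dependence

Each free-energy expression carries one Nernst term 0.0592·pH, so the
default model shifts all five reactions equally with pH:
Δ_rGᵢ(pH) = Δ_rGᵢ(7) + 0.0592 (pH − 7). A uniform shift cancels in x₁ and
in the thresholds, making the default criterion pH-independent. Because
the five reactions in principle consume different numbers of protons, the
per-reaction multipliers are exposed (`Conditions.proton_coefficients`) so
users can encode differing H⁺ stoichiometries; any non-uniform choice makes
x₁ genuinely pH-dependent.

### The constants audit

The same free energies can be reconstructed from tabulated standard data
(solution-phase reaction free energies, radical entropies, adsorbate
solvation terms) through a Hess cycle. The reconstruction reproduces the
canonical constants of reactions i and ii at printed precision (−1.3056 vs
−1.3; 1.4409 vs 1.4) but **not** those of reactions iii–v (2.59 vs 2.1,
6.97 vs 8.54, 13.66 vs 16.4); the sign conventions of the entropy terms and
the role of two tabulated constants that no simplified expression consumes
cannot be pinned down from the available description. The package
therefore treats the simplified constants as canonical everywhere and
confines the reconstruction to `audit_constants`, a transparency diagnostic
that reports each reconstructed constant, the canonical value and their
difference, flagging discrepancies above 0.05 eV without ever overriding.

### Numerical choices

- Partition weights are computed relative to the minimum free energy
  before exponentiation, so the fractions remain finite and normalised for
  |Δ_rG|/kT of at least 10³ (channels beyond float range underflow to
  exactly zero weight, which is the correct limit).
- Strict inequalities throughout: thresholds, x₁ > 0.5, window membership.
- The scaling-relation refit is ordinary least squares (numpy.polyfit);
  fewer than two points or zero spread in E_ads,HO raises a degenerate-fit
  error rather than returning a meaningless line.
- x₁ is monotonically non-decreasing in both adsorption energies; strict
  increase holds wherever the channels depending on the bumped energy carry
  representable Boltzmann weight.

## The energy-level principle

The canonical potential scale is V vs the hydrogen electrode at pH 7. On
this scale more positive = more oxidising, so a gapped material satisfies
vbm_potential > cbm_potential (the conduction edge is the more reducing
level); this convention is validated on construction. The window defaults
to (φ₁, φ₂) = (−0.16, 0.94) V and is held fixed at its pH-7 values
(whether φ₂ should shift with pH is chemistry the descriptor model does not
resolve; the window is configurable).

Membership is strictly open, with an optional symmetric `tolerance` knob
(default 0) for near-miss materials such as a metal with its Fermi level at
−0.19 V, 30 mV below φ₁. Classification into the eleven types is
exhaustive and exclusive by construction. Types VI/VII/VIII and X/XI all
mean "no iFMO"; the convention adopted here (VI: the gap spans the window,
VII: all levels below φ₁, VIII: all above φ₂; X/XI: metal Fermi level
below/above) has no behavioural consequence — all map to mechanism `none`.
Mixed cases (edge and mid-gap level both inside) keep the edge-based type
label and report every in-window level; the mechanism is derived from the
full iFMO set (occupied only → HOMO-mediated, unoccupied only →
LUMO-mediated, both kinds or a metallic level → both).

A measured reduction potential (e.g. MOF cyclic voltammetry) is ingested
as the potential at which the material accepts an electron, i.e. as the CBM
of a gapped material; the unknown VBM is placed a configurable 3 V above
it, safely outside the default window, and is flagged as a synthetic
placeholder.

Reference-scale conversions: SCE-referenced measurements gain the 0.245 V
SCE offset, and pH is converted with the Nernst slope,
φ_HE(target) = φ − 0.0592 (target_pH − measured_pH) (+ 0.245 if SCE). The
vacuum-scale mapping uses a configurable absolute electrode potential for
the standard hydrogen electrode (default 4.44 V vs vacuum, the IUPAC
consensus value) with the same pH sign convention, and round-trips with its
inverse to 10⁻¹².

## The screening funnel

Stage 1 (stability): n_elements ≤ 2, ΔH_hull < 0.2 eV/atom, ω̃²_min >
10⁻⁵ eV/Å², E_g,HSE > 0. Comparison strictness follows the stated filters
exactly (hull `<`, omega² `>`, gap `>`, element count `≤`). Stage 2
admits materials whose only iFMO is a single band edge (types I and II by
default; configurable for exploratory screens). Stage 3 applies the
adsorption criterion in `rectangle` (default) or `full_x1` mode.

Missing data is a per-stage, machine-readable fail reason
(`missing_data:<field>`) rather than an exception, so a malformed record
cannot abort a run; missing-data counts are summarised in the report. A
material is evaluated at stage k only if it passed stage k−1, giving
non-increasing, nested survivor sets by construction. Results are
deterministic and order-invariant.

The supercell planner for adsorption calculations applies one pass of two
rules: if one in-plane vector exceeds 1.5× the other (strictly), the
shorter is doubled; then, on the updated lengths, if either is ≤ 5 Å both
are doubled. Multipliers are therefore in {1, 2, 4}. The pass is not
iterated — a cell of 3 Å doubles once to 6 Å and is not re-examined.

## The synthetic generator

The generator emulates a 2D-materials-database-like property table. Each
stage's pass rate is a tunable target: the stability gates draw each field
from an in-range or out-of-range distribution with per-gate probability
p = target^(1/3) (three live gates for gapped materials; metals have no
gap and always fail the gap filter); band edges are placed by drawing a
type outcome (I/II with the stage-2 target probability, the remaining mass
spread over III–VIII) and then sampling potentials consistent with it, so
stage-2 behaviour is controlled directly rather than through
absolute-potential distributions; adsorption energies clear their
thresholds with per-gate probability sqrt(stage-3 target), and E_ads,O
follows the active scaling line plus Gaussian noise (sd 0.15 eV, a typical
scatter for adsorption-energy scaling relations).

Default targets mirror the proportions of the published 2D screen
(≈ 9.7%, ≈ 34%, ≈ 96%). Targets are approximate by design — realised
fractions fluctuate binomially around them.

What the generator does **not** emulate: the joint field correlations of a
real database (stability, gap and adsorption energies are drawn
independently given the gate outcomes), realistic chemical formulas, or
multi-level mid-gap spectra. Passing funnel tests therefore demonstrates
the correctness of the screening logic and its bookkeeping, not predictive
performance on real materials data.

The packaged reference records (graphene, V2C, nanographene, the
MIL-53(Fe)-X substituent series, pristine CeO2(111), a MIL-47(V)-like
frame) are frozen constants with provenance notes, guarded against drift by
a checksum. Only the MIL-53(Fe) series endpoints (0.28 V for X = NH2,
0.31 V for X = NO2) are individually reported values; the six intermediate
substituents carry linear interpolations in the Hammett σ_m constant and
are flagged `synthetic_interpolated`.

## Problem sizes

The test suite exercises tables of 40–2000 synthetic materials and the
pinned regression funnel uses 500 records; the acceptance script evaluates
a single five-channel partition function. The entire suite completes in a
few seconds on one CPU.

## Known limitations

- All inputs are descriptors: the package computes no electronic
  structure, no adsorption energies from atomic coordinates, and no
  transition states.
- The selectivity model is purely thermodynamic; kinetically limited
  catalysts fall outside its assumptions.
- The free energies are not normalised per mole of superoxide consumed,
  although the five reactions consume different amounts; the partition
  function follows the published formulation as printed.
- Real nanomaterials expose multiple, possibly reconstructed surfaces;
  single-surface adsorption energies can misclassify them (the pristine
  CeO2(111) fixture, which fails the H* criterion while defective ceria is
  active, is the canonical example).
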