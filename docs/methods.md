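# Methods

`tsqscreen` implements the desk-scale half of a screening pipeline for
triplet-state quenchers (TSQs): small cyclic 8π-electron molecules that
accept triplet energy from an imaging fluorophore's dark T₁ state and
dissipate it quickly, restoring fluorescence ("self-healing" dyes).  The
expensive quantum-chemical inputs — per-compound triplet energies E_T1,
spin–orbit couplings (SOC), reorganization energies λ, inversion barriers
ΔG‡, optimized S₀/T₁ geometries and atomic-overlap matrices — are taken
as given (CSV/XYZ/matrix files); everything downstream of them is
computed here.

## Planarity metrics

For a declared ring of n ∈ {6,7,8} atoms the package computes the n
signed IUPAC torsions over consecutive quadruples (i, i+1, i+2, i+3 mod
n) in stored ring order, using the atan2 cross/dot formulation on the
range (−180°, 180°].  The per-state planarity metric is

    φ = (1/n) Σᵢ |θᵢ|   (degrees),

and the excitation change Δ(φ_T1 − φ_S0) = φ_T1 − φ_S0.  Negative values
mean the ring planarizes on excitation to T₁ (the COT behaviour; typical
of 7/8-membered-ring candidates), positive values mean T₁ puckering
(typical of the 8π 6-membered rings).  Absolute values are averaged
*per state* before differencing; averaging signed torsions would cancel
the alternating pucker pattern of a tub or chair and report a planar ring
as planar = 0 regardless of amplitude.  Collinear atom triples raise an
error rather than returning 0, to surface corrupt geometries.

## HOMA

The harmonic-oscillator model of aromaticity over the ring bonds:

    HOMA = 1 − (1/n) Σᵢ α(tᵢ) (R_opt(tᵢ) − Rᵢ)²,

with the Krygowski reference parameterization shipped as the default
(CC 257.7 Å⁻²/1.388 Å, CN 93.52/1.334, CO 157.38/1.265, CS 94.09/1.677,
NN 130.33/1.309, NO 57.21/1.248) and fully overridable via JSON.  Bond
types are unordered element pairs; no bond-order perception is attempted.

## Multicenter index (MCI)

From atomic-overlap matrices S(A) in the occupied-MO basis, the ring
index for one ordering (A₁…A_n) is

    Iring = occⁿ · Tr[S(A₁) S(A₂) … S(A_n)],

and MCI sums Iring over the (n−1)!/2 ring orderings distinct under
rotation and reversal — implemented by fixing the first atom and keeping
one representative per reversal pair, and cross-checked in the tests
against the full n!-permutation sum divided by 2n (both routes agree to
1 × 10⁻¹⁰ up to n = 8).  Enumeration is capped at n = 10.

Occupation convention: a closed-shell state uses a single channel with
occupation 2 (factor 2ⁿ); an open-shell triplet uses α and β channels
with factor 1 each, summed.  These are two distinct conventions (two
identical open-shell channels give 2·Tr, not 2ⁿ·Tr); each state is
evaluated in the convention matching its wavefunction, and state
differences always compare like with like after ring-size normalization.

Normalized MCI uses the sign-preserving root sign(x)·|x|^(1/n), the only
branch that keeps the normalized axis continuous through zero so
antiaromatic (negative-MCI) states plot below it.  ΔMCI^(1/n) (T1−S0) is
the difference of the normalized values.

Atomic partitions that close only approximately (Σ_A S(A) ≈ I) are
accepted with a logged warning above the configurable 1 × 10⁻⁶ residual
tolerance, since numerically integrated real-space partitions never close
exactly; symmetry of each S(A) is enforced at 1 × 10⁻⁸.

## Marcus-theory ISC rates

The T₁ → S₀ intersystem-crossing rate uses the canonical semiclassical
golden-rule form with the SOC matrix element H as electronic coupling:

    k_ISC = (2π/ħ) H² (4πλk_BT)^(−1/2) exp(−(λ−E_T1)²/(4λk_BT)),

with H converted cm⁻¹ → J, λ and E_T1 kJ/mol → J per molecule, CODATA
constants via scipy, and T defaulting to 298.15 K (configurable).  SOC is
a single effective coupling — no ×3 triplet-sublevel degeneracy factor —
so absolute rates carry a convention ambiguity that cancels exactly in
`isc_ratio_vs_reference`, the preferred comparison surface (verified
against the quotient of full rates to 1 × 10⁻¹⁰ relative).  E_T1 ≤ λ is
classified as the Marcus normal region (the boundary is measure-zero and
assigned to normal); rates computed outside the weak-coupling window
0 < SOC ≤ 10 cm⁻¹ are returned but flagged invalid.  The documented gap
between this expression's activationless ceiling (~2.5 × 10⁸ s⁻¹ at
SOC = 1 cm⁻¹, E_T1 = 106 kJ/mol) and the 2 × 10⁹ s⁻¹ literature value
for the benchmark quencher is analysed in `cot_rate_reconciliation.md`.

SOC strengths are labelled weak (< 10 cm⁻¹), medium (10–100) and strong
(> 100).  Singlet-oxygen safety requires ³TSQ + ³O₂ → TSQ + ¹O₂ to be
endergonic: ΔE = E(¹O₂) − E_T1 > 0.  The effective E(¹O₂) defaults to
the 94.3 kJ/mol experimental ¹Δg excitation energy but is configurable,
because free-energy treatments of the criterion sit substantially higher
— under the experimental value every candidate with E_T1 > 94.3 kJ/mol,
including the benchmark quencher itself (106 kJ/mol), would fail.  The
acceptance script reports the funnel under an effective computed energy
of 145 kJ/mol, chosen once to sit just above the 100–140 kJ/mol
8-membered-ring triplet-energy band so that the whole band is O₂-safe,
consistent with the screening narrative.

## Empirical fits

* **Sigmoid** (photostability proxy): radical-addition reaction energy vs
  MCI_T1 is fitted with the 4-parameter logistic
  y = y_lo + (y_hi − y_lo)/(1 + e^{−(x−x₀)/w}).  Initialization from the
  extreme y-deciles and the median crossing plus a fixed 6 × 5 multistart
  grid over (x₀, w); the best SSE solution wins, so the fitter is
  deterministic.  R² is reported on the original y scale.
* **Linear**: ordinary least squares with R² = 1 − SS_res/SS_tot (used
  for λ vs Δφ and ln k_ISC vs E_T1 relations).
* **Power**: y = a|x|^b via log-log least squares — |x| because
  normalized-MCI changes can be negative — with R² on the original
  scale; exactly constant data return b = 0 flagged degenerate.

## Screening funnel

Attributes and defaults (all windows closed):

| criterion          | rule                        | default      |
|--------------------|-----------------------------|--------------|
| e_t1_window        | 80 ≤ E_T1 ≤ 200 kJ/mol      | enforced     |
| soc_weak_nonzero   | 0 < SOC ≤ 10 cm⁻¹           | enforced     |
| inversion_ok       | ΔG‡ ≤ 35 kJ/mol             | enforced     |
| planar_t1          | φ_T1 ≤ 5°                   | enforced     |
| baird_aromatic_t1  | MCI_T1^(1/n) ≥ 0.35         | **advisory** |
| o2_safe            | E(¹O₂) − E_T1 > 0           | enforced     |

The Baird-aromaticity cutoff is advisory (reported, not conjoined into
the overall verdict) because no numeric threshold is established for it;
0.35 separates the markedly aromatic 7/8-ring cluster from the 6-ring
band in the synthetic distributions.  Heteroatom counts are reported,
never filtered.  The funnel conjoins criteria in the order energy window
→ SOC → inversion → planarity → O₂ and reports survivors after each
step; survivor counts are non-increasing by construction.  Fluorophore
matching excludes candidates whose S₁ lies at or below the fluorophore's
S₁ (+ margin) and ranks the rest by |ΔE_T1|, ties broken by larger
k_ISC, then compound id.

## Synthetic study conditions

The generator emulates the screened candidate set: 117/75/22 compounds
with 6/7/8-membered rings (214 total), per-ring-size marginals listed in
`synthetic.py` (8-ring E_T1 confined to 100–140 kJ/mol and SOC ≤ 1 cm⁻¹;
6-ring SOC up to 126 cm⁻¹; Δφ negative for 7/8-rings and positive for
6-rings; λ = E_T1 + N(10, 15) truncated above 5 kJ/mol so most of the
portfolio is normal-region).  Distribution families (uniform,
log-uniform, normal) are the simplest consistent with those ranges.
Values not pinned by the study conditions were fixed once at realistic
levels: ΔG‡ ~ U(0, 10) kJ/mol for the near-planar-S₀ 6-rings vs
U(0, 40)/U(5, 40) for the puckered 7/8-rings; E_S1 = E_T1 + U(80, 180)
kJ/mol, placing mid-band candidates in the ~200–350 kJ/mol S₁ band;
heteroatom counts 1–4 from {N, O, S}.  Per-compound pass/fail truth is
planted at generation time by evaluating the same criteria object the
screen will use, so planted-truth recovery is an exact (not statistical)
check.

What the generator does **not** emulate: correlations between SOC and
heteroatom identity, the λ–Δφ coupling within ring classes (λ is tied to
E_T1, not to planarity change, so correlation fits on synthetic columns
test machinery, not the physical effect), annulation patterns, or any
quantum-chemical consistency between the property table and the
geometry/AOM files.  Passing tests therefore demonstrate correctness of
the descriptor and screening computations, not the quantum-chemical
accuracy of any real compound's screening verdict.

Ring geometries are circles with 1.40 Å bond targets and alternating
out-of-plane displacement z_k = a·(−1)^k ("tub"; "chair-like" restricted
to even rings where the alternation is the true chair); a = 0.15 Å
reproduces a physical COT-like tub (mean ring dihedral ≈ 54°).  Hückel
AOMs come from the analytic cycle eigenvectors with degenerate pairs
resolved to cosine/sine combinations in a fixed order, giving exactly
closed partitions (Σ_A S(A) = I to machine precision).

## Problem sizes and tolerances

The shipped test suite and `scripts/acceptance.py` run the default
214-compound portfolio, rings up to n = 8 for the dual-route MCI check
(the n!-permutation oracle at n = 8 enumerates 40 320 orderings in under
a second), and 100 seeded replicates for the sigmoid-midpoint recovery
check (median |x̂₀ − x₀| ≤ 0.05 at σ = 5 kJ/mol, n = 30).  Numerical
agreement thresholds: dihedrals vs an independent vector-algebra oracle
to 1 × 10⁻⁸ °, MCI dual routes to 1 × 10⁻¹⁰, rate-ratio algebraic
equivalence to 1 × 10⁻¹⁰ relative, unit-conversion round trips to
1 × 10⁻¹² relative.

## Known limitations

* No electronic-structure computation: all quantum-chemical descriptors
  are inputs.  No ring perception (ring atoms are declared), no
  Cremer–Pople puckering coordinates, no NICS/FLU indices, no
  multi-ring 12π/16π circuit enumeration.
* Rates are semiclassical Marcus only — no vibronic (MLJ) corrections —
  and absolute values inherit the prefactor-convention ambiguity above.
* Fluorophore matching is an energy-gap heuristic; no triplet-triplet
  energy-transfer rate constants and no linker chemistry.
* Hydrophilicity (heteroatom count) is reported but never modelled or
  filtered.
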