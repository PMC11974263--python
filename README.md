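# tsqscreen

Screening toolkit for **triplet-state quenchers (TSQs)** — small cyclic
8π-electron molecules (cyclooctatetraene and its hetero/annulated
relatives) that are tethered to imaging fluorophores to build
"self-healing" dyes.  A fluorophore stuck in its dark triplet state T₁
hands its energy to the TSQ by triplet–triplet energy transfer; the TSQ
must then relax to S₀ quickly and harmlessly, over and over, without
photodegrading or sensitizing singlet oxygen.  This package implements
the descriptor and decision layer of that search for computational
chemists and probe developers: given quantum-chemical inputs per
candidate (triplet energies, spin–orbit couplings, reorganization
energies, geometries, atomic-overlap matrices), it computes the
screening descriptors, applies the multi-attribute funnel, and matches
survivors to fluorophores.

What it computes:

* **Planarity** — signed ring torsions, per-state mean absolute dihedral
  φ, and the excitation change Δ(φ_T1 − φ_S0) (negative ⇒ the ring
  planarizes in T₁, as COT does).
* **Aromaticity** — the geometric HOMA index, and the electronic
  multicenter index MCI = Σ_orderings occⁿ·Tr[S(A₁)…S(A_n)] from
  atomic-overlap matrices, with ring-size-normalized MCI^(1/n) and the
  T₁–S₀ change ΔMCI^(1/n) as the Baird-aromaticity (photostability)
  measure.
* **Kinetics** — semiclassical Marcus ISC rates
  k_ISC = (2π/ħ)H²(4πλk_BT)^(−1/2)·e^(−(λ−E_T1)²/4λk_BT) with SOC as the
  coupling, normal/inverted-region classification (E_T1 ≤ λ ⇒ normal),
  SOC strength bands, and convention-free rate ratios against the COT
  benchmark.
* **Safety** — the singlet-oxygen criterion: ³TSQ + ³O₂ → TSQ + ¹O₂ must
  be endergonic.
* **Fits** — the 4-parameter logistic of radical-addition energy vs
  MCI_T1, linear R² correlations (λ vs Δφ), and power fits.
* **The funnel** — E_T1 window (80–200 kJ/mol) → weak nonzero SOC
  (≤ 10 cm⁻¹) → inversion barrier (≤ 35 kJ/mol) → planar T₁ (≤ 5°) →
  O₂-safe, with ring-size breakdowns and fluorophore ranking.
* **Synthetic study conditions** — generators for a 214-compound-like
  portfolio, puckered/planar ring geometries, exactly-closed Hückel
  atomic-overlap matrices, and sigmoid-truth datasets, so the whole
  pipeline runs and is testable without any quantum-chemistry output.

## Worked example

```python
from tsqscreen import (
    PhotophysicsRecord, PortfolioSpec, ScreeningCriteria,
    classify_soc, generate_portfolio, marcus_k_isc,
    rank_for_fluorophore, screen_portfolio, singlet_oxygen_gap,
)

# the benchmark quencher's profile: E_T1 = 106 kJ/mol, SOC = 1.0 cm^-1
cot = PhotophysicsRecord(e_t1=106.0, e_s1=300.0, soc=1.0,
                         lambda_reorg=110.0, dg_inversion=10.0)
rate = marcus_k_isc(cot)
print(f"k_ISC = {rate.k_isc:.3e} /s  region={rate.region.value}")
print(f"SOC class: {classify_soc(cot.soc).value}")
gap, safe = singlet_oxygen_gap(cot.e_t1, e_singlet_o2=145.0)
print(f"O2 gap = {gap:+.1f} kJ/mol  endergonic={safe}")

crit = ScreeningCriteria(e_singlet_o2=145.0)   # computed-free-energy O2 criterion
records, truth = generate_portfolio(PortfolioSpec(seed=42), crit)
report = screen_portfolio(records, crit)
for ring, c in sorted(report.counts_by_ring.items()):
    print(f"{ring}-MR: {c['passed']}/{c['total']} pass")

best = rank_for_fluorophore(records, fluor_e_t1=179.1, fluor_e_s1=179.1)[0]
print(f"best match for Cy5: {best.compound_id}  E_T1={best.photophysics.e_t1:.1f}")
```

prints

```
k_ISC = 2.383e+08 /s  region=normal
SOC class: weak
O2 gap = +39.0 kJ/mol  endergonic=True
6-MR: 0/117 pass
7-MR: 17/75 pass
8-MR: 19/22 pass
best match for Cy5: mr6-016  E_T1=178.8
```

Reading the output: the benchmark profile sits in the Marcus normal
region with a weak coupling and a ~2.4 × 10⁸ s⁻¹ canonical rate (see
`docs/cot_rate_reconciliation.md` for why the literature benchmark value
of 2 × 10⁹ s⁻¹ implies a different prefactor convention, and why rate
*ratios* are convention-free).  On the synthetic 214-compound portfolio
the funnel behaves like the real candidate landscape: almost all
8-membered rings survive (their 100–140 kJ/mol triplet energies fit the
fluorophore window and their SOCs are weak), a substantial fraction of
7-membered rings survive, and the high-E_T1/strong-SOC 6-membered rings
are eliminated.  The ranked match for a Cy5-like fluorophore is the
candidate whose E_T1 lands nearest 179.1 kJ/mol among those whose S₁ is
safely above the fluorophore's.

The same operations are available from the shell:

```sh
tsq-screen simulate --seed 42 --out study/
tsq-screen screen --portfolio study/portfolio.csv --out report.json
tsq-screen rank --portfolio study/portfolio.csv \
    --fluorophore-et1 179.1 --fluorophore-es1 179.1
tsq-screen rates --portfolio study/portfolio.csv --out rates.csv
```

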