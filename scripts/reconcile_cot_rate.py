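#!/usr/bin/env python
"""Compare Marcus-rate prefactor conventions against the COT benchmark.

The literature value for the benchmark quencher's T1 -> S0 intersystem
crossing is k_ISC = 2e9 /s at SOC = 1.0 cm^-1 and E_T1 = 106 kJ/mol.  This
script evaluates the canonical semiclassical golden-rule rate over a wide
reorganization-energy scan and several plausible convention variants, and
prints how far each falls from 2e9.  See docs/cot_rate_reconciliation.md
for the discussion.

Usage: python scripts/reconcile_cot_rate.py
"""

from __future__ import annotations

import numpy as np

from tsqscreen import PhotophysicsRecord, marcus_k_isc

TARGET = 2.0e9
E_T1 = 106.0
SOC = 1.0


def main() -> None:
    lams = np.linspace(20.0, 400.0, 3800)
    rates = np.array(
        [
            marcus_k_isc(PhotophysicsRecord(e_t1=E_T1, soc=SOC, lambda_reorg=lam)).k_isc
            for lam in lams
        ]
    )
    i = int(np.argmax(rates))
    peak, lam_peak = rates[i], lams[i]
    print(f"canonical semiclassical rate, SOC={SOC} cm^-1, E_T1={E_T1} kJ/mol")
    print(f"  ceiling: {peak:.3e} /s at lambda = {lam_peak:.1f} kJ/mol (activationless)")
    print(f"  target (literature benchmark): {TARGET:.1e} /s")
    print(f"  shortfall factor: {TARGET / peak:.2f}x\n")

    print("convention variants at the activationless point:")
    for label, factor in [
        ("x3 triplet-sublevel summation", 3.0),
        ("SOC interpreted as sqrt(sum over sublevels), i.e. H^2 x 3", 3.0),
        ("2pi/hbar -> 4pi^2/hbar (h/hbar slip)", 2.0 * np.pi),
        ("x3 sublevels AND h/hbar slip", 3.0 * 2.0 * np.pi),
    ]:
        value = factor * peak
        print(f"  {label:55s} {value:.3e} /s ({value / TARGET:.2f}x target)")
    print(
        "\nno single canonical factor reaches 2e9 except the combined "
        "sublevel+prefactor variant (~2.3x); the published rate most likely "
        "uses a different effective-coupling or prefactor convention. "
        "Ratios between candidate rates are convention-independent."
    )


if __name__ == "__main__":
    main()
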