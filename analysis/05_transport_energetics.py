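#!/usr/bin/env python
"""Antiport stoichiometry and proton-motive-force energetics.

Tabulates, for 1:1, 1:2 and 1:3 Zn2+:H+ stoichiometries, the net cycle
charge, the equilibrium Zn2+ gradient at dpH = 1 with and without a -80 mV
membrane potential, and the pH-unit equivalent of the electrical term.
Writes results/transport_gradients.csv.
"""

from pathlib import Path

import pandas as pd

from zincsite.transport import (
    log10_equilibrium_gradient,
    net_charge,
    ph_equivalent_of_potential,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    rows = []
    for m in (1, 2, 3):
        z = net_charge(m, 1)
        lg0 = log10_equilibrium_gradient(m, 1, 1.0, 0.0, 298.0)
        lgv = log10_equilibrium_gradient(m, 1, 1.0, -0.08, 298.0)
        rows.append({
            "protons_per_cycle": m, "zinc_per_cycle": 1, "net_charge": z,
            "log10_gradient_vm0": round(lg0, 3),
            "log10_gradient_vm_-80mV": round(lgv, 3),
            "ph_equivalent_of_potential": round(
                ph_equivalent_of_potential(z, -0.08, 298.0), 3),
        })
        print(f"1 Zn2+ : {m} H+  (z = {z:+d}):  gradient 10^{lg0:.1f} at "
              f"Vm = 0, 10^{lgv:.1f} at Vm = -80 mV")
    out = ROOT / "results" / "transport_gradients.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print("\nThe electroneutral 1:2 cycle ignores the potential; the 1:1 "
          "cycle pays an electrical penalty worth more than one pH unit; "
          "the 1:3 cycle gains from it, reaching 10^4.4.")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
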