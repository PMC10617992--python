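#!/usr/bin/env python
"""Fit the synthetic MST titrations with mass-action and Hill models.

For each site and pH, fits the law of mass action (binding-regime limit:
the free Zn2+ is chelator-buffered, so no protein depletion applies) with
bootstrap confidence intervals, plus a Hill fit for cooperativity. The
fitted apparent K_d's are compared against the truth models' apparent K_d
to show the pH dependence of metal binding, and written to
results/binding_fits.csv.
"""

from pathlib import Path

import pandas as pd

from zincsite.mstfit import MSTCurve, fit_hill, fit_mass_action, read_curves
from zincsite.statespace import apparent_kd, model_from_json

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"


def main() -> None:
    rows = []
    for site in ("siteA", "siteB"):
        truth = model_from_json((DATA / f"{site}_truth.json").read_text())
        curves = read_curves(DATA / f"{site}_mst.csv", protein_conc=1e-13)
        for curve in curves:
            ma = fit_mass_action(curve, n_boot=200, seed=1)
            try:
                hill = fit_hill(curve, n_boot=0)
                hill_cols = {"ec50_M": hill.ec50, "hill_n": hill.hill_n}
            except Exception:
                hill_cols = {"ec50_M": float("nan"), "hill_n": float("nan")}
            kd_truth = apparent_kd(truth, curve.pH)
            rows.append({
                "site": site, "ph": curve.pH,
                "kd_M": ma.kd, "kd_ci68_lo": ma.ci68["kd"][0],
                "kd_ci68_hi": ma.ci68["kd"][1],
                "kd_truth_M": kd_truth, "kd_ratio": ma.kd / kd_truth,
                "residual_rms": ma.residual_rms, **hill_cols,
            })
            print(f"{site} pH {curve.pH:.1f}: K_d = {ma.kd:.3g} M "
                  f"(truth {kd_truth:.3g} M, ratio {ma.kd / kd_truth:.2f})")
    out = ROOT / "results" / "binding_fits.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nApparent K_d rises steeply toward acidic pH at the transport "
          f"site, reflecting proton competition for the metal-binding "
          f"residues.\nwrote {out}")


if __name__ == "__main__":
    main()
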