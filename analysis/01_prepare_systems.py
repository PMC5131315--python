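#!/usr/bin/env python
"""Scaled-charge ion preparation and composition arithmetic.

Derives the electronic-continuum scaling factor for water, the resulting
simulation charges of Ca2+ and Cl-, the neutralising-cation count of the
mixed 4:1 PC:PS bilayer, and nominal salt concentrations for a range of
ion counts.  Writes results/composition.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from calcimem import charges

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> int:
    f_exact = charges.scaling_factor(charges.EPS_ELECTRONIC_WATER)
    f = round(f_exact, 2)
    scaled = charges.scale_charges({"CA": 2.0, "CL": -1.0}, f).scaled
    print(f"ECC scaling factor 1/sqrt({charges.EPS_ELECTRONIC_WATER}) = "
          f"{f_exact:.4f} (displayed {f})")
    print(f"simulation charges: Ca2+ {scaled['CA']:+.2f}e, Cl- {scaled['CL']:+.2f}e")

    # mixed bilayer: 12 PC->PS replacements per leaflet, lipid charges unscaled
    n_ps = 24
    n_neut = charges.neutralizing_cation_count(-float(n_ps), scaled["CA"])
    print(f"{n_ps} anionic lipids (-1e each) need {n_neut} cations of "
          f"{scaled['CA']:+.2f}e to neutralise exactly")

    rows = []
    n_water = 4300
    for target_mM in (100, 306, 400, 600, 700, 919):
        pairs = charges.ion_pairs_for_concentration(target_mM / 1000, n_water)
        realised = charges.nominal_concentration(pairs, n_water)
        rows.append({
            "target_mM": target_mM,
            "n_water": n_water,
            "caCl2_units": pairs,
            "realised_mM": round(realised * 1000, 1),
        })
    df = pd.DataFrame(rows)
    df.insert(0, "scaling_factor", f)
    df.insert(1, "q_Ca_e", scaled["CA"])
    df.insert(2, "q_Cl_e", scaled["CL"])
    df.insert(3, "neutralizing_Ca", n_neut)
    df.to_csv(OUT / "composition.csv", index=False)
    print(f"\nnominal concentrations at {n_water} waters "
          f"(55.51 M pure-water convention):")
    print(df[["target_mM", "caCl2_units", "realised_mM"]].to_string(index=False))
    print(f"\nwrote {OUT / 'composition.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
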