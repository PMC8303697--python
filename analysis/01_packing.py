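#!/usr/bin/env python
"""Solution densities -> water molarity and hard-sphere packing coefficients.

Reads the 30 measured solution densities (pure water, sugar and denaturant
binaries, sugar+denaturant ternaries), recovers the water molarity of each
from the mass balance, and computes the packing coefficients xi1-xi3 that
parameterize the cavity-work calculation.  Writes results/packing.tsv.
"""

from pathlib import Path

from sptdsc.report import packing_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = packing_table()
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "packing.tsv", sep="\t", index=False)
    water = df[df.label == "water"].iloc[0]
    densest = df.loc[df.xi3.idxmax()]
    print(f"{len(df)} solutions; pure water packs xi3 = {water.xi3:.3f}")
    print(f"densest packing: {densest.label} (xi3 = {densest.xi3:.3f}, "
          f"rho = {densest.density_g_L:.0f} g/L)")
    print("every co-solute, stabilizer or denaturant, raises xi3 above water:",
          bool((df[df.label != 'water'].xi3 > water.xi3).all()))
    print(f"wrote {OUT / 'packing.tsv'}")


if __name__ == "__main__":
    main()
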