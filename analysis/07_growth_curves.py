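#!/usr/bin/env python
"""Growth-curve dose-response summary and IC20-based exposure ladder.

AUC per well over 24 h, percent of untreated control, interpolated IC20,
and the 25%/50%/100% IC20 treatment doses used for pooled exposures.
"""

from poolscreen import io
from poolscreen.growth import dose_response, icx, treatment_doses, well_aucs


def main() -> None:
    curves = io.read_growth_csv("results/data/growth_curves.csv")
    aucs = well_aucs(curves)
    dr = dose_response(aucs)
    dr.to_csv("results/dose_response.tsv", sep="\t", index=False, float_format="%.6g")
    for _, r in dr.iterrows():
        print(f"dose {r['dose']:>4.1f} mM: {r['percent_of_control']:6.1f}% of control "
              f"(SE {r['se']:.2f}, n={int(r['n'])})")
    ic20 = icx(dr, 20.0)
    if ic20 is None:
        print("IC20: no crossing of the 80% level on this dose grid")
        return
    ladder = treatment_doses(ic20)
    print(f"IC20 = {ic20:.2f} mM -> exposure ladder: "
          f"25% = {ladder['25']:.2f} mM, 50% = {ladder['50']:.2f} mM, "
          f"100% = {ladder['100']:.2f} mM")


if __name__ == "__main__":
    main()
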