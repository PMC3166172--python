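#!/usr/bin/env python
"""Differential strain sensitivity analysis of the normalized screen.

Per-condition fitness scores and Welch/BH significance, then the >=3-of-6
consensus filter; reports how many planted strains were recovered.
"""

import pandas as pd

from poolscreen import io
from poolscreen.dssa import consensus_filter, dssa_table


def main() -> None:
    chip_level = pd.read_csv("results/chip_level.tsv", sep="\t").set_index("strain")
    design = io.read_design("results/data/design.tsv")
    truth = pd.read_csv("results/data/truth.tsv", sep="\t")

    table = dssa_table(chip_level, design, "HQ", alpha=0.05)
    table.to_csv("results/dssa.tsv", sep="\t", index=False, float_format="%.6g")
    cons = consensus_filter(table, k_min=3, sign="any")
    cons.to_csv("results/dssa_consensus.tsv", sep="\t")

    planted = set(truth["strain"])
    hits = set(cons.index[cons["consensus"]])
    print(f"significant calls: {int(table['significant'].sum())} across "
          f"{table['condition'].nunique()} conditions")
    print(f"consensus genes (>=3 of 6): {len(hits)}; "
          f"planted recovered: {len(hits & planted)}/{len(planted)}; "
          f"spurious: {len(hits - planted)}")


if __name__ == "__main__":
    main()
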