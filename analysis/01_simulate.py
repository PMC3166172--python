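#!/usr/bin/env python
"""Simulate one full synthetic screen: a 4,607-strain pool treated with one
compound at 3 doses x 2 generations (3 replicates each, 12 controls per
generation), with 40 strains planted at a known growth defect, plus pathway
graphs, a scored interaction network with a planted module, and wild-type
growth curves for dose selection.

Writes everything under results/data/.
"""

from pathlib import Path

from poolscreen import io
from poolscreen.datagen import (
    PlantedTruth,
    PoolDesign,
    WellParams,
    generate_growth_curves,
    generate_network,
    generate_pathways,
    generate_pool,
    strain_ids,
)

OUT = Path("results/data")
SEED = 20260920

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = PoolDesign(seed=SEED)
    ids = strain_ids(design.n_strains)
    planted = tuple(
        PlantedTruth(s, {"25": 0.15, "50": 0.25, "100": 0.4}) for s in ids[:40]
    )
    intensity, chips, truth = generate_pool(design, planted)
    io.write_intensity(intensity, OUT / "intensity.tsv")
    io.write_design(chips, OUT / "design.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"pool: {intensity.shape[0]} strain-tag rows x {intensity.shape[1]} chips; "
          f"{len(planted)} planted sensitive strains")

    pathways, _, planted_genes = generate_pathways(
        12, (6, 14), planted_pathway="pw000", n_planted_genes=4, seed=SEED + 1
    )
    io.write_edge_list(pathways, OUT / "pathways.tsv")
    print(f"pathways: {len(pathways)} graphs; perturbed genes planted in pw000: {planted_genes}")

    edges, module = generate_network(1000, planted_module_size=12, seed=SEED + 2)
    io.write_string_edges(edges, OUT / "network.tsv")
    (OUT / "network_module.txt").write_text("\n".join(module) + "\n")
    print(f"network: {len(edges)} scored edges; planted module of {len(module)} nodes")

    wells = [(WellParams("wild_type", "HQ", d), 3) for d in (0.0, 1.0, 2.0, 4.0, 8.0)]
    curves = generate_growth_curves(wells, dose_effect=0.08, noise_sd=0.003, seed=SEED + 3)
    io.write_growth_csv(curves, OUT / "growth_curves.csv")
    print(f"growth: {curves['well'].nunique()} wells x 97 time points")


if __name__ == "__main__":
    main()
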