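"""End-to-end pipeline orchestration over synthetic data.

Stages: simulate -> normalize -> dssa -> dosemodel -> enrichment -> network
-> growth. Each stage writes its outputs as plain-text tables under the
configured output directory and records row counts and content hashes in a
manifest, so a rerun with the same configuration and seed is byte-for-byte
reproducible. Stage toggles allow partial runs; a stage whose upstream
output is missing fails with an error naming the missing stage.

The statistical thresholds collected in :class:`PipelineConfig` are the
screen's printed operating points: DSSA q < 0.05, category enrichment
p < 0.01, Holm family-wise 0.05, pathway coverage >= 60%, and an
interaction-score cutoff of 700.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import datagen, dosemodel, dssa, enrichment, growth, io, network
from .datagen import PlantedTruth, PoolDesign
from .normalize import fastlo_normalize, regroup_tags


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "normalize", "dssa", "dosemodel", "enrichment", "network", "growth",
    )
    # simulation scale
    n_strains: int = 400
    n_planted: int = 20
    planted_defect: float = 0.4
    # analysis thresholds (screen operating points)
    dssa_q: float = 0.05
    category_p: float = 0.01
    holm_alpha: float = 0.05
    coverage_min: float = 0.6
    score_cutoff: int = 700
    n_perm: int = 9999
    # normalization
    span: float = 0.4
    tol: float = 0.01

    def __post_init__(self) -> None:
        for name in ("dssa_q", "category_p", "holm_alpha", "coverage_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} out of range: {v}")
        if not 0 <= self.score_cutoff <= 1000:
            raise ValueError("score_cutoff must be in [0, 1000]")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from YAML, with keyword overrides."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    raw.update(overrides)
    return PipelineConfig(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and return the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}

    def record(stage: str, files: dict[str, Path], rows: int) -> None:
        manifest["stages"][stage] = {
            "complete": True,
            "rows": rows,
            "hashes": {k: _hash_file(p) for k, p in files.items()},
        }

    def require(stage: str) -> None:
        if stage not in manifest["stages"]:
            raise RuntimeError(
                f"stage '{stage}' output required but the stage did not run; "
                f"enable it or provide its outputs"
            )

    if "simulate" in config.stages:
        design = PoolDesign(
            n_strains=config.n_strains,
            seed=int(rng.integers(2**31)),
        )
        ids = datagen.strain_ids(config.n_strains)
        planted = tuple(
            PlantedTruth(s, {d: config.planted_defect for d in design.dose_levels})
            for s in ids[: config.n_planted]
        )
        intensity, chips, truth = datagen.generate_pool(design, planted)
        io.write_intensity(intensity, out / "intensity.tsv")
        io.write_design(chips, out / "design.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        record("simulate", {"intensity": out / "intensity.tsv", "design": out / "design.tsv",
                            "truth": out / "truth.tsv"}, len(intensity))
        state = {"intensity": intensity, "design": chips, "truth": truth,
                 "compound": design.compound}

    if "normalize" in config.stages:
        require("simulate")
        normed, report = fastlo_normalize(state["intensity"], span=config.span, tol=config.tol)
        chip_level = regroup_tags(normed)
        io.write_intensity(normed, out / "normalized.tsv")
        record("normalize", {"normalized": out / "normalized.tsv"}, len(normed))
        manifest["stages"]["normalize"]["iterations"] = report.iterations
        state["normalized"] = normed
        state["chip_level"] = chip_level

    if "dssa" in config.stages:
        require("normalize")
        table = dssa.dssa_table(state["chip_level"], state["design"],
                                state["compound"], alpha=config.dssa_q)
        cons = dssa.consensus_filter(table)
        table.to_csv(out / "dssa.tsv", sep="\t", index=False, float_format="%.6g")
        cons.to_csv(out / "consensus.tsv", sep="\t")
        record("dssa", {"dssa": out / "dssa.tsv", "consensus": out / "consensus.tsv"}, len(table))
        state["dssa"] = table
        state["consensus"] = cons

    if "dosemodel" in config.stages:
        require("normalize")
        fits = []
        for g in sorted(state["design"]["generation"].unique()):
            f = dosemodel.fit_dose_models(state["normalized"], state["design"],
                                          state["compound"], int(g), alpha=config.holm_alpha)
            f.insert(0, "generation", g)
            fits.append(f)
        fit = pd.concat(fits)
        fit.to_csv(out / "dose_models.tsv", sep="\t", float_format="%.6g")
        record("dosemodel", {"dose_models": out / "dose_models.tsv"}, len(fit))
        state["dose_models"] = fit

    if "enrichment" in config.stages:
        require("dosemodel")
        g5 = int(sorted(state["design"]["generation"].unique())[0])
        kw = dosemodel.kruskal_wallis(state["chip_level"], state["design"],
                                      state["compound"], g5)
        pathways, _universe, _planted = datagen.generate_pathways(
            8, (6, 12), n_planted_genes=3, seed=int(rng.integers(2**31))
        )
        # map pathway gene ids onto measured strains so coverage is realistic
        strains = list(state["chip_level"].index)
        mapped = {}
        k = 0
        for pid, gph in pathways.items():
            relabel = {}
            for node in gph.nodes:
                relabel[node] = strains[k % len(strains)]
                k += 1
            mapped[pid] = type(gph)(((relabel[a], relabel[b]) for a, b in gph.edges))
        cov = enrichment.coverage_filter(mapped, set(strains), config.coverage_min)
        results = []
        for pid in cov.index[cov["retained"]]:
            r = enrichment.sepea_test(mapped[pid], kw["H"], n_perm=config.n_perm,
                                      seed=int(rng.integers(2**31)))
            results.append((pid, r.statistic, r.p_value))
        enr = pd.DataFrame(results, columns=["pathway", "statistic", "p_value"])
        enr.to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        record("enrichment", {"pathway_enrichment": out / "pathway_enrichment.tsv"}, len(enr))
        state["enrichment"] = enr

    if "network" in config.stages:
        require("dosemodel")
        edges, module = datagen.generate_network(seed=int(rng.integers(2**31)))
        net = network.load_network(edges, cutoff=config.score_cutoff)
        fit = state["dose_models"]
        selected = set(fit.index[fit["selected"]])
        # map selected strain ids onto network node ids
        nodes = sorted(net.nodes)

        def stable(s: str) -> int:
            return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")

        sig = {nodes[stable(s) % len(nodes)] for s in selected} or set(module)
        clusters = network.detect_clusters(net, sig)
        rows = []
        for cl in clusters[:10]:
            p = network.cluster_significance(net, set(cl.members), sig,
                                             n_draws=config.n_perm,
                                             seed=int(rng.integers(2**31)))
            rows.append((cl.cluster_id, len(cl.members), cl.n_significant, p))
        res = pd.DataFrame(rows, columns=["cluster", "size", "n_significant", "p_value"])
        res.to_csv(out / "network_clusters.tsv", sep="\t", index=False, float_format="%.6g")
        record("network", {"network_clusters": out / "network_clusters.tsv"}, len(res))

    if "growth" in config.stages:
        wells = [
            (datagen.WellParams("wild_type", state.get("compound", "HQ"), d), 3)
            for d in (0.0, 1.0, 2.0, 4.0, 8.0)
        ]
        curves = datagen.generate_growth_curves(
            wells, dose_effect=0.08, noise_sd=0.003, seed=int(rng.integers(2**31))
        )
        io.write_growth_csv(curves, out / "growth_curves.csv")
        aucs = growth.well_aucs(curves)
        dr = growth.dose_response(aucs)
        ic20 = growth.icx(dr, 20.0)
        dr.to_csv(out / "dose_response.tsv", sep="\t", index=False, float_format="%.6g")
        record("growth", {"growth_curves": out / "growth_curves.csv",
                          "dose_response": out / "dose_response.tsv"}, len(dr))
        manifest["stages"]["growth"]["ic20"] = ic20

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
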