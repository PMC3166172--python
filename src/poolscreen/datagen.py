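"""Synthetic pooled-screen data with known planted truth.

Emulates the design of a genome-wide homozygous deletion pool exposed to a
toxicant at three sub-inhibitory doses (25%, 50% and 100% of the wild-type
IC20) for two generation points (5 and 15 population doublings), assayed on
barcode arrays with paired UP/DOWN tags, and compared against 12 rich-media
control chips.

Signals are generated directly on the log2 scale as an additive model:

    Y(strain, tag, chip) = baseline_strain
                           + depletion(strain, dose, generation)
                           + chip_effect(chip)
                           + tag_offset * [tag == DOWN]
                           + noise

A strain carrying a growth-rate defect ``d`` (fraction of a doubling lost per
generation) at a given dose is depleted by ``d * generations`` log2 units
relative to the unaffected pool: one doubling is one log2 unit of abundance
advantage for strains that keep dividing at full rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

UP = "UP"
DOWN = "DOWN"
CONTROL = "control"

#: dose-group labels as percent of the wild-type IC20
DOSE_LEVELS = ("25", "50", "100")


@dataclass(frozen=True)
class PoolDesign:
    """Design of one pooled exposure experiment (one compound).

    Defaults mirror the screen design this package models: a 4,607-strain
    homozygous deletion pool, 12 control chips versus 3 replicate chips at
    each of 3 dose groups, at 5 and 15 generations of growth.
    """

    n_strains: int = 4607
    n_controls: int = 12
    n_reps_per_dose: int = 3
    dose_levels: tuple[str, ...] = DOSE_LEVELS
    generations: tuple[int, ...] = (5, 15)
    tag_offset: float = 0.5
    chip_sd: float = 0.2
    noise_sd: float = 0.3
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    compound: str = "HQ"
    share_controls: bool = False  # one control set for all generations?
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains <= 0 or self.n_controls < 2 or self.n_reps_per_dose < 2:
            raise ValueError("need n_strains > 0, >=2 control and >=2 treated chips")
        if not self.dose_levels or CONTROL in self.dose_levels:
            raise ValueError("dose_levels must be non-empty and exclude the control label")
        if min(self.chip_sd, self.noise_sd, self.baseline_sd) < 0:
            raise ValueError("variance parameters must be >= 0")


@dataclass(frozen=True)
class PlantedTruth:
    """A strain planted with a known per-generation growth defect.

    ``per_generation_defect`` maps dose-group label to the fractional growth
    defect per doubling, so the expected log2 depletion at (dose, g) is
    ``-defect * g``.
    """

    strain_id: str
    per_generation_defect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d, v in self.per_generation_defect.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"defect for dose {d} outside [0, 1]: {v}")

    def expected_log2_depletion(self, dose: str, generations: int) -> float:
        return -self.per_generation_defect.get(dose, 0.0) * generations


def strain_ids(n: int) -> list[str]:
    return [f"strain{i:05d}" for i in range(n)]


def _chip_table(design: PoolDesign) -> pd.DataFrame:
    rows = []
    for g in design.generations:
        ctag = "gALL" if design.share_controls else f"g{g}"
        for r in range(design.n_reps_per_dose):
            for dose in design.dose_levels:
                rows.append(
                    (f"{design.compound}_g{g}_d{dose}_r{r + 1}",
                     design.compound, dose, g, r + 1)
                )
        for r in range(design.n_controls):
            rows.append((f"ctrl_{ctag}_r{r + 1:02d}", CONTROL, CONTROL, g, r + 1))
    df = pd.DataFrame(rows, columns=["chip", "compound", "dose", "generation", "replicate"])
    df = df.drop_duplicates(subset="chip").set_index("chip")
    return df


def generate_pool(
    design: PoolDesign, planted: tuple[PlantedTruth, ...] = ()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one pooled screen.

    Returns ``(intensity, design_table, truth)`` where ``intensity`` is a
    log2 signal matrix indexed by (strain, tag) with one column per chip,
    ``design_table`` annotates the chips, and ``truth`` lists the expected
    log2 depletion of every planted (strain, dose, generation) cell.
    """
    ids = set()
    for p in planted:
        if p.strain_id in ids:
            raise ValueError(f"duplicate planted strain {p.strain_id}")
        ids.add(p.strain_id)
    strains = strain_ids(design.n_strains)
    universe = set(strains)
    if not ids <= universe:
        raise ValueError(f"planted strains outside the pool: {sorted(ids - universe)}")

    chips = _chip_table(design)
    rng = np.random.default_rng(design.seed)
    n_chips = len(chips)

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, design.n_strains)
    chip_eff = rng.normal(0.0, design.chip_sd, n_chips)

    # expected depletion per (strain, chip); zero everywhere except planted
    # strains on treated chips
    depletion = np.zeros((design.n_strains, n_chips))
    pos = {s: i for i, s in enumerate(strains)}
    for p in planted:
        i = pos[p.strain_id]
        for j, (_, row) in enumerate(chips.iterrows()):
            if row["dose"] != CONTROL:
                depletion[i, j] = p.expected_log2_depletion(row["dose"], row["generation"])

    index = pd.MultiIndex.from_product([strains, [UP, DOWN]], names=["strain", "tag"])
    values = np.empty((design.n_strains * 2, n_chips))
    for t, tag in enumerate((UP, DOWN)):
        noise = rng.normal(0.0, design.noise_sd, (design.n_strains, n_chips))
        block = (
            baseline[:, None]
            + depletion
            + chip_eff[None, :]
            + (design.tag_offset if tag == DOWN else 0.0)
            + noise
        )
        values[t::2, :] = block
    intensity = pd.DataFrame(values, index=index, columns=chips.index)

    truth_rows = [
        (p.strain_id, dose, g, p.per_generation_defect.get(dose, 0.0),
         p.expected_log2_depletion(dose, g))
        for p in planted
        for dose in design.dose_levels
        for g in design.generations
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["strain", "dose", "generation", "defect", "expected_log2_depletion"],
    )
    return intensity, chips, truth


# ---------------------------------------------------------------------------
# pathway graphs


def generate_pathways(
    n_pathways: int,
    sizes: tuple[int, int],
    planted_pathway: str = "pw000",
    n_planted_genes: int = 3,
    adjacency_mode: str = "clustered",
    seed: int = 0,
) -> tuple[dict[str, nx.Graph], list[str], list[str]]:
    """Generate connected pathway graphs over a shared gene universe.

    Each pathway is a connected undirected graph on its own gene ids. In the
    planted pathway, ``n_planted_genes`` genes are marked as perturbed: in
    ``clustered`` mode they form a connected subgraph, in ``scattered`` mode
    no two of them are adjacent.

    Returns ``(pathways, universe, planted_genes)``.
    """
    lo, hi = sizes
    if lo < 3:
        raise ValueError("pathway sizes must be >= 3")
    if adjacency_mode not in ("clustered", "scattered"):
        raise ValueError(f"unknown adjacency_mode {adjacency_mode!r}")
    rng = np.random.default_rng(seed)
    pathways: dict[str, nx.Graph] = {}
    universe: list[str] = []
    planted_genes: list[str] = []
    for k in range(n_pathways):
        pid = f"pw{k:03d}"
        n = int(rng.integers(lo, hi + 1))
        genes = [f"{pid}_gene{i:03d}" for i in range(n)]
        universe.extend(genes)
        # random spanning tree plus a few chords keeps the graph connected
        g = nx.Graph()
        g.add_nodes_from(genes)
        order = list(rng.permutation(genes))
        for a, b in zip(order, order[1:]):
            g.add_edge(a, b)
        extra = max(0, int(rng.integers(0, n // 2 + 1)))
        for _ in range(extra):
            a, b = rng.choice(genes, 2, replace=False)
            if a != b:
                g.add_edge(a, b)
        if pid == planted_pathway:
            if n_planted_genes > n:
                raise ValueError("planted set larger than pathway")
            if adjacency_mode == "clustered":
                # grow a connected set along edges from a random start
                start = order[0]
                chosen = [start]
                frontier = set(g.neighbors(start))
                while len(chosen) < n_planted_genes:
                    nxt = sorted(frontier - set(chosen))[0]
                    chosen.append(nxt)
                    frontier |= set(g.neighbors(nxt))
                planted_genes = chosen
            else:
                chosen = []
                for cand in order:
                    if all(not g.has_edge(cand, c) for c in chosen):
                        chosen.append(cand)
                    if len(chosen) == n_planted_genes:
                        break
                if len(chosen) < n_planted_genes:
                    raise ValueError("could not place a scattered planted set")
                planted_genes = chosen
        pathways[pid] = g
    return pathways, universe, planted_genes


# ---------------------------------------------------------------------------
# interaction network


def generate_network(
    n_nodes: int = 500,
    m_attach: int = 3,
    planted_module_size: int = 12,
    module_density: float = 0.8,
    score_range: tuple[int, int] = (700, 1000),
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Scored interaction network with heavy-tailed degrees and a planted module.

    The backbone is a preferential-attachment graph, which gives the
    heavy-tailed (approximately power-law) degree distribution seen in
    protein-interaction networks, with a relatively small number of highly
    connected hub nodes. A planted module of ``planted_module_size`` nodes is
    densified to ``module_density`` internal edge probability. Edge scores
    are uniform integers in ``score_range``, mimicking high-confidence
    interaction scores.

    Returns ``(edges, module)`` where ``edges`` has columns
    (protein1, protein2, combined_score).
    """
    if planted_module_size >= n_nodes:
        raise ValueError("planted module must be smaller than the network")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31)))
    names = {i: f"prot{i:04d}" for i in g.nodes}
    module_idx = rng.choice(n_nodes, planted_module_size, replace=False)
    for a in range(planted_module_size):
        for b in range(a + 1, planted_module_size):
            if rng.random() < module_density:
                g.add_edge(int(module_idx[a]), int(module_idx[b]))
    lo, hi = score_range
    rows = [
        (names[min(u, v)], names[max(u, v)], int(rng.integers(lo, hi + 1)))
        for u, v in sorted(g.edges())
    ]
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    module = sorted(names[int(i)] for i in module_idx)
    return edges, module


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class WellParams:
    """Logistic growth parameters for one culture condition."""

    strain: str
    compound: str
    dose: float
    lag_h: float = 2.0
    rate_per_h: float = 0.5
    capacity: float = 1.2
    od0: float = 0.02

    def __post_init__(self) -> None:
        if min(self.rate_per_h, self.capacity, self.od0) <= 0 or self.lag_h < 0:
            raise ValueError("kinetic parameters must be positive")


def logistic_od(t: np.ndarray, p: WellParams, dose_rate_factor: float = 1.0) -> np.ndarray:
    """Noise-free logistic OD; the dose acts multiplicatively on growth rate."""
    r = p.rate_per_h * dose_rate_factor
    tt = np.clip(t - p.lag_h, 0.0, None)
    return p.capacity / (1.0 + (p.capacity / p.od0 - 1.0) * np.exp(-r * tt))


def generate_growth_curves(
    wells: list[tuple[WellParams, int]],
    dose_effect: float = 0.0,
    duration_h: float = 24.0,
    interval_min: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format growth curves sampled every 15 min for 24 h (97 points).

    ``wells`` pairs a parameter set with a replicate count; replicates share
    parameters. ``dose_effect`` is the fractional growth-rate reduction per
    unit dose (rate factor ``max(0, 1 - dose_effect * dose)``).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    rows = []
    w = 0
    for params, n_reps in wells:
        factor = max(0.0, 1.0 - dose_effect * params.dose)
        clean = logistic_od(t, params, factor)
        for _ in range(n_reps):
            w += 1
            od = clean + rng.normal(0.0, noise_sd, t.shape) if noise_sd > 0 else clean
            for ti, oi in zip(t, od):
                rows.append((f"well{w:03d}", params.strain, params.compound,
                             params.dose, float(ti), float(oi)))
    return pd.DataFrame(rows, columns=["well", "strain", "compound", "dose", "time_h", "od"])
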