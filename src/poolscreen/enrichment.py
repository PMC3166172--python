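"""Functional-category and pathway enrichment.

Three layers:

* flat hypergeometric over-representation of functional categories (GMT
  gene sets) in a query gene list, upper-tail p = P(X >= k);
* a graph-structure-aware permutation test for pathway enrichment: pathways
  whose perturbed genes sit close to each other in the pathway graph score
  higher than pathways with the same genes scattered. The observed statistic
  for pathway graph (V, E) with per-gene scores s is

      T = mean_{g in V} s_g + mean_{(g,h) in E} min(s_g, s_h)

  (edge term zero for edgeless pathways). The null redistributes scores by
  drawing |V| genes' statistics from the measured universe without
  replacement and assigning them randomly to node positions; the p-value
  uses the plus-one convention p = (1 + #{T* >= T}) / (B + 1), counting ties
  as exceedances. This is a proximity-rewarding statistic in the spirit of
  structurally enhanced pathway enrichment; it is validated by its own
  calibration and topology-sensitivity properties.
* average-linkage hierarchical clustering of -log10 pathway p-value
  profiles under Spearman rank-correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass(frozen=True)
class EnrichmentResult:
    target_id: str
    statistic: float
    p_value: float
    n_permutations: int = 0
    members: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def hypergeom_enrich(
    query: set[str],
    categories: dict[str, set[str]],
    population: set[str],
    p_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric category enrichment.

    ``population`` is the measured gene universe (size N); for each category
    of size K in the population and a query of size n overlapping it in k
    genes, p = P(X >= k) with X ~ Hypergeom(N, K, n). Categories with
    p < ``p_cutoff`` are returned sorted by ascending p.
    """
    if not population:
        raise ValueError("empty population")
    query = set(query) & population
    n = len(query)
    bign = len(population)
    out = []
    for cid, members in categories.items():
        inpop = set(members) & population
        k = len(query & inpop)
        bigk = len(inpop)
        p = float(stats.hypergeom.sf(k - 1, bign, bigk, n))
        if p < p_cutoff:
            out.append(
                EnrichmentResult(
                    cid, float(k), p,
                    members=tuple(sorted(query & inpop)),
                    extra={"N": bign, "K": bigk, "n": n, "k": k},
                )
            )
    return sorted(out, key=lambda r: (r.p_value, r.target_id))


def coverage_filter(
    pathways: dict[str, nx.Graph],
    measured: set[str],
    min_coverage: float = 0.6,
) -> pd.DataFrame:
    """Retain pathways with measured data for at least ``min_coverage`` of genes.

    The boundary is inclusive. Returns a frame with coverage per pathway and
    a ``retained`` flag.
    """
    rows = []
    for pid, g in pathways.items():
        nodes = set(g.nodes)
        cov = len(nodes & measured) / len(nodes) if nodes else 0.0
        rows.append((pid, len(nodes), cov, cov >= min_coverage))
    return pd.DataFrame(rows, columns=["pathway", "n_genes", "coverage", "retained"]).set_index("pathway")


def pathway_statistic(graph: nx.Graph, scores: pd.Series | dict) -> float:
    """Node-mean plus edge-minimum-mean proximity statistic."""
    s = dict(scores)
    nodes = list(graph.nodes)
    t = float(np.mean([s[g] for g in nodes]))
    edges = list(graph.edges)
    if edges:
        t += float(np.mean([min(s[g], s[h]) for g, h in edges]))
    return t


def sepea_test(
    graph: nx.Graph,
    gene_stats: pd.Series,
    n_perm: int = 100_000,
    seed: int = 0,
    chunk: int = 2000,
) -> EnrichmentResult:
    """Permutation pathway-enrichment test on a proximity-rewarding statistic.

    ``gene_stats`` maps every measured gene (the universe) to its gene-level
    dose-response statistic (e.g. Kruskal-Wallis H). The pathway's nodes
    must be a subset of the universe. The null draws |V| statistics from the
    universe without replacement and assigns them to node positions at
    random, ``n_perm`` times.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    nodes = list(graph.nodes)
    missing = [g for g in nodes if g not in gene_stats.index]
    if missing:
        raise ValueError(f"pathway genes without statistics: {missing[:5]}")
    if len(nodes) > len(gene_stats):
        raise ValueError("pathway larger than the measured universe")
    pool = gene_stats.to_numpy(float)
    k = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    edge_idx = np.array([(pos[g], pos[h]) for g, h in graph.edges], dtype=int)
    obs_scores = gene_stats.loc[nodes].to_numpy(float)
    t_obs = _stat_from_vec(obs_scores[None, :], edge_idx)[0]

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # without-replacement draws via per-row random keys
        keys = rng.random((b, len(pool)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        draws = pool[idx]
        t_null = _stat_from_vec(draws, edge_idx)
        exceed += int(np.sum(t_null >= t_obs - 1e-12))
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return EnrichmentResult(
        getattr(graph, "name", "") or "pathway", float(t_obs), float(p),
        n_permutations=n_perm, members=tuple(nodes),
    )


def _stat_from_vec(draws: np.ndarray, edge_idx: np.ndarray) -> np.ndarray:
    t = draws.mean(axis=1)
    if len(edge_idx):
        t = t + np.minimum(draws[:, edge_idx[:, 0]], draws[:, edge_idx[:, 1]]).mean(axis=1)
    return t


def sepea_exhaustive(graph: nx.Graph, gene_stats: pd.Series) -> float:
    """Exact enumeration p-value over all ordered assignments (tiny universes).

    Enumerates every injection of universe genes into the |V| node positions
    and reports the fraction of assignments whose statistic ties or exceeds
    the observed one. Only feasible when ``P(N, |V|)`` is small.
    """
    from itertools import permutations

    nodes = list(graph.nodes)
    k = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    edge_idx = np.array([(pos[g], pos[h]) for g, h in graph.edges], dtype=int)
    pool = gene_stats.to_numpy(float)
    t_obs = _stat_from_vec(gene_stats.loc[nodes].to_numpy(float)[None, :], edge_idx)[0]
    draws = np.array(list(permutations(pool, k)))
    t_all = _stat_from_vec(draws, edge_idx)
    return float(np.mean(t_all >= t_obs - 1e-12))


@dataclass
class PathwayClustergram:
    neglog10: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]


def cluster_pathways(p_matrix: pd.DataFrame) -> PathwayClustergram:
    """Average-linkage clustering of -log10 p profiles, Spearman distance.

    ``p_matrix`` is pathway x condition p-values. Missing entries are
    imputed as p = 1 with a warning. Constant profiles, whose rank
    correlation is undefined, are placed at the maximum correlation distance
    (2) from every other profile.
    """
    if len(p_matrix) < 2:
        raise ValueError("need at least two pathways to cluster")
    p = p_matrix.copy()
    if p.isna().any().any():
        warnings.warn("missing p-values imputed as 1", stacklevel=2)
        p = p.fillna(1.0)
    mat = -np.log10(p.to_numpy(float))
    n = len(p)
    # Spearman = Pearson on within-profile ranks (average ties)
    ranks = stats.rankdata(mat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    constant = mat.std(axis=1) == 0
    if constant.any():
        warnings.warn("constant -log10 p profile; distance set to maximum (2)", stacklevel=2)
        dist[constant, :] = 2.0
        dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    condensed = dist[np.triu_indices(n, 1)]
    link = hierarchy.average(condensed)
    order = hierarchy.leaves_list(link)
    return PathwayClustergram(
        neglog10=pd.DataFrame(mat, index=p.index, columns=p.columns),
        linkage=link,
        leaf_order=[p.index[i] for i in order],
    )
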