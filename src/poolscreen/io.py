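"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8, tab-separated with a header row; missing values are
empty fields, matching the blank-cell convention of printed fitness tables.
Unicode minus signs (U+2212) are normalized to ASCII hyphens on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def _read_text(path: str | Path) -> str:
    return Path(path).read_text(encoding="utf-8").replace("−", "-")


def read_intensity(path: str | Path) -> pd.DataFrame:
    """Read a (strain, tag) x chip log2 intensity TSV."""
    df = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t")
    if df.columns[:2].tolist() != ["strain", "tag"]:
        raise ValueError(f"{path}: expected leading 'strain' and 'tag' columns")
    return df.set_index(["strain", "tag"])


def write_intensity(m: pd.DataFrame, path: str | Path) -> None:
    m.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t",
                     dtype={"chip": str, "compound": str, "dose": str})
    required = {"chip", "compound", "dose", "generation", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    return df.set_index("chip")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(_read_text(path).splitlines(), 1):
        if not line.strip():
            continue
        parts = [p for p in line.rstrip("\t").split("\t")]
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description and >=1 member")
        name, _desc, *members = parts
        sets[name] = {m for m in members if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Pathway edge list TSV: pathway_id, gene_a, gene_b."""
    df = pd.read_csv(_io.StringIO(_read_text(path)), sep="\t", dtype=str)
    if list(df.columns) != ["pathway_id", "gene_a", "gene_b"]:
        raise ValueError(f"{path}: expected columns pathway_id, gene_a, gene_b")
    return df


def write_edge_list(pathways: dict, path: str | Path) -> None:
    rows = [
        (pid, a, b)
        for pid, g in pathways.items()
        for a, b in sorted(tuple(sorted(e)) for e in g.edges)
    ]
    pd.DataFrame(rows, columns=["pathway_id", "gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_string_edges(path: str | Path) -> pd.DataFrame:
    """Scored interaction edges: protein1, protein2, combined_score."""
    text = _read_text(path)
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype={"protein1": str, "protein2": str})
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    bad = pd.to_numeric(df["combined_score"], errors="coerce").isna()
    if bad.any():
        raise ValueError(f"{path}: malformed score at line {int(np.flatnonzero(bad)[0]) + 2}")
    return df


def write_string_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_io.StringIO(_read_text(path)))
    required = {"well", "strain", "compound", "dose", "time_h", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: growth CSV missing columns {sorted(missing)}")
    return df


def write_growth_csv(curves: pd.DataFrame, path: str | Path) -> None:
    curves.to_csv(path, index=False, float_format="%.6g")


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            bl = max(node.dist - child.dist, 0.0)
            parts.append(f"{walk(child)}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"

    return walk(tree) + ";"


def write_newick(linkage: np.ndarray, labels: list[str], path: str | Path) -> None:
    Path(path).write_text(linkage_to_newick(linkage, labels) + "\n", encoding="utf-8")
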