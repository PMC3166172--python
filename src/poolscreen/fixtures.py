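"""Transcribed consensus-hit tables shipped with the package.

The three TSV files under ``data/`` are transcriptions of the printed
per-compound consensus tables of the screen this package models (hydroquinone,
catechol and 1,2,4-benzenetriol). Each row is a gene whose deletion strain was
significantly sensitive in at least three of the six treatment conditions for
that compound; cells hold the fitness score (log2 ratio) where the strain was
significant and are empty otherwise. Unicode minus signs were normalized to
ASCII during transcription.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

CONDITION_COLUMNS = ["5g_25", "5g_50", "5g_100", "15g_25", "15g_50", "15g_100"]

_FILES = {
    "T2": "table2_hq_consensus.tsv",
    "T3": "table3_cat_consensus.tsv",
    "T4": "table4_bt_consensus.tsv",
}

COMPOUND_OF = {"T2": "HQ", "T3": "CAT", "T4": "BT"}


def load_paper_fixture(table_id: str) -> pd.DataFrame:
    """Load one consensus fitness table (``T2``, ``T3`` or ``T4``).

    Returns a DataFrame indexed by ORF with a ``gene`` column (standard name,
    may be empty) and one float column per condition; NaN marks a cell where
    the strain was not significant.
    """
    if table_id not in _FILES:
        raise KeyError(f"unknown fixture table {table_id!r}; expected one of {sorted(_FILES)}")
    ref = resources.files("poolscreen.data").joinpath(_FILES[table_id])
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"orf": str, "gene": str})
    expected = ["orf", "gene", *CONDITION_COLUMNS]
    if list(df.columns) != expected:
        raise ValueError(f"malformed fixture {table_id}: columns {list(df.columns)}")
    df["gene"] = df["gene"].fillna("")
    for c in CONDITION_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
    if df["orf"].duplicated().any():
        raise ValueError(f"malformed fixture {table_id}: duplicate ORFs")
    if not np.isfinite(df[CONDITION_COLUMNS].to_numpy()).any(axis=1).all():
        raise ValueError(f"malformed fixture {table_id}: row with no scores")
    return df.set_index("orf")
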