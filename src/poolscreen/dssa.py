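"""Differential strain sensitivity analysis (DSSA).

For each strain and treatment condition the fitness score is

    score = mean(log2 signal | treated) - mean(log2 signal | control)

computed on chip-level (tag-averaged, normalized) values. A negative score
means the deletion strain depleted from the pool, i.e. the deleted gene is
required for tolerance of the compound. Per-condition significance is a
Welch (unequal-variance) two-sample t test of treated versus control chips,
with Benjamini-Hochberg q-values within the condition. A consensus filter
then flags genes significant in at least ``k_min`` of a compound's six
conditions (3 doses x 2 generations), mirroring the printed consensus
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datagen import CONTROL
from .fixtures import CONDITION_COLUMNS


@dataclass(frozen=True)
class TreatmentCondition:
    """One of the six treatment conditions of a compound."""

    compound: str
    dose: str        # percent of IC20: "25", "50" or "100"
    generation: int  # doublings: 5 or 15

    @property
    def label(self) -> str:
        return f"{self.generation}g_{self.dose}"


def conditions_for(compound: str, design: pd.DataFrame) -> list[TreatmentCondition]:
    """Enumerate the treatment conditions of ``compound`` present in a design."""
    treated = design[design["compound"] == compound]
    out = [
        TreatmentCondition(compound, dose, int(g))
        for (g, dose) in sorted(
            {(r["generation"], r["dose"]) for _, r in treated.iterrows()},
            key=lambda t: (t[0], float(t[1])),
        )
    ]
    if not out:
        raise KeyError(f"no treated chips for compound {compound!r} in design")
    return out


def _split_chips(design: pd.DataFrame, condition: TreatmentCondition) -> tuple[list, list]:
    treated = design[
        (design["compound"] == condition.compound)
        & (design["dose"] == condition.dose)
        & (design["generation"] == condition.generation)
    ].index.tolist()
    controls = design[
        (design["dose"] == CONTROL) & (design["generation"] == condition.generation)
    ].index.tolist()
    if not controls:  # shared control set across generations
        controls = design[design["dose"] == CONTROL].index.tolist()
    if len(treated) < 2 or len(controls) < 2:
        raise KeyError(
            f"condition {condition} needs >=2 treated and >=2 control chips "
            f"(found {len(treated)}/{len(controls)})"
        )
    return treated, controls


def fitness_scores(
    values: pd.DataFrame, design: pd.DataFrame, condition: TreatmentCondition
) -> pd.Series:
    """Per-strain fitness score for one condition (negative = sensitive)."""
    treated, controls = _split_chips(design, condition)
    score = values[treated].mean(axis=1) - values[controls].mean(axis=1)
    score.name = condition.label
    return score


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-strain variances toward a common value.

    Models the sample variances as scaled F draws around a common prior
    (s0^2, d0) and estimates the prior by matching the moments of log s^2
    (the spread of log variances in excess of what df alone explains fixes
    the prior df). Returns the posterior variances
    (d0 s0^2 + df s^2) / (d0 + df) and d0. Degenerate inputs (zero spread)
    collapse to complete pooling.
    """
    from scipy.special import digamma, polygamma
    from scipy.optimize import brentq

    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    e = np.log(s2[ok])
    excess = e.var(ddof=1) - polygamma(1, df / 2.0)
    if excess <= 1e-8:
        d0 = np.inf
    else:
        f = lambda d0: polygamma(1, d0 / 2.0) - excess
        if f(0.1) < 0:  # spread larger than any prior can explain
            d0 = 0.1
        else:
            d0 = brentq(f, 0.1, 1e7)
    if np.isinf(d0):
        s0_2 = float(np.exp(e.mean() - digamma(df / 2.0) + np.log(df / 2.0)))
        return np.full_like(s2, s0_2), d0
    s0_2 = float(np.exp(e.mean() - digamma(df / 2.0) + digamma(d0 / 2.0)
                        + np.log(df / d0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, float(d0)


def significance(
    values: pd.DataFrame,
    design: pd.DataFrame,
    condition: TreatmentCondition,
    alpha: float = 0.05,
    moderated: bool = True,
) -> pd.DataFrame:
    """Per-strain treated-vs-control test with BH q-values within the condition.

    The default is a variance-moderated unequal-variance t: each group's
    per-strain variance is shrunk toward the across-strain consensus before
    entering the Welch statistic, and the Satterthwaite degrees of freedom
    are computed from the moderated variances with the prior df added to
    each group's df. With only three treated chips the raw Welch statistic
    has ~2 residual df and a far tail so heavy that Benjamini-Hochberg loses
    false-discovery control; moderation restores calibrated tails exactly as
    in standard small-replicate array practice. ``moderated=False`` gives the
    plain Welch test.

    Degenerate strains (zero variance in both groups) get p = 1 when the
    group means agree and p = 0 when they differ.
    """
    treated, controls = _split_chips(design, condition)
    x = values[treated].to_numpy(float)
    y = values[controls].to_numpy(float)
    diff = np.nanmean(x, axis=1) - np.nanmean(y, axis=1)
    if moderated:
        nx = np.sum(np.isfinite(x), axis=1)
        ny = np.sum(np.isfinite(y), axis=1)
        vx = np.nanvar(x, axis=1, ddof=1)
        vy = np.nanvar(y, axis=1, ddof=1)
        dfx, dfy = float(np.median(nx) - 1), float(np.median(ny) - 1)
        vx_mod, d0x = _squeeze_variances(vx, dfx)
        vy_mod, d0y = _squeeze_variances(vy, dfy)
        ax_, ay_ = vx_mod / nx, vy_mod / ny
        se2 = ax_ + ay_
        dfx_t = np.minimum(dfx + d0x, 1e6)
        dfy_t = np.minimum(dfy + d0y, 1e6)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(se2)
            df = se2**2 / (ax_**2 / dfx_t + ay_**2 / dfy_t)
            p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        res = stats.ttest_ind(x, y, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = np.where(np.abs(diff[degenerate]) < 1e-12, 1.0, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "score": diff,
            "p_value": p,
            "q_value": q,
            "significant": q < alpha,
        },
        index=values.index,
    )
    return out


def dssa_table(
    values: pd.DataFrame,
    design: pd.DataFrame,
    compound: str,
    alpha: float = 0.05,
    moderated: bool = True,
) -> pd.DataFrame:
    """Long-format fitness table over all conditions of one compound."""
    frames = []
    for cond in conditions_for(compound, design):
        sig = significance(values, design, cond, alpha=alpha, moderated=moderated)
        sig.insert(0, "condition", cond.label)
        sig.insert(0, "compound", compound)
        frames.append(sig.reset_index(names="strain"))
    return pd.concat(frames, ignore_index=True)


def consensus_filter(
    table: pd.DataFrame, k_min: int = 3, sign: str = "any"
) -> pd.DataFrame:
    """Genes significant in at least ``k_min`` conditions.

    ``table`` is either the long table from :func:`dssa_table` (with a
    ``significant`` column) or a wide printed-table fixture whose condition
    cells are scores-if-significant and NaN otherwise. ``sign`` restricts the
    counted conditions to ``negative_only`` scores or counts ``any`` sign;
    the printed consensus tables include a resistant (positive-score) gene,
    so ``any`` is the default.

    Returns a per-gene frame with ``n_significant_conditions`` and a
    ``consensus`` flag, sorted by descending count.
    """
    if sign not in ("any", "negative_only"):
        raise ValueError(f"unknown sign mode {sign!r}")
    if "significant" in table.columns:  # long format
        t = table.copy()
        hit = t["significant"].to_numpy(bool)
        if sign == "negative_only":
            hit &= t["score"].to_numpy(float) < 0
        t["hit"] = hit
        counts = t.groupby("strain", sort=False)["hit"].sum().astype(int)
    else:  # wide fixture format
        cols = [c for c in CONDITION_COLUMNS if c in table.columns]
        block = table[cols]
        hit = block.notna()
        if sign == "negative_only":
            hit &= block < 0
        counts = hit.sum(axis=1).astype(int)
    out = pd.DataFrame(
        {
            "n_significant_conditions": counts,
            "consensus": counts >= k_min,
        }
    )
    return out.sort_values("n_significant_conditions", ascending=False)


def consensus_genes(table: pd.DataFrame, k_min: int = 3, sign: str = "any") -> list[str]:
    c = consensus_filter(table, k_min=k_min, sign=sign)
    return c.index[c["consensus"]].tolist()
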