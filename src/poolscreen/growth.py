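"""Growth-curve summaries: AUC, percent of control, and ICx estimation.

Microplate OD readings (15-minute intervals over 24 h) are background
corrected by subtracting each well's initial reading, integrated by the
trapezoid rule to an area under the curve (AUC, od-hours) as the growth
measure, and expressed as a percentage of the untreated control. The ICx
(dose inhibiting growth by x percent) is read off the mean dose-response
by linear interpolation at the first crossing of the (100 - x)% level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def background_correct(curve: pd.DataFrame) -> pd.DataFrame:
    """Subtract each well's first (pre-growth) OD reading."""
    out = curve.copy()
    first_time = out.groupby("well")["time_h"].transform("min")
    base = out.loc[out["time_h"] == first_time, ["well", "od"]].drop_duplicates("well")
    out = out.merge(base.rename(columns={"od": "od0"}), on="well")
    out["od"] = out["od"] - out["od0"]
    return out.drop(columns="od0")


def auc(time_h: np.ndarray, od: np.ndarray) -> float:
    """Trapezoidal area under the growth curve in od-hours."""
    t = np.asarray(time_h, float)
    y = np.asarray(od, float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    return float(np.trapezoid(y, t))


def well_aucs(curves: pd.DataFrame, correct_background: bool = True) -> pd.DataFrame:
    """AUC per well; negative AUCs are kept but flagged."""
    c = background_correct(curves) if correct_background else curves
    rows = []
    for well, grp in c.groupby("well"):
        grp = grp.sort_values("time_h")
        a = auc(grp["time_h"].to_numpy(), grp["od"].to_numpy())
        meta = grp.iloc[0]
        rows.append((well, meta["strain"], meta["compound"], float(meta["dose"]), a, a < 0))
    return pd.DataFrame(rows, columns=["well", "strain", "compound", "dose", "auc", "negative"])


def percent_of_control(treated: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Mean treated AUC as a percent of mean control AUC, with SE.

    The standard error propagates replicate variation of both means through
    the ratio by the delta method:
    SE = 100 * (T/C) * sqrt(var(T)/T^2 + var(C)/C^2) with var(.) the
    squared standard error of each mean.
    """
    t = np.asarray(treated, float)
    c = np.asarray(control, float)
    if len(t) < 1 or len(c) < 1:
        raise ValueError("need at least one replicate per group")
    mt, mc = t.mean(), c.mean()
    if mc == 0:
        raise ValueError("control mean AUC is zero")
    pct = 100.0 * mt / mc
    vt = t.var(ddof=1) / len(t) if len(t) > 1 else 0.0
    vc = c.var(ddof=1) / len(c) if len(c) > 1 else 0.0
    se = abs(pct) * np.sqrt((vt / mt**2 if mt != 0 else 0.0) + vc / mc**2)
    return float(pct), float(se)


def dose_response(aucs: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-control response per dose (dose 0 is the control).

    Expects the output of :func:`well_aucs` for one strain/compound. The
    response at dose 0 is 100% by construction.
    """
    if not (aucs["dose"] == 0).any():
        raise ValueError("no dose-0 control wells")
    control = aucs.loc[aucs["dose"] == 0, "auc"].to_numpy()
    rows = []
    for dose, grp in aucs.groupby("dose"):
        pct, se = percent_of_control(grp["auc"].to_numpy(), control)
        rows.append((float(dose), pct, se, len(grp)))
    return pd.DataFrame(rows, columns=["dose", "percent_of_control", "se", "n"]).sort_values("dose")


def icx(dr: pd.DataFrame, x: float = 20.0) -> float | None:
    """Dose at which the response first crosses (100 - x)% of control.

    Linear interpolation between the flanking grid doses; ``None`` (with no
    exception) when the response never crosses the level.
    """
    level = 100.0 - x
    d = dr.sort_values("dose")
    doses = d["dose"].to_numpy(float)
    resp = d["percent_of_control"].to_numpy(float)
    for i in range(len(doses) - 1):
        lo, hi = resp[i], resp[i + 1]
        if (lo - level) * (hi - level) <= 0 and lo != hi:
            frac = (lo - level) / (lo - hi)
            return float(doses[i] + frac * (doses[i + 1] - doses[i]))
    return None


def treatment_doses(ic20: float) -> dict[str, float]:
    """Equitoxic exposure ladder used in the pooled screen: 25%, 50%, 100% of IC20."""
    return {"25": 0.25 * ic20, "50": 0.5 * ic20, "100": ic20}
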