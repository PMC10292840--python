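"""Conversion of group-difference statistics to correlation-scale effects.

Extreme-group designs (young vs old) report a standardized mean difference
d or a t statistic; both are mapped to a point-biserial correlation via
r = d / sqrt(d^2 + a), a = (n1+n2)^2 / (n1*n2), with a delta-method
sampling variance. Continuous-age designs use Pearson's r with the usual
large-sample variance (1-r^2)^2 / (n-1). Pooling happens on the raw
correlation scale throughout (not Fisher-z).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

GROUP_STATS_COLUMNS = (
    "mean_young", "mean_old", "sd_young", "sd_old", "n_young", "n_old", "t_value",
)


@dataclass(frozen=True)
class GroupStats:
    """Two-group summary statistics for one young-vs-old comparison."""

    n_young: int
    n_old: int
    mean_young: float | None = None
    mean_old: float | None = None
    sd_young: float | None = None
    sd_old: float | None = None
    t_value: float | None = None


def smd_to_r(d: float, n1: int, n2: int) -> tuple[float, float]:
    """Standardized mean difference -> point-biserial r and its variance.

    var_r is the delta-method transform of
    var_d = (n1+n2)/(n1*n2) + d^2/(2*(n1+n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"group sizes must be >= 2 (got {n1}, {n2})")
    a = (n1 + n2) ** 2 / (n1 * n2)
    r = d / math.sqrt(d * d + a)
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2))
    var_r = a * a * var_d / (d * d + a) ** 3
    return r, var_r


def t_to_r(t: float, df: int) -> float:
    """t statistic of a two-group comparison -> point-biserial r."""
    if df < 1:
        raise ValueError(f"df must be >= 1 (got {df})")
    return t / math.sqrt(t * t + df)


def pearson_var(r: float, n: int) -> float:
    """Large-sample variance of Pearson's r: (1-r^2)^2 / (n-1)."""
    if n < 3:
        raise ValueError(f"n must be >= 3 (got {n})")
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1 (got {r})")
    return (1 - r * r) ** 2 / (n - 1)


def orient(r: float, trait_increases_with_age_when_positive: bool) -> float:
    """Enforce the direction convention: positive = trait increases with age.

    Flips the sign when the source statistic was coded the other way round.
    """
    return r if trait_increases_with_age_when_positive else -r


def from_group_stats(gs: GroupStats) -> tuple[float, float]:
    """(r, var_r) from two-group stats; prefers means/SDs, falls back to t.

    d is signed old minus young, so a positive r means the outcome is higher
    in the older group. Pooled SD uses the usual (n-1)-weighted combination.
    """
    n1, n2 = gs.n_young, gs.n_old
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    have_means = all(
        x is not None and np.isfinite(x)
        for x in (gs.mean_young, gs.mean_old, gs.sd_young, gs.sd_old)
    )
    if have_means:
        sp = math.sqrt(
            ((n1 - 1) * gs.sd_young**2 + (n2 - 1) * gs.sd_old**2) / (n1 + n2 - 2)
        )
        if sp <= 0:
            raise ValueError("pooled SD must be positive")
        d = (gs.mean_old - gs.mean_young) / sp
    elif gs.t_value is not None and np.isfinite(gs.t_value):
        d = gs.t_value * math.sqrt(1 / n1 + 1 / n2)
    else:
        raise ValueError("need either means+SDs or a t value alongside group sizes")
    return smd_to_r(d, n1, n2)


def convert_group_stats_table(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a table of two-group statistics to (r, var_r) columns.

    Extra ``mean_*``/``sd_*``/``n_*`` columns beyond the young/old pair are
    rejected: intermediate age groups do not enter the analysis.
    """
    extra = [
        c for c in df.columns
        if c.split("_")[0] in {"mean", "sd", "n"} and c not in GROUP_STATS_COLUMNS
    ]
    if extra:
        raise ValueError(
            f"only youngest-vs-oldest comparisons are supported; "
            f"unexpected group columns: {extra}"
        )
    missing = [c for c in ("n_young", "n_old") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    out = df.copy()
    rs, vs = [], []
    for row in df.itertuples(index=False):
        d = row._asdict()
        gs = GroupStats(
            n_young=int(d["n_young"]),
            n_old=int(d["n_old"]),
            mean_young=d.get("mean_young"),
            mean_old=d.get("mean_old"),
            sd_young=d.get("sd_young"),
            sd_old=d.get("sd_old"),
            t_value=d.get("t_value"),
        )
        r, v = from_group_stats(gs)
        rs.append(r)
        vs.append(v)
    out["r"] = rs
    out["var_r"] = vs
    return out
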