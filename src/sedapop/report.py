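"""Group comparison statistics and stratigraphic summary tables.

Welch's unequal-variance t-test (with Welch-Satterthwaite degrees of
freedom and two-sided p-values) is the comparison used for damage rates,
fragment lengths and lineage proportions between colony-age groups;
ordinary least squares supports the colony-size ~ diversity regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupStats:
    """Result container for two-group comparisons and simple regressions."""

    n_x: int = 0
    n_y: int = 0
    mean_x: float = float("nan")
    mean_y: float = float("nan")
    var_x: float = float("nan")
    var_y: float = float("nan")
    t: float = float("nan")
    df: float = float("nan")
    p: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    degenerate: bool = False


def welch_t(x, y) -> GroupStats:
    """Welch's two-sample t-test, two-sided.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny); df by Welch-Satterthwaite.
    Both variances zero with equal means yields t = 0 with df flagged
    degenerate; n < 2 in either group is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if mx == my:
            return GroupStats(
                n_x=nx, n_y=ny, mean_x=mx, mean_y=my, var_x=vx, var_y=vy,
                t=0.0, df=float("nan"), p=1.0, degenerate=True,
            )
        raise ValueError("zero variance in both groups with unequal means")
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupStats(
        n_x=nx, n_y=ny, mean_x=float(mx), mean_y=float(my),
        var_x=float(vx), var_y=float(vy), t=float(t), df=float(df), p=float(p),
    )


def linear_fit(x, y) -> GroupStats:
    """Ordinary least squares y ~ x with r^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("linear_fit requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sps.linregress(x, y)
    pred = res.intercept + res.slope * x
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else 0.0
    return GroupStats(
        n_x=len(x), n_y=len(x), slope=float(res.slope),
        intercept=float(res.intercept), r2=float(r2),
        t=float(res.slope / res.stderr) if res.stderr > 0 else float("nan"),
        df=float(len(x) - 2), p=float(res.pvalue),
    )


def stratigraphic_table(metrics: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-site stratigraphic report: samples ordered by depth with their
    summary metrics as columns.

    ``metrics`` is indexed (or keyed) by sample_id and may carry mean_pi,
    prop_rs, ct_rate_1, fish and krill read counts; ``meta`` needs
    sample_id, site and depth_cm.  A fish:krill ratio column is added when
    both counts are present (zero-krill denominators are flagged NaN with
    ``ratio_defined`` False).  Rows with missing metadata are flagged.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    metrics = metrics.copy()
    if "sample_id" in metrics.columns:
        metrics = metrics.set_index("sample_id")
    table = meta.join(metrics, how="left")
    table["meta_missing"] = table[["site", "depth_cm"]].isna().any(axis=1)
    if {"fish_reads", "krill_reads"} <= set(table.columns):
        krill = table["krill_reads"].astype(float)
        table["fish_krill_ratio"] = np.where(
            krill > 0, table["fish_reads"].astype(float) / krill, np.nan
        )
        table["ratio_defined"] = krill > 0
    return table.sort_values(["site", "depth_cm"], na_position="last")
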