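"""Genetic and phenotypic trends across generations, inbreeding summaries.

The genetic trend is the regression of the per-generation mean predicted
breeding value on the generation number — the realized response to
selection.  Generation means enter the regression unweighted by default;
animal-level regression is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrendResult:
    table: pd.DataFrame      # generation, n, mean
    slope: float             # trait units per generation
    slope_se: float
    intercept: float
    p: float
    r2: float


def _ols_trend(x: np.ndarray, y: np.ndarray):
    k = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    tss = float(((y - ybar) ** 2).sum())
    df = k - 2
    scale = max(tss, 1.0)
    if rss <= 1e-14 * scale:
        # exact fit: slope inference degenerates
        se = 0.0
        p = 1.0 if abs(slope) <= 1e-14 * math.sqrt(scale) else 0.0
        r2 = 1.0 if tss > 0 else float("nan")
    else:
        se = math.sqrt(rss / df / sxx)
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return slope, se, intercept, p, r2


def _trend_from_values(df: pd.DataFrame, value_col: str,
                       per_animal: bool) -> TrendResult:
    grouped = df.groupby("generation")[value_col]
    table = grouped.agg(n="size", mean="mean").reset_index()
    table = table.sort_values("generation").reset_index(drop=True)
    if len(table) < 3:
        raise ValueError("trend regression needs at least 3 generations")
    if per_animal:
        x = df["generation"].to_numpy(dtype=float)
        y = df[value_col].to_numpy(dtype=float)
    else:
        x = table["generation"].to_numpy(dtype=float)
        y = table["mean"].to_numpy(dtype=float)
    slope, se, intercept, p, r2 = _ols_trend(x, y)
    return TrendResult(table=table, slope=slope, slope_se=se,
                       intercept=intercept, p=p, r2=r2)


def genetic_trend(bv_table: pd.DataFrame, value_col: str = "bv_direct",
                  per_animal: bool = False,
                  include_generations=None) -> TrendResult:
    """OLS of per-generation mean breeding value on generation number.

    ``include_generations`` restricts to the listed generations (e.g. to
    exclude an unrecorded founder generation).
    """
    df = bv_table
    if include_generations is not None:
        df = df[df["generation"].isin(include_generations)]
    return _trend_from_values(df, value_col, per_animal)


def phenotypic_trend(records: pd.DataFrame, trait: str,
                     per_animal: bool = False) -> TrendResult:
    """OLS of per-generation raw trait mean on generation number."""
    df = records.loc[records[trait].notna()]
    return _trend_from_values(df, trait, per_animal)


def inbreeding_summary(F: np.ndarray):
    """(mean F overall, mean F among inbred animals, number inbred).

    An animal is inbred when F > 0; with no inbred animals the second
    mean is not available (NaN).
    """
    F = np.asarray(F, dtype=float)
    inbred = F > 0
    n_inbred = int(inbred.sum())
    mean_all = float(F.mean()) if len(F) else float("nan")
    mean_inbred = float(F[inbred].mean()) if n_inbred else float("nan")
    return mean_all, mean_inbred, n_inbred
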