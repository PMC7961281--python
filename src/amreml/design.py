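"""Fixed-effect encoding, least-squares means and factor screening.

Factors are coded sum-to-zero, so in an additive model the least-squares
mean of a level is simply intercept + level effect, and the grand mean
equals the unweighted average of the level means.  Factor significance
uses Type-III style F tests (full model vs. the model with that factor's
columns removed), which is what decides whether a factor enters the
downstream genetic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


@dataclass
class FixedEffectSpec:
    """Ordered factors with declared level sets (sum-to-zero coding)."""

    factors: list  # list of (name, [levels])

    @property
    def names(self):
        return [f[0] for f in self.factors]

    def levels(self, name):
        for f, lv in self.factors:
            if f == name:
                return list(lv)
        raise KeyError(name)

    @classmethod
    def from_data(cls, records: pd.DataFrame, names) -> "FixedEffectSpec":
        """Infer level sets from the data (sorted order)."""
        factors = []
        for name in names:
            lv = sorted(records[name].dropna().unique().tolist())
            factors.append((name, lv))
        return cls(factors)


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list          # 'intercept' or (factor, level)
    factor_cols: dict      # factor -> list of column indices
    rows: np.ndarray       # indices of retained records in the input frame
    n_dropped: int
    inestimable: list      # (factor, level) with zero observations


@dataclass
class LSMeansTable:
    means: pd.DataFrame    # factor, level, estimate, se, n
    tests: pd.DataFrame    # factor, F, df_num, df_den, p, retain
    grand_mean: float
    grand_se: float
    alpha: float = 0.05

    def retained_factors(self):
        return self.tests.loc[self.tests["retain"], "factor"].tolist()


def build_design(records: pd.DataFrame, spec: FixedEffectSpec,
                 trait: str | None = None) -> DesignMatrix:
    """Sum-to-zero full-column-rank incidence matrix for the fixed effects.

    Records missing the trait value (when given) are dropped and counted.
    A record with a level outside the declared set is a hard error.
    """
    df = records
    keep = np.ones(len(df), dtype=bool)
    if trait is not None:
        keep &= df[trait].notna().to_numpy()
    n_dropped = int((~keep).sum())
    rows = np.flatnonzero(keep)
    df = df.iloc[rows]

    cols = ["intercept"]
    blocks = [np.ones((len(df), 1))]
    factor_cols = {}
    inestimable = []
    for name, levels in spec.factors:
        vals = df[name].to_numpy()
        bad = ~np.isin(vals, np.asarray(levels, dtype=vals.dtype))
        if bad.any():
            offending = df.index[bad][:10].tolist()
            raise DesignError(
                f"factor {name!r} has undeclared levels in rows {offending}")
        observed = [lv for lv in levels if (vals == lv).any()]
        for lv in levels:
            if lv not in observed:
                inestimable.append((name, lv))
        if len(observed) < 2:
            logger.warning("factor %r has <2 observed levels; skipped", name)
            factor_cols[name] = []
            continue
        ref = observed[-1]
        start = sum(b.shape[1] for b in blocks)
        block = np.zeros((len(df), len(observed) - 1))
        for j, lv in enumerate(observed[:-1]):
            block[vals == lv, j] = 1.0
            cols.append((name, lv))
        block[vals == ref, :] = -1.0
        blocks.append(block)
        factor_cols[name] = list(range(start, start + block.shape[1]))

    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("fixed-effect design is rank deficient "
                          "(confounded factors or empty cells)")
    return DesignMatrix(X=X, columns=cols, factor_cols=factor_cols,
                        rows=rows, n_dropped=n_dropped,
                        inestimable=inestimable)


def ls_means(records: pd.DataFrame, spec: FixedEffectSpec, trait: str,
             alpha: float = 0.05) -> LSMeansTable:
    """Least-squares means per factor level with Type-III style F tests.

    The LSM of a level is the model-based marginal mean averaging over the
    other factors; under sum-to-zero coding and an additive model this is
    intercept + level effect.  Factors with p <= alpha are flagged for
    retention in the genetic model.
    """
    design = build_design(records, spec, trait=trait)
    X = design.X
    y = records.iloc[design.rows][trait].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError("not enough records to fit the fixed-effect model")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid

    vals_by_factor = {name: records.iloc[design.rows][name].to_numpy()
                      for name in spec.names}

    rows_out = []
    for name, levels in spec.factors:
        cidx = design.factor_cols[name]
        observed = [lv for lv in levels if (name, lv) not in design.inestimable]
        for lv in levels:
            if (name, lv) in design.inestimable:
                rows_out.append((name, lv, np.nan, np.nan, 0))
                continue
            c = np.zeros(p)
            c[0] = 1.0
            if cidx:
                if lv == observed[-1]:
                    for j in cidx:
                        c[j] = -1.0
                else:
                    j = cidx[observed.index(lv)]
                    c[j] = 1.0
            est = float(c @ beta)
            se = float(np.sqrt(sigma2 * c @ XtX_inv @ c))
            cnt = int((vals_by_factor[name] == lv).sum())
            rows_out.append((name, lv, est, se, cnt))
    means = pd.DataFrame(rows_out,
                         columns=["factor", "level", "estimate", "se", "n"])

    tests_out = []
    for name, _ in spec.factors:
        cidx = design.factor_cols[name]
        if not cidx:
            tests_out.append((name, np.nan, 0, df_resid, np.nan, False))
            continue
        keep = [j for j in range(p) if j not in cidx]
        Xr = X[:, keep]
        beta_r, rss_r = np.linalg.lstsq(Xr, y, rcond=None)[:2]
        rss_r = float(rss_r[0]) if len(rss_r) else float(
            np.sum((y - Xr @ beta_r) ** 2))
        df_num = len(cidx)
        F = ((rss_r - rss) / df_num) / sigma2
        pval = float(stats.f.sf(F, df_num, df_resid))
        tests_out.append((name, float(F), df_num, df_resid, pval,
                          pval <= alpha))
    tests = pd.DataFrame(tests_out, columns=["factor", "F", "df_num",
                                             "df_den", "p", "retain"])

    grand_se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    return LSMeansTable(means=means, tests=tests,
                        grand_mean=float(beta[0]), grand_se=grand_se,
                        alpha=alpha)
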