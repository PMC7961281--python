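"""Genetic-parameter derivation and likelihood-ratio model selection.

Variance-component estimates become the field's standard ratios —
heritability h2 = s2_a/s2_p, maternal m2 = s2_m/s2_p, maternal permanent
environmental c2 = s2_c/s2_p, the direct-maternal correlation r_am, and
total heritability h2_T = h2 + 0.5 m2 + 1.5 m r_am h — with delta-method
standard errors.  Model choice walks the nesting lattice of the six
random-effect structures by likelihood-ratio tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from amreml.varcomp import (BivariateResult, FitResult, ModelSpec,
                            VarianceComponents)

logger = logging.getLogger(__name__)


@dataclass
class GeneticParameters:
    h2: float
    h2_se: float | None = None
    m2: float | None = None
    m2_se: float | None = None
    c2: float | None = None
    c2_se: float | None = None
    r_am: float | None = None
    r_am_se: float | None = None
    h2_T: float = 0.0
    sigma2_p: float = 0.0
    sigma2_p_se: float | None = None

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("h2", "h2_se", "m2", "m2_se", "c2", "c2_se",
                 "r_am", "r_am_se", "h2_T", "sigma2_p", "sigma2_p_se")}


@dataclass
class ModelComparison:
    table: pd.DataFrame        # model_id, n_params, logL, converged
    lrt_table: pd.DataFrame    # small, large, statistic, df, p
    best_model_id: int
    alpha: float


def total_heritability(h2: float, m2: float | None = None,
                       r_am: float | None = None) -> float:
    """h2_T = h2 + 0.5 m2 + 1.5 m r_am h, with h = sqrt(h2), m = sqrt(m2).

    The total heritability measures the transmissible fraction of the
    phenotypic variance when the dam's genes act on her offspring both
    directly and through the maternal environment; absent terms count 0.
    """
    m2 = m2 or 0.0
    r_am = r_am or 0.0
    h = math.sqrt(max(h2, 0.0))
    m = math.sqrt(max(m2, 0.0))
    return h2 + 0.5 * m2 + 1.5 * m * r_am * h


def _ratios_from_vector(vec: np.ndarray, names: list,
                        include_cov_am: bool) -> dict:
    d = dict(zip(names, vec))
    s2a = d.get("sigma2_a", 0.0)
    s2m = d.get("sigma2_m", 0.0)
    sam = d.get("sigma_am", 0.0)
    s2c = d.get("sigma2_c", 0.0)
    s2e = d.get("sigma2_e", 0.0)
    s2p = s2a + s2m + s2c + s2e + (sam if include_cov_am else 0.0)
    out = {"sigma2_p": s2p, "h2": s2a / s2p}
    if "sigma2_m" in names:
        out["m2"] = s2m / s2p
    if "sigma2_c" in names:
        out["c2"] = s2c / s2p
    if "sigma_am" in names:
        denom = math.sqrt(abs(s2a * s2m))
        out["r_am"] = sam / denom if denom > 0 else 0.0
    out["h2_T"] = total_heritability(out["h2"], out.get("m2"),
                                     out.get("r_am"))
    return out


def derive_parameters(fit: FitResult | VarianceComponents,
                      include_cov_am: bool | None = None) -> GeneticParameters:
    """Variance ratios (and total heritability) with delta-method SEs.

    Accepts either a full fit (SEs propagated from its information
    matrix) or bare components (point estimates only).  A component the
    model does not carry is reported as absent, never as zero.
    """
    if isinstance(fit, FitResult):
        comp = fit.components
        names = list(fit.param_names)
        cov = fit.info_matrix
    else:
        comp = fit
        names = [k for k, v in comp.as_dict().items()
                 if v != 0.0 or k in ("sigma2_a", "sigma2_e")]
        cov = None
    if include_cov_am is None:
        include_cov_am = comp.include_cov_am_in_p
    if comp.sigma2_p <= 0:
        raise ValueError("phenotypic variance must be positive")

    vec = np.array([comp.as_dict()[k] for k in names])
    point = _ratios_from_vector(vec, names, include_cov_am)

    ses = {}
    if cov is not None:
        keys = [k for k in ("h2", "m2", "c2", "r_am", "sigma2_p")
                if k in point]
        h = np.array([max(1e-6 * abs(v), 1e-10) for v in vec])
        grads = {k: np.zeros(len(vec)) for k in keys}
        for j in range(len(vec)):
            up, dn = vec.copy(), vec.copy()
            up[j] += h[j]
            dn[j] -= h[j]
            r_up = _ratios_from_vector(up, names, include_cov_am)
            r_dn = _ratios_from_vector(dn, names, include_cov_am)
            for k in keys:
                grads[k][j] = (r_up[k] - r_dn[k]) / (2 * h[j])
        for k in keys:
            var = float(grads[k] @ cov @ grads[k])
            ses[k] = math.sqrt(var) if var > 0 else float("nan")

    return GeneticParameters(
        h2=point["h2"], h2_se=ses.get("h2"),
        m2=point.get("m2"), m2_se=ses.get("m2"),
        c2=point.get("c2"), c2_se=ses.get("c2"),
        r_am=point.get("r_am"), r_am_se=ses.get("r_am"),
        h2_T=point["h2_T"],
        sigma2_p=point["sigma2_p"], sigma2_p_se=ses.get("sigma2_p"))


def lrt(fit_small: FitResult, fit_large: FitResult):
    """Likelihood-ratio test of nested variance-component models.

    Returns (statistic, df, p); the statistic is floored at zero since
    optimizer noise can leave the larger model fractionally below the
    smaller one.
    """
    if not fit_small.model.nested_in(fit_large.model):
        raise ValueError(
            f"model {fit_small.model.model_id} is not nested in "
            f"model {fit_large.model.model_id}")
    statistic = max(0.0, 2.0 * (fit_large.logL - fit_small.logL))
    df = fit_large.model.n_params - fit_small.model.n_params
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return statistic, df, p


def select_best_model(fits, alpha: float = 0.05) -> ModelComparison:
    """Pick the most parsimonious adequate model by nested LRTs.

    A model is *justified* when it beats every nested sub-model that was
    fitted, and *adequate* when no fitted super-model improves on it
    significantly.  Among models that are both, the winner is the one
    with the highest logL, ties resolved toward fewer parameters then
    the lower model number.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    usable = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            logger.warning("model %d excluded from selection (unconverged)",
                           f.model.model_id)
    if not usable:
        raise ValueError("no converged fits to select among")
    by_id = {f.model.model_id: f for f in usable}

    rows = [(f.model.model_id, f.model.n_params, f.logL, f.converged)
            for f in usable]
    table = pd.DataFrame(rows, columns=["model_id", "n_params", "logL",
                                        "converged"]).sort_values("model_id")

    pairs = []
    for s in usable:
        for l in usable:
            if s.model.nested_in(l.model):
                stat, df, p = lrt(s, l)
                pairs.append((s.model.model_id, l.model.model_id,
                              stat, df, p))
    lrt_table = pd.DataFrame(pairs, columns=["small", "large", "statistic",
                                             "df", "p"])

    def pval(s_id, l_id):
        row = lrt_table[(lrt_table["small"] == s_id)
                        & (lrt_table["large"] == l_id)]
        return float(row["p"].iloc[0])

    candidates = []
    for f in usable:
        mid = f.model.model_id
        subs = [g.model.model_id for g in usable if g.model.nested_in(f.model)]
        sups = [g.model.model_id for g in usable if f.model.nested_in(g.model)]
        justified = all(pval(s, mid) <= alpha for s in subs)
        adequate = all(pval(mid, l) > alpha for l in sups)
        if justified and adequate:
            candidates.append(f)
    if not candidates:
        # fall back to minimal adequate: not beaten by any super-model
        candidates = [f for f in usable
                      if all(pval(f.model.model_id, g.model.model_id) > alpha
                             for g in usable if f.model.nested_in(g.model))]
    if not candidates:
        candidates = usable

    best = sorted(candidates,
                  key=lambda f: (-f.logL, f.model.n_params,
                                 f.model.model_id))[0]
    return ModelComparison(table=table.reset_index(drop=True),
                           lrt_table=lrt_table,
                           best_model_id=best.model.model_id, alpha=alpha)


def correlation_significance(biv: BivariateResult,
                             refits: dict | None = None,
                             n_records: int | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Significance of the between-trait correlations from one pair.

    The additive (r_a) and maternal permanent environmental (r_c)
    correlations are tested by 1-df LRTs against the refit with the
    corresponding covariance pinned at zero; the residual and phenotypic
    correlations use the classical t = r sqrt((n-2)/(1-r^2)) test.
    """
    refits = refits or {}
    n = n_records if n_records is not None else biv.n_records
    rows = []

    for label, effect in (("r_a", "additive"), ("r_c", "pe")):
        if effect not in biv.blocks:
            continue
        B = biv.blocks[effect]
        if B[0, 0] <= 0 or B[1, 1] <= 0:
            continue
        r = biv.correlation(effect)
        refit = refits.get(label)
        if refit is None:
            rows.append((label, r, "lrt", float("nan"), float("nan"), False))
            continue
        stat = max(0.0, 2.0 * (biv.logL - refit.logL))
        p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
        rows.append((label, r, "lrt", stat, p, p <= alpha))

    for label, r in (("r_e", biv.correlation("residual")),
                     ("r_p", biv.r_p)):
        if abs(r) >= 1.0:
            logger.warning("%s = %.3f: t-test undefined at |r| = 1; "
                           "reported significant by convention", label, r)
            rows.append((label, r, "t", float("inf"), 0.0, True))
            continue
        if r == 0.0:
            rows.append((label, r, "t", 0.0, 1.0, False))
            continue
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append((label, r, "t", t, p, p <= alpha))

    return pd.DataFrame(rows, columns=["component", "estimate", "test",
                                       "statistic", "p", "significant"])
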