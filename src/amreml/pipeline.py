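"""End-to-end analysis pipeline: factor screening, model fitting and
selection, genetic parameters, correlations, trends, inbreeding.

The pipeline mirrors how a breeding-program dataset is analysed in
practice: least-squares screening decides the fixed effects per trait;
the six candidate animal models are fitted by REML and compared by LRT;
the best model supplies the genetic parameters and BLUP breeding values;
bivariate refits give correlations between traits; trends come from the
regression of mean breeding value (or phenotype) on generation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from amreml import __version__
from amreml.design import FixedEffectSpec, ls_means
from amreml.params import (correlation_significance, derive_parameters,
                           select_best_model)
from amreml.pedigree import inbreeding_coefficients, read_pedigree
from amreml.trends import genetic_trend, inbreeding_summary, phenotypic_trend
from amreml.varcomp import FitOptions, fit_bivariate, fit_univariate

logger = logging.getLogger(__name__)

PARAM_ROW_ORDER = ["sigma2_a", "sigma2_m", "sigma_am", "sigma2_c",
                   "sigma2_e", "sigma2_p", "h2", "m2", "r_am", "c2",
                   "h2_T", "logL"]


@dataclass
class TraitConfig:
    name: str
    factors: list = field(default_factory=list)
    models: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])


@dataclass
class RunConfig:
    pedigree: str
    phenotypes: str
    outdir: str
    traits: list = field(default_factory=list)      # list[TraitConfig]
    pairs: list = field(default_factory=list)       # [(trait_x, trait_y)]
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = [TraitConfig(**t) for t in raw.pop("traits", [])]
        pairs = [tuple(p) for p in raw.pop("pairs", [])]
        return cls(traits=traits, pairs=pairs, **raw)

    def validate(self):
        if not self.traits:
            raise ValueError("config lists no traits to analyse")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in config")


def _fit_to_dict(fit, params=None) -> dict:
    out = {
        "model": fit.model.model_id,
        "logL": fit.logL,
        "converged": fit.converged,
        "n_restarts": fit.n_restarts,
        "n_records": fit.n_records,
        "components": fit.components.as_dict(fit.param_names),
        "se": fit.se,
        "boundary": fit.boundary,
    }
    if params is not None:
        out["parameters"] = params.as_dict()
    return out


def _param_table_row(fit, params) -> dict:
    """One column of the per-trait parameter table, in the canonical
    row order (variances first, then ratios, then logL)."""
    comp = fit.components.as_dict()
    present = set(fit.param_names)
    row = {}
    for key in PARAM_ROW_ORDER:
        if key in ("sigma2_a", "sigma2_m", "sigma_am", "sigma2_c",
                   "sigma2_e"):
            row[key] = comp[key] if key in present else None
        elif key == "sigma2_p":
            row[key] = params.sigma2_p
        elif key == "logL":
            row[key] = fit.logL
        else:
            row[key] = getattr(params, key)
    return row


@dataclass
class AnalysisReport:
    config_hash: str
    seed: int
    version: str
    traits: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    inbreeding: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": {"config_hash": self.config_hash,
                           "seed": self.seed, "version": self.version},
            "traits": self.traits,
            "correlations": self.correlations,
            "inbreeding": self.inbreeding,
            "timings": self.timings,
        }


def run_pipeline(cfg: RunConfig,
                 options: FitOptions | None = None) -> AnalysisReport:
    """Execute every stage and persist intermediates under ``cfg.outdir``."""
    cfg.validate()
    options = options or FitOptions()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hashed = asdict(cfg)
    hashed.pop("outdir")  # output location must not change the analysis hash
    cfg_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str)
        .encode()).hexdigest()[:16]
    report = AnalysisReport(config_hash=cfg_hash, seed=cfg.seed,
                            version=__version__)

    ped = read_pedigree(cfg.pedigree)
    data = pd.read_csv(cfg.phenotypes)
    data["animal"] = data["animal"].astype(str)
    if "dam" in data.columns:
        data["dam"] = data["dam"].astype(str)

    best_fits = {}
    for tc in cfg.traits:
        t0 = time.perf_counter()
        stage = {"trait": tc.name}
        try:
            retained = list(tc.factors)
            if tc.factors:
                spec = FixedEffectSpec.from_data(data, tc.factors)
                lsm = ls_means(data, spec, tc.name, alpha=cfg.alpha)
                retained = lsm.retained_factors()
                stage["ls_means"] = lsm.means.to_dict("records")
                stage["factor_tests"] = lsm.tests.to_dict("records")
                stage["retained_factors"] = retained
            fixed = (FixedEffectSpec.from_data(data, retained)
                     if retained else None)
            fits = []
            for mid in tc.models:
                logger.info("trait %s: fitting model %d", tc.name, mid)
                fits.append(fit_univariate(ped, data, tc.name, mid,
                                           fixed=fixed, options=options))
            comparison = select_best_model(fits, alpha=cfg.alpha)
            best = next(f for f in fits
                        if f.model.model_id == comparison.best_model_id)
            params = derive_parameters(best)
            best_fits[tc.name] = (best, fixed)

            stage["model_comparison"] = comparison.table.to_dict("records")
            stage["lrt"] = comparison.lrt_table.to_dict("records")
            stage["best_model"] = comparison.best_model_id
            stage["fits"] = {f.model.model_id: _fit_to_dict(f) for f in fits}
            stage["parameters"] = _param_table_row(best, params)
            stage["parameter_se"] = {
                "h2": params.h2_se, "m2": params.m2_se, "c2": params.c2_se,
                "r_am": params.r_am_se, "sigma2_p": params.sigma2_p_se}

            bv = best.bv
            bv.to_csv(outdir / f"bv_{tc.name}.csv", index=False)
            recorded = sorted(data.loc[data[tc.name].notna(),
                                       "generation"].unique())
            gt = genetic_trend(bv, include_generations=recorded)
            pt = phenotypic_trend(data, tc.name)
            stage["genetic_trend"] = {
                "slope": gt.slope, "se": gt.slope_se, "p": gt.p,
                "r2": gt.r2,
                "generation_means": gt.table.to_dict("records")}
            stage["phenotypic_trend"] = {
                "slope": pt.slope, "se": pt.slope_se, "p": pt.p,
                "r2": pt.r2,
                "generation_means": pt.table.to_dict("records")}
        except Exception as exc:
            with open(outdir / "partial_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, default=str)
            raise RuntimeError(
                f"pipeline stage failed for trait {tc.name!r}: {exc}"
            ) from exc
        report.traits[tc.name] = stage
        report.timings[tc.name] = round(time.perf_counter() - t0, 2)

    for tx, ty in cfg.pairs:
        t0 = time.perf_counter()
        fx, fy = best_fits[tx], best_fits[ty]
        biv = fit_bivariate(ped, data, tx, ty, fx[0].model, fy[0].model,
                            fixed_x=fx[1], fixed_y=fy[1],
                            start=(fx[0], fy[0]), options=options)
        refits = {}
        for label, effect in (("r_a", "additive"), ("r_c", "pe")):
            if effect == "pe" and "pe" not in biv.blocks:
                continue
            pin = {"r_a": 0.0} if label == "r_a" else {"r_pe": 0.0}
            if any(n in biv.param_names for n in pin):
                refits[label] = fit_bivariate(
                    ped, data, tx, ty, fx[0].model, fy[0].model,
                    fixed_x=fx[1], fixed_y=fy[1], start=(fx[0], fy[0]),
                    constraints=pin, options=options)
        table = correlation_significance(biv, refits=refits,
                                         alpha=cfg.alpha)
        report.correlations.append({
            "pair": [tx, ty], "logL": biv.logL,
            "n_records": biv.n_records,
            "estimates": table.to_dict("records")})
        report.timings[f"{tx}:{ty}"] = round(time.perf_counter() - t0, 2)

    F = inbreeding_coefficients(ped)
    mean_all, mean_inbred, n_inbred = inbreeding_summary(F)
    report.inbreeding = {"mean_F": mean_all,
                         "mean_F_inbred": mean_inbred,
                         "n_inbred": n_inbred, "n_animals": ped.n}

    write_report(report, outdir)
    return report


def _fmt(x, dp=3):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.{dp}f}"
    return str(x)


def report_markdown(report: AnalysisReport) -> str:
    """Human-readable twin of the JSON report."""
    lines = ["# Analysis report", "",
             f"seed: {report.seed}  config: {report.config_hash}  "
             f"version: {report.version}", ""]
    for trait, stage in report.traits.items():
        lines.append(f"## {trait}")
        lines.append("")
        lines.append(f"Best model: {stage['best_model']}")
        lines.append("")
        lines.append("| quantity | estimate |")
        lines.append("|---|---|")
        for key in PARAM_ROW_ORDER:
            val = stage["parameters"].get(key)
            lines.append(f"| {key} | {_fmt(val)} |")
        gt = stage["genetic_trend"]
        lines.append("")
        lines.append(f"Genetic trend: {_fmt(gt['slope'])} ± "
                     f"{_fmt(gt['se'])} per generation "
                     f"(p = {_fmt(gt['p'])})")
        pt = stage["phenotypic_trend"]
        lines.append(f"Phenotypic trend: {_fmt(pt['slope'])} ± "
                     f"{_fmt(pt['se'])} per generation "
                     f"(p = {_fmt(pt['p'])})")
        lines.append("")
    if report.correlations:
        lines.append("## Correlations")
        lines.append("")
        lines.append("| pair | component | estimate | p | significant |")
        lines.append("|---|---|---|---|---|")
        for block in report.correlations:
            pair = " / ".join(block["pair"])
            for row in block["estimates"]:
                lines.append(
                    f"| {pair} | {row['component']} | "
                    f"{_fmt(row['estimate'])} | {_fmt(row['p'])} | "
                    f"{row['significant']} |")
        lines.append("")
    ib = report.inbreeding
    lines.append("## Inbreeding")
    lines.append("")
    lines.append(f"mean F = {_fmt(ib['mean_F'], 4)}; "
                 f"mean F among inbred = {_fmt(ib['mean_F_inbred'], 4)}; "
                 f"inbred animals = {ib['n_inbred']} / {ib['n_animals']}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: AnalysisReport, outdir) -> None:
    """JSON (full precision) and markdown (rounded) forms of the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)
    with open(outdir / "report.md", "w") as fh:
        fh.write(report_markdown(report))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return str(obj)
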