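"""REML estimation for pedigree animal models and BLUP breeding values.

Six nested random-effect structures are supported, all of the form

    y = X b + Z_a a + Z_m m + Z_pe pe + e

with V(a) = A sigma2_a, V(m) = A sigma2_m, Cov(a, m) = A sigma_am,
V(pe) = I sigma2_c and V(e) = I sigma2_e:

    model 1: a
    model 2: a + m            (cov(a,m) = 0)
    model 3: a + m            (cov(a,m) = A sigma_am)
    model 4: a + pe
    model 5: a + m + pe       (cov(a,m) = 0)
    model 6: a + m + pe       (cov(a,m) = A sigma_am)

The restricted likelihood is evaluated through the sparse mixed-model
equations (never through the dense phenotypic covariance), and maximised
by a derivative-free simplex search on transformed parameters
(log variances, atanh of the direct-maternal correlation), declared
converged when the variance of the -2 logL values across the simplex
falls below 1e-8, with automatic restarts from the incumbent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from amreml.design import FixedEffectSpec, build_design
from amreml.pedigree import Pedigree, a_inverse, inbreeding_coefficients, log_det_a

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)
PENALTY = 1e30


class ModelError(ValueError):
    pass


class NonIdentifiableError(ModelError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects (beyond the residual) the model carries."""

    model_id: int
    maternal: bool = False
    pe: bool = False
    cov_am: bool = False

    @property
    def param_names(self):
        names = ["sigma2_a"]
        if self.maternal:
            names.append("sigma2_m")
        if self.cov_am:
            names.append("sigma_am")
        if self.pe:
            names.append("sigma2_c")
        names.append("sigma2_e")
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def nested_in(self, other: "ModelSpec") -> bool:
        """True when this model's random structure is a special case of other's."""
        if self.model_id == other.model_id:
            return False
        return (set(self.param_names) < set(other.param_names))


MODEL_SPECS = {
    1: ModelSpec(1),
    2: ModelSpec(2, maternal=True),
    3: ModelSpec(3, maternal=True, cov_am=True),
    4: ModelSpec(4, pe=True),
    5: ModelSpec(5, maternal=True, pe=True),
    6: ModelSpec(6, maternal=True, pe=True, cov_am=True),
}


@dataclass
class VarianceComponents:
    sigma2_a: float = 0.0
    sigma2_m: float = 0.0
    sigma_am: float = 0.0
    sigma2_c: float = 0.0
    sigma2_e: float = 0.0
    include_cov_am_in_p: bool = True

    @property
    def sigma2_p(self) -> float:
        total = self.sigma2_a + self.sigma2_m + self.sigma2_c + self.sigma2_e
        if self.include_cov_am_in_p:
            total += self.sigma_am
        return total

    @property
    def r_am(self) -> float:
        denom = math.sqrt(self.sigma2_a * self.sigma2_m)
        return self.sigma_am / denom if denom > 0 else 0.0

    def as_dict(self, names=None):
        d = {"sigma2_a": self.sigma2_a, "sigma2_m": self.sigma2_m,
             "sigma_am": self.sigma_am, "sigma2_c": self.sigma2_c,
             "sigma2_e": self.sigma2_e}
        if names is not None:
            d = {k: d[k] for k in names}
        return d


@dataclass
class FitOptions:
    simplex_var_tol: float = 1e-8
    restart_logl_tol: float = 1e-6
    max_restarts: int = 10
    max_iter: int = 4000
    initial_step: float = 0.4
    drop_unknown_dam: bool = True
    compute_se: bool = True
    boundary_ratio: float = 1e-6
    include_cov_am_in_p: bool = True


@dataclass
class FitResult:
    model: ModelSpec
    components: VarianceComponents
    logL: float
    converged: bool
    n_restarts: int
    bv: pd.DataFrame | None = None
    info_matrix: np.ndarray | None = None  # covariance of parameter estimates
    se: dict = field(default_factory=dict)
    param_names: list = field(default_factory=list)
    boundary: list = field(default_factory=list)
    n_records: int = 0
    trait: str | None = None


# ---------------------------------------------------------------------------
# workspace: everything that does not change with theta
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed sparse pieces of the mixed-model equations for one trait."""

    def __init__(self, ped: Pedigree, data: pd.DataFrame, trait: str,
                 model: ModelSpec, fixed: FixedEffectSpec | None,
                 options: FitOptions):
        self.ped = ped
        self.model = model
        self.options = options
        self.trait = trait

        df = data.loc[data[trait].notna()].copy()
        if df.empty:
            raise ModelError(f"no records with non-missing {trait!r}")
        missing = set(df["animal"].astype(str)) - set(ped.id_index)
        if missing:
            raise ModelError(
                f"records for animals absent from the pedigree: "
                f"{sorted(missing)[:5]}")
        df["_ai"] = df["animal"].astype(str).map(ped.id_index)

        if "dam" in df.columns:
            dam_tok = df["dam"].astype(str)
            df["_di"] = dam_tok.map(lambda t: ped.id_index.get(t, -1))
        else:
            df["_di"] = ped.dam[df["_ai"].to_numpy()]

        if model.maternal or model.pe:
            unknown = df["_di"] < 0
            if unknown.any():
                if not options.drop_unknown_dam:
                    raise ModelError(
                        f"{int(unknown.sum())} records have unknown dams "
                        "under a maternal model")
                logger.warning("dropping %d records with unknown dams "
                               "under a maternal model", int(unknown.sum()))
                df = df.loc[~unknown]

        self.data = df
        y = df[trait].to_numpy(dtype=float)
        n = len(y)

        if fixed is None or not fixed.factors:
            X = np.ones((n, 1))
            self.design = None
        else:
            design = build_design(df.reset_index(drop=True), fixed, trait=trait)
            X = design.X
            self.design = design
        self.p = X.shape[1]
        self.n = n
        self.n_anim = ped.n

        ai = df["_ai"].to_numpy()
        di = df["_di"].to_numpy()
        rows = np.arange(n)
        Za = sparse.csr_matrix((np.ones(n), (rows, ai)), shape=(n, ped.n))
        blocks = [sparse.csr_matrix(X), Za]
        layout = [("beta", self.p), ("a", ped.n)]
        if model.maternal:
            Zm = sparse.csr_matrix((np.ones(n), (rows, di)), shape=(n, ped.n))
            blocks.append(Zm)
            layout.append(("m", ped.n))
        if model.pe:
            pe_dams = np.unique(di)
            pe_pos = {d: j for j, d in enumerate(pe_dams)}
            cols = np.array([pe_pos[d] for d in di])
            Zpe = sparse.csr_matrix((np.ones(n), (rows, cols)),
                                    shape=(n, len(pe_dams)))
            blocks.append(Zpe)
            layout.append(("pe", len(pe_dams)))
            self.pe_dam_ids = [ped.ids[d] for d in pe_dams]
            counts = np.bincount(cols)
            if counts.max() < 2:
                raise NonIdentifiableError(
                    "no dam has more than one recorded progeny; the "
                    "maternal permanent environmental variance is not "
                    "identifiable")
        self.layout = layout
        self.offsets = {}
        off = 0
        for name, size in layout:
            self.offsets[name] = (off, off + size)
            off += size
        self.dim = off

        M = sparse.hstack(blocks, format="csc")
        self.MtM = (M.T @ M).tocsc()
        self.Mty = M.T @ y
        self.yty = float(y @ y)

        F = inbreeding_coefficients(ped)
        self.Ainv = a_inverse(ped, F).tocoo()
        self.logdetA = log_det_a(ped, F)
        self.var_y = float(np.var(y, ddof=1))

        if (ped.sire < 0).all() and (ped.dam < 0).all():
            if np.bincount(ai, minlength=ped.n).max() < 2:
                raise NonIdentifiableError(
                    "all animals are unrelated founders with single "
                    "records; sigma2_a and sigma2_e are not separable")

    # -- assembly -----------------------------------------------------------

    def _g_inverse(self, theta: VarianceComponents):
        """Sparse G inverse over the random-effect columns plus log|G|."""
        m = self.model
        pieces = []
        logdetG = 0.0
        n_anim = self.n_anim
        if m.maternal and m.cov_am:
            G0 = np.array([[theta.sigma2_a, theta.sigma_am],
                           [theta.sigma_am, theta.sigma2_m]])
            det0 = np.linalg.det(G0)
            if det0 <= 0 or theta.sigma2_a <= 0:
                return None, None
            G0inv = np.linalg.inv(G0)
            pieces.append(sparse.kron(G0inv, self.Ainv, format="csc"))
            logdetG += n_anim * math.log(det0) + 2.0 * self.logdetA
        else:
            if theta.sigma2_a <= 0:
                return None, None
            pieces.append(self.Ainv.tocsc() / theta.sigma2_a)
            logdetG += n_anim * math.log(theta.sigma2_a) + self.logdetA
            if m.maternal:
                if theta.sigma2_m <= 0:
                    return None, None
                pieces.append(self.Ainv.tocsc() / theta.sigma2_m)
                logdetG += n_anim * math.log(theta.sigma2_m) + self.logdetA
        if m.pe:
            if theta.sigma2_c <= 0:
                return None, None
            n_pe = self.offsets["pe"][1] - self.offsets["pe"][0]
            pieces.append(sparse.identity(n_pe, format="csc")
                          / theta.sigma2_c)
            logdetG += n_pe * math.log(theta.sigma2_c)
        Ginv = sparse.block_diag(pieces, format="csc")
        return Ginv, logdetG

    def coefficient_matrix(self, theta: VarianceComponents):
        """Full-MME coefficient matrix (with R^-1 and G^-1) and log|G|."""
        Ginv, logdetG = self._g_inverse(theta)
        if Ginv is None:
            return None, None
        pad = sparse.block_diag(
            [sparse.csc_matrix((self.p, self.p)), Ginv], format="csc")
        C = self.MtM / theta.sigma2_e + pad
        return C, logdetG

    def solve(self, theta: VarianceComponents):
        """Factorize the MME; returns (solution, logdetC, logdetG, yPy)."""
        C, logdetG = self.coefficient_matrix(theta)
        if C is None or theta.sigma2_e <= 0:
            return None
        rhs = self.Mty / theta.sigma2_e
        try:
            lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                      options={"SymmetricMode": True})
        except RuntimeError:
            return None
        diag = lu.U.diagonal()
        if np.any(diag == 0) or not np.all(np.isfinite(diag)):
            return None
        logdetC = float(np.sum(np.log(np.abs(diag))))
        sol = lu.solve(rhs)
        yPy = self.yty / theta.sigma2_e - float(sol @ rhs)
        return sol, logdetC, logdetG, yPy

    def minus2_logl(self, theta: VarianceComponents) -> float:
        out = self.solve(theta)
        if out is None:
            return PENALTY
        _, logdetC, logdetG, yPy = out
        m2 = ((self.n - self.p) * LOG2PI
              + self.n * math.log(theta.sigma2_e)
              + logdetG + logdetC + yPy)
        if not math.isfinite(m2):
            return PENALTY
        return m2

    # -- parameter transforms ----------------------------------------------

    def pack(self, theta: VarianceComponents) -> np.ndarray:
        m = self.model
        x = [math.log(theta.sigma2_a)]
        if m.maternal:
            x.append(math.log(theta.sigma2_m))
        if m.cov_am:
            r = theta.r_am
            x.append(math.atanh(np.clip(r, -0.999999, 0.999999)))
        if m.pe:
            x.append(math.log(theta.sigma2_c))
        x.append(math.log(theta.sigma2_e))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> VarianceComponents:
        m = self.model
        x = np.clip(x, -40.0, 40.0)
        i = 0
        s2a = math.exp(x[i]); i += 1
        s2m = sam = s2c = 0.0
        if m.maternal:
            s2m = math.exp(x[i]); i += 1
        if m.cov_am:
            sam = math.tanh(x[i]) * math.sqrt(s2a * s2m); i += 1
        if m.pe:
            s2c = math.exp(x[i]); i += 1
        s2e = math.exp(x[i])
        return VarianceComponents(
            sigma2_a=s2a, sigma2_m=s2m, sigma_am=sam,
            sigma2_c=s2c, sigma2_e=s2e,
            include_cov_am_in_p=self.options.include_cov_am_in_p)

    def theta_from_dict(self, d: dict) -> VarianceComponents:
        return VarianceComponents(
            sigma2_a=d.get("sigma2_a", 0.0),
            sigma2_m=d.get("sigma2_m", 0.0),
            sigma_am=d.get("sigma_am", 0.0),
            sigma2_c=d.get("sigma2_c", 0.0),
            sigma2_e=d.get("sigma2_e", 0.0),
            include_cov_am_in_p=self.options.include_cov_am_in_p)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def assemble_mme(ped: Pedigree, data: pd.DataFrame, model: ModelSpec,
                 theta: VarianceComponents, trait: str,
                 fixed: FixedEffectSpec | None = None,
                 options: FitOptions | None = None):
    """Henderson mixed-model equations in residual-variance-scaled form.

    Returns ``(C, rhs, layout)`` with C = M'M + sigma2_e * G^-1 padded over
    the fixed columns, rhs = M'y; the solution equals the BLUE/BLUP vector.
    """
    ws = _Workspace(ped, data, trait, model, fixed, options or FitOptions())
    Ginv, _ = ws._g_inverse(theta)
    if Ginv is None:
        raise ModelError("variance parameters outside the feasible region")
    pad = sparse.block_diag(
        [sparse.csc_matrix((ws.p, ws.p)), Ginv * theta.sigma2_e],
        format="csc")
    C = ws.MtM + pad
    return C, ws.Mty.copy(), list(ws.layout)


def restricted_loglik(ped: Pedigree, data: pd.DataFrame, model: ModelSpec,
                      theta: VarianceComponents, trait: str,
                      fixed: FixedEffectSpec | None = None,
                      options: FitOptions | None = None) -> float:
    """Restricted log-likelihood, evaluated through the sparse MME."""
    ws = _Workspace(ped, data, trait, model, fixed, options or FitOptions())
    m2 = ws.minus2_logl(theta)
    if m2 >= PENALTY:
        raise ModelError("variance parameters outside the feasible region")
    return -0.5 * m2


def _nelder_mead(f, x0, step, var_tol, max_iter):
    """Simplex minimiser converged when var(f-values) < var_tol."""
    n = len(x0)
    simplex = [np.asarray(x0, dtype=float)]
    for i in range(n):
        x = simplex[0].copy()
        x[i] += step
        simplex.append(x)
    fvals = np.array([f(x) for x in simplex])
    n_eval = n + 1
    alpha, gamma, rho, sig = 1.0, 2.0, 0.5, 0.5
    for _ in range(max_iter):
        order = np.argsort(fvals)
        simplex = [simplex[k] for k in order]
        fvals = fvals[order]
        if np.var(fvals) < var_tol:
            return simplex[0], fvals[0], True, n_eval
        centroid = np.mean(simplex[:-1], axis=0)
        xr = centroid + alpha * (centroid - simplex[-1])
        fr = f(xr); n_eval += 1
        if fr < fvals[0]:
            xe = centroid + gamma * (xr - centroid)
            fe = f(xe); n_eval += 1
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            xc = centroid + rho * (simplex[-1] - centroid)
            fc = f(xc); n_eval += 1
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = xc, fc
            else:
                for k in range(1, n + 1):
                    simplex[k] = simplex[0] + sig * (simplex[k] - simplex[0])
                    fvals[k] = f(simplex[k])
                n_eval += n
    order = np.argsort(fvals)
    return simplex[order[0]], fvals[order[0]], False, n_eval


def _default_start(ws: _Workspace) -> VarianceComponents:
    """Equal partition of the phenotypic variance over fitted components."""
    m = ws.model
    n_var = 2 + int(m.maternal) + int(m.pe)
    share = max(ws.var_y / n_var, 0.05 * ws.var_y)
    return VarianceComponents(
        sigma2_a=share,
        sigma2_m=share if m.maternal else 0.0,
        sigma_am=0.0,
        sigma2_c=share if m.pe else 0.0,
        sigma2_e=max(ws.var_y - (n_var - 1) * share, 0.05 * ws.var_y),
        include_cov_am_in_p=ws.options.include_cov_am_in_p)


def _observed_information(ws: _Workspace, theta: VarianceComponents):
    """Parameter covariance from a numerically differenced observed
    information matrix at the optimum, on the untransformed scale."""
    names = ws.model.param_names
    th0 = np.array([theta.as_dict()[k] for k in names])
    scale = max(ws.var_y, 1e-8)

    def f(vec):
        d = dict(zip(names, vec))
        t = ws.theta_from_dict({**theta.as_dict(), **d})
        return ws.minus2_logl(t)

    q = len(names)
    # steps must be large enough that second differences of -2logL rise
    # well above sparse-factorization roundoff
    h = np.array([max(0.05 * abs(v), 1e-3 * scale) for v in th0])
    f0 = f(th0)
    H = np.zeros((q, q))
    for k in range(q):
        ek = np.zeros(q); ek[k] = h[k]
        fp, fm = f(th0 + ek), f(th0 - ek)
        if max(fp, fm) >= PENALTY:
            return None
        H[k, k] = (fp + fm - 2 * f0) / h[k] ** 2
    for k in range(q):
        for l in range(k + 1, q):
            ek = np.zeros(q); ek[k] = h[k]
            el = np.zeros(q); el[l] = h[l]
            fpp, fpm = f(th0 + ek + el), f(th0 + ek - el)
            fmp, fmm = f(th0 - ek + el), f(th0 - ek - el)
            if max(fpp, fpm, fmp, fmm) >= PENALTY:
                return None
            H[k, l] = H[l, k] = (fpp - fpm - fmp + fmm) / (4 * h[k] * h[l])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def _extract_blup(ws: _Workspace, theta: VarianceComponents) -> pd.DataFrame:
    out = ws.solve(theta)
    if out is None:
        raise ModelError("MME not solvable at the converged parameters")
    sol = out[0]
    a0, a1 = ws.offsets["a"]
    table = pd.DataFrame({
        "animal": ws.ped.ids,
        "generation": ws.ped.generation,
        "bv_direct": sol[a0:a1],
    })
    if ws.model.maternal:
        m0, m1 = ws.offsets["m"]
        table["bv_maternal"] = sol[m0:m1]
    return table


def fit_univariate(ped: Pedigree, data: pd.DataFrame, trait: str,
                   model: ModelSpec | int,
                   fixed: FixedEffectSpec | None = None,
                   options: FitOptions | None = None,
                   start: VarianceComponents | None = None) -> FitResult:
    """Maximise the restricted likelihood for one trait under one model.

    The search runs on transformed parameters (log variances, atanh
    direct-maternal correlation); each simplex pass is declared converged
    when the variance of -2 logL over the vertices is below the tolerance,
    and the search restarts from the incumbent until the likelihood stops
    improving.
    """
    if isinstance(model, int):
        model = MODEL_SPECS[model]
    options = options or FitOptions()
    ws = _Workspace(ped, data, trait, model, fixed, options)

    theta0 = start if start is not None else _default_start(ws)
    x = ws.pack(theta0)

    def objective(xv):
        return ws.minus2_logl(ws.unpack(xv))

    best_f = objective(x)
    if best_f >= PENALTY:
        raise ModelError("starting values outside the feasible region")
    n_restarts = 0
    converged = False
    step = options.initial_step
    for r in range(options.max_restarts):
        x_new, f_new, conv, _ = _nelder_mead(
            objective, x, step=step, var_tol=options.simplex_var_tol,
            max_iter=options.max_iter)
        improvement = 0.5 * (best_f - f_new)  # in logL units
        if f_new < best_f:
            x, best_f = x_new, f_new
        n_restarts = r
        converged = conv
        if conv and improvement < options.restart_logl_tol and r > 0:
            break
        step = max(step * 0.5, 0.05)

    theta = ws.unpack(x)
    logL = -0.5 * best_f

    boundary = []
    s2p = theta.sigma2_p
    for name, val in theta.as_dict(model.param_names).items():
        if name.startswith("sigma2") and name != "sigma2_e":
            if val < options.boundary_ratio * s2p:
                boundary.append(name)

    cov = None
    se = {}
    if options.compute_se:
        if boundary:
            logger.warning("variance(s) %s at the boundary; standard errors "
                           "not available", boundary)
        else:
            cov = _observed_information(ws, theta)
            if cov is not None:
                d = np.diag(cov)
                se = {nm: (math.sqrt(v) if v > 0 else float("nan"))
                      for nm, v in zip(model.param_names, d)}

    bv = _extract_blup(ws, theta)
    return FitResult(model=model, components=theta, logL=logL,
                     converged=converged, n_restarts=n_restarts, bv=bv,
                     info_matrix=cov, se=se,
                     param_names=list(model.param_names),
                     boundary=boundary, n_records=ws.n, trait=trait)


def blup_breeding_values(fit: FitResult) -> pd.DataFrame:
    """Per-animal BLUP solutions from a converged fit (parents without
    records receive values through the pedigree links)."""
    if not fit.converged:
        raise ModelError("breeding values requested from an unconverged fit")
    return fit.bv.copy()


def standard_errors(fit: FitResult) -> pd.DataFrame:
    """Per-parameter standard errors from the fit's information matrix."""
    rows = []
    for name in fit.param_names:
        val = fit.components.as_dict()[name]
        s = fit.se.get(name, float("nan"))
        rows.append((name, val, s, name in fit.boundary))
    return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                       "boundary"])


# ---------------------------------------------------------------------------
# bivariate analysis
# ---------------------------------------------------------------------------

@dataclass
class BivariateResult:
    traits: tuple
    models: tuple
    blocks: dict            # effect -> 2x2 covariance matrix (np.ndarray)
    logL: float
    converged: bool
    n_records: int
    constraints: dict = field(default_factory=dict)
    param_cov: np.ndarray | None = None
    param_names: list = field(default_factory=list)

    def correlation(self, effect: str) -> float:
        B = self.blocks.get(effect)
        if B is None or B[0, 0] <= 0 or B[1, 1] <= 0:
            return float("nan")
        return float(B[0, 1] / math.sqrt(B[0, 0] * B[1, 1]))

    @property
    def phenotypic_block(self) -> np.ndarray:
        P = np.zeros((2, 2))
        for B in self.blocks.values():
            P += B
        return P

    @property
    def r_p(self) -> float:
        P = self.phenotypic_block
        return float(P[0, 1] / math.sqrt(P[0, 0] * P[1, 1]))


class _BivariateWorkspace:
    """Two traits on a common set of recorded animals (equal design).

    Effects carried by both traits get a full 2x2 covariance block; an
    effect carried by only one trait keeps its single variance.  The
    residual block is always 2x2.
    """

    def __init__(self, ped, data, trait_x, trait_y, model_x, model_y,
                 fixed_x, fixed_y, options):
        self.ped = ped
        self.options = options
        mx = MODEL_SPECS[model_x] if isinstance(model_x, int) else model_x
        my = MODEL_SPECS[model_y] if isinstance(model_y, int) else model_y
        self.models = (mx, my)
        self.traits = (trait_x, trait_y)

        df = data.loc[data[trait_x].notna() & data[trait_y].notna()].copy()
        df["_ai"] = df["animal"].astype(str).map(ped.id_index)
        if df["_ai"].isna().any():
            raise ModelError("bivariate records for animals not in pedigree")
        df["_ai"] = df["_ai"].astype(int)
        if "dam" in df.columns:
            df["_di"] = df["dam"].astype(str).map(
                lambda t: ped.id_index.get(t, -1))
        else:
            df["_di"] = ped.dam[df["_ai"].to_numpy()]
        needs_dam = mx.maternal or my.maternal or mx.pe or my.pe
        if needs_dam:
            bad = df["_di"] < 0
            if bad.any():
                logger.warning("dropping %d bivariate records with unknown "
                               "dams", int(bad.sum()))
                df = df.loc[~bad]
        self.data = df
        self.n = len(df)

        # per-trait design pieces M_t = [X_t Z-blocks], identical row space
        self.effects = ["a"]
        if mx.maternal or my.maternal:
            self.effects.append("m")
        if mx.pe or my.pe:
            self.effects.append("pe")
        self.carried = {
            "a": (True, True),
            "m": (mx.maternal, my.maternal),
            "pe": (mx.pe, my.pe),
        }

        ai = df["_ai"].to_numpy()
        di = df["_di"].to_numpy()
        rows = np.arange(self.n)
        Za = sparse.csr_matrix((np.ones(self.n), (rows, ai)),
                               shape=(self.n, ped.n))
        Zm = sparse.csr_matrix((np.ones(self.n), (rows, np.maximum(di, 0))),
                               shape=(self.n, ped.n)) if "m" in self.effects else None
        if "pe" in self.effects:
            pe_dams = np.unique(di)
            pe_pos = {d: j for j, d in enumerate(pe_dams)}
            cols = np.array([pe_pos[d] for d in di])
            Zpe = sparse.csr_matrix((np.ones(self.n), (rows, cols)),
                                    shape=(self.n, len(pe_dams)))
            self.n_pe = len(pe_dams)
        else:
            Zpe = None
            self.n_pe = 0

        # column layout of the stacked system: beta1, beta2, then per
        # effect the trait-1 and trait-2 columns adjacent, so each 2x2
        # covariance block maps to one contiguous kron-structured slice
        # of G inverse.
        X1 = (np.ones((self.n, 1)) if (fixed_x is None or not fixed_x.factors)
              else build_design(df.reset_index(drop=True), fixed_x).X)
        X2 = (np.ones((self.n, 1)) if (fixed_y is None or not fixed_y.factors)
              else build_design(df.reset_index(drop=True), fixed_y).X)
        self.p = X1.shape[1] + X2.shape[1]

        Zs = {"a": Za, "m": Zm, "pe": Zpe}
        cols1 = [sparse.csr_matrix(X1)]
        cols2 = [sparse.csr_matrix(X2)]
        self.layout = [("beta1", X1.shape[1]), ("beta2", X2.shape[1])]
        zero = {e: sparse.csr_matrix((self.n, Zs[e].shape[1]))
                for e in self.effects}
        for e in self.effects:
            cx, cy = self.carried[e]
            if cx:
                cols1.append(Zs[e]); cols2.append(zero[e])
                self.layout.append((f"{e}1", Zs[e].shape[1]))
            if cy:
                cols1.append(zero[e]); cols2.append(Zs[e])
                self.layout.append((f"{e}2", Zs[e].shape[1]))
        # insert beta2 zeros into trait-1 rows and vice versa
        M1 = sparse.hstack(
            [cols1[0], sparse.csr_matrix((self.n, X2.shape[1]))] + cols1[1:],
            format="csr")
        M2 = sparse.hstack(
            [sparse.csr_matrix((self.n, X1.shape[1])), cols2[0]] + cols2[1:],
            format="csr")
        self.dim = M1.shape[1]

        y1 = df[trait_x].to_numpy(dtype=float)
        y2 = df[trait_y].to_numpy(dtype=float)
        self.P11 = (M1.T @ M1).tocsc()
        self.P12 = (M1.T @ M2).tocsc()
        self.P22 = (M2.T @ M2).tocsc()
        self.M1ty1 = M1.T @ y1
        self.M1ty2 = M1.T @ y2
        self.M2ty1 = M2.T @ y1
        self.M2ty2 = M2.T @ y2
        self.yy = np.array([[y1 @ y1, y1 @ y2], [y1 @ y2, y2 @ y2]])
        self.vars = (float(np.var(y1, ddof=1)), float(np.var(y2, ddof=1)))

        F = inbreeding_coefficients(ped)
        self.Ainv = a_inverse(ped, F).tocsc()
        self.logdetA = log_det_a(ped, F)

        # free parameters: per effect and residual
        self.param_names = []
        for e in self.effects + ["e"]:
            cx, cy = self.carried.get(e, (True, True))
            if cx:
                self.param_names.append(f"v_{e}1")
            if cy:
                self.param_names.append(f"v_{e}2")
            if cx and cy:
                self.param_names.append(f"r_{e}")

    def unpack(self, x, constraints):
        x = np.clip(x, -40, 40)
        vals = {}
        i = 0
        for name in self.param_names:
            if name in constraints:
                vals[name] = constraints[name]
            else:
                v = x[i]; i += 1
                vals[name] = math.tanh(v) if name.startswith("r_") else math.exp(v)
        return vals

    def pack(self, vals, constraints):
        out = []
        for name in self.param_names:
            if name in constraints:
                continue
            v = vals[name]
            if name.startswith("r_"):
                out.append(math.atanh(np.clip(v, -0.999999, 0.999999)))
            else:
                out.append(math.log(max(v, 1e-12)))
        return np.array(out)

    def blocks_from(self, vals):
        blocks = {}
        for e in self.effects + ["e"]:
            cx, cy = self.carried.get(e, (True, True))
            B = np.zeros((2, 2))
            if cx:
                B[0, 0] = vals[f"v_{e}1"]
            if cy:
                B[1, 1] = vals[f"v_{e}2"]
            if cx and cy:
                B[0, 1] = B[1, 0] = (vals[f"r_{e}"]
                                     * math.sqrt(B[0, 0] * B[1, 1]))
            blocks[e] = B
        return blocks

    def minus2_logl(self, vals):
        blocks = self.blocks_from(vals)
        R0 = blocks["e"]
        detR = np.linalg.det(R0)
        if detR <= 0:
            return PENALTY
        R0inv = np.linalg.inv(R0)
        r11, r12, r22 = R0inv[0, 0], R0inv[0, 1], R0inv[1, 1]
        rhs = (r11 * self.M1ty1 + r12 * (self.M1ty2 + self.M2ty1)
               + r22 * self.M2ty2)

        # G inverse as a block-diagonal pad aligned with the column layout
        pieces = [sparse.csc_matrix((self.p, self.p))]
        logdetG = 0.0
        for e in self.effects:
            cx, cy = self.carried[e]
            B = blocks[e]
            size = self.ped.n if e in ("a", "m") else self.n_pe
            base = (self.Ainv if e in ("a", "m")
                    else sparse.identity(size, format="csc"))
            if cx and cy:
                det0 = np.linalg.det(B)
                if det0 <= 0:
                    return PENALTY
                pieces.append(sparse.kron(np.linalg.inv(B), base,
                                          format="csc"))
                logdetG += size * math.log(det0)
                if e in ("a", "m"):
                    logdetG += 2 * self.logdetA
            else:
                v = B[0, 0] if cx else B[1, 1]
                if v <= 0:
                    return PENALTY
                pieces.append(base / v)
                logdetG += size * math.log(v)
                if e in ("a", "m"):
                    logdetG += self.logdetA

        C = (r11 * self.P11 + r12 * (self.P12 + self.P12.T)
             + r22 * self.P22
             + sparse.block_diag(pieces, format="csc")).tocsc()
        try:
            lu = splu(C, permc_spec="MMD_AT_PLUS_A",
                      options={"SymmetricMode": True})
        except RuntimeError:
            return PENALTY
        diag = lu.U.diagonal()
        if np.any(diag == 0) or not np.all(np.isfinite(diag)):
            return PENALTY
        logdetC = float(np.sum(np.log(np.abs(diag))))
        sol = lu.solve(rhs)
        yRy = (r11 * self.yy[0, 0] + 2 * r12 * self.yy[0, 1]
               + r22 * self.yy[1, 1])
        yPy = yRy - float(sol @ rhs)
        m2 = ((2 * self.n - self.p) * LOG2PI + self.n * math.log(detR)
              + logdetG + logdetC + yPy)
        return m2 if math.isfinite(m2) else PENALTY


def fit_bivariate(ped: Pedigree, data: pd.DataFrame, trait_x: str,
                  trait_y: str, model_x, model_y,
                  fixed_x: FixedEffectSpec | None = None,
                  fixed_y: FixedEffectSpec | None = None,
                  constraints: dict | None = None,
                  start: tuple | None = None,
                  options: FitOptions | None = None) -> BivariateResult:
    """Two-trait REML combining each trait's best univariate structure.

    Effects carried by both traits receive a 2x2 covariance block
    (parameterised as log variances + atanh correlation, so the block can
    never leave the positive-definite region); ``constraints`` pins named
    parameters, e.g. ``{"r_a": 0.0}`` for the additive-covariance LRT.
    Records lacking either trait are excluded so the two traits share one
    design (equal-design layout).
    """
    options = options or FitOptions()
    constraints = dict(constraints or {})
    ws = _BivariateWorkspace(ped, data, trait_x, trait_y, model_x, model_y,
                             fixed_x, fixed_y, options)

    vals0 = {}
    for name in ws.param_names:
        if name.startswith("r_"):
            vals0[name] = 0.0
        else:
            e, t = name[2:-1], int(name[-1]) - 1
            vy = ws.vars[t]
            n_eff = sum(ws.carried.get(k, (True, True))[t]
                        for k in ws.effects) + 1
            vals0[name] = vy / n_eff
    if start is not None:
        fx, fy = start
        for fit, t in ((fx, 1), (fy, 2)):
            if fit is None:
                continue
            c = fit.components
            vals0[f"v_a{t}"] = max(c.sigma2_a, 1e-8)
            if f"v_m{t}" in ws.param_names and c.sigma2_m > 0:
                vals0[f"v_m{t}"] = c.sigma2_m
            if f"v_pe{t}" in ws.param_names and c.sigma2_c > 0:
                vals0[f"v_pe{t}"] = c.sigma2_c
            vals0[f"v_e{t}"] = max(c.sigma2_e, 1e-8)

    x0 = ws.pack(vals0, constraints)

    def objective(xv):
        return ws.minus2_logl(ws.unpack(xv, constraints))

    best_f = objective(x0)
    if best_f >= PENALTY:
        raise ModelError("bivariate starting values infeasible")
    x = x0
    converged = False
    step = options.initial_step
    for r in range(options.max_restarts):
        x_new, f_new, conv, _ = _nelder_mead(
            objective, x, step=step, var_tol=options.simplex_var_tol,
            max_iter=options.max_iter)
        improvement = 0.5 * (best_f - f_new)
        if f_new < best_f:
            x, best_f = x_new, f_new
        converged = conv
        if conv and improvement < options.restart_logl_tol and r > 0:
            break
        step = max(step * 0.5, 0.05)

    vals = ws.unpack(x, constraints)
    blocks = ws.blocks_from(vals)
    named = {"a": "additive", "m": "maternal", "pe": "pe", "e": "residual"}
    out_blocks = {named[k]: v for k, v in blocks.items()}
    return BivariateResult(traits=(trait_x, trait_y),
                           models=tuple(m.model_id if isinstance(m, ModelSpec)
                                        else m for m in ws.models),
                           blocks=out_blocks, logL=-0.5 * best_f,
                           converged=converged, n_records=ws.n,
                           constraints=constraints,
                           param_names=list(ws.param_names))
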