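import math

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.linalg import spsolve

from amreml.varcomp import (MODEL_SPECS, FitOptions, ModelError,
                            NonIdentifiableError, VarianceComponents,
                            assemble_mme, blup_breeding_values,
                            fit_bivariate, fit_univariate,
                            restricted_loglik, standard_errors)
from amreml.pedigree import pedigree_from_frame

from oracles import (dense_blup, dense_restricted_loglik, dense_v,
                     incidence)

LOG2PI = math.log(2.0 * math.pi)

THETAS = [
    VarianceComponents(sigma2_a=2.0, sigma2_m=1.0, sigma_am=0.5,
                       sigma2_c=0.8, sigma2_e=3.0),
    VarianceComponents(sigma2_a=0.5, sigma2_m=2.5, sigma_am=-0.6,
                       sigma2_c=0.2, sigma2_e=1.2),
    VarianceComponents(sigma2_a=4.0, sigma2_m=0.3, sigma_am=0.0,
                       sigma2_c=1.5, sigma2_e=0.7),
]

FAST = FitOptions(compute_se=False)


def records_with_dams(toy_data):
    return toy_data[toy_data["dam"] != "0"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# oracle equivalence (acceptance criterion 2 exercises the same identities;
# here every model x theta pair is covered)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5, 6])
@pytest.mark.parametrize("k", range(len(THETAS)))
def test_restricted_loglik_matches_dense(toy_ped, toy_data, model_id, k):
    model = MODEL_SPECS[model_id]
    data = toy_data if model_id == 1 else records_with_dams(toy_data)
    theta = THETAS[k]
    got = restricted_loglik(toy_ped, data, model, theta, "T")
    want = dense_restricted_loglik(toy_ped, data, "T", model, theta)
    assert got == pytest.approx(want, abs=1e-8)


@pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5, 6])
def test_mme_solution_matches_dense_blup(toy_ped, toy_data, model_id):
    model = MODEL_SPECS[model_id]
    data = toy_data if model_id == 1 else records_with_dams(toy_data)
    theta = THETAS[0]
    C, rhs, layout = assemble_mme(toy_ped, data, model, theta, "T")
    sol = spsolve(C.tocsc(), rhs)
    offsets = {}
    off = 0
    for name, size in layout:
        offsets[name] = (off, off + size)
        off += size

    a_hat, m_hat = dense_blup(toy_ped, data, "T", model, theta)
    a0, a1 = offsets["a"]
    assert np.max(np.abs(sol[a0:a1] - a_hat)) <= 1e-8
    if model.maternal:
        m0, m1 = offsets["m"]
        assert np.max(np.abs(sol[m0:m1] - m_hat)) <= 1e-8

    # fixed block equals the GLS estimate
    y, X, Za, Zm, Zpe, _ = incidence(toy_ped, data, "T")
    V = dense_v(toy_ped, Za, Zm, Zpe, model, theta)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    b0, b1 = offsets["beta"]
    assert np.max(np.abs(sol[b0:b1] - beta)) <= 1e-8


@pytest.mark.parametrize("model_id", [1, 4])
def test_fitted_blup_matches_dense(toy_ped, toy_data, model_id):
    data = toy_data if model_id == 1 else records_with_dams(toy_data)
    fit = fit_univariate(toy_ped, data, "T", model_id, options=FAST)
    a_hat, _ = dense_blup(toy_ped, data, "T", fit.model, fit.components)
    bv = blup_breeding_values(fit)
    assert np.max(np.abs(bv["bv_direct"].to_numpy() - a_hat)) <= 1e-8
    # reported logL equals the dense likelihood at the fitted parameters
    want = dense_restricted_loglik(toy_ped, data, "T", fit.model,
                                   fit.components)
    assert fit.logL == pytest.approx(want, abs=1e-8)


# ---------------------------------------------------------------------------
# fit behaviour
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sim_fit(sim_small):
    return fit_univariate(sim_small.pedigree, sim_small.phenotypes, "T", 1,
                          options=FAST)


def test_scaling_invariance(sim_small, sim_fit):
    """y -> c y scales variances by c^2, shifts logL by -(n-p) log c,
    and leaves the heritability unchanged."""
    c = 7.0
    data = sim_small.phenotypes.copy()
    data["T"] = data["T"] * c
    scaled = fit_univariate(sim_small.pedigree, data, "T", 1, options=FAST)
    base = sim_fit
    assert scaled.components.sigma2_a == pytest.approx(
        c * c * base.components.sigma2_a, rel=1e-3)
    assert scaled.components.sigma2_e == pytest.approx(
        c * c * base.components.sigma2_e, rel=1e-3)
    h2_b = base.components.sigma2_a / base.components.sigma2_p
    h2_s = scaled.components.sigma2_a / scaled.components.sigma2_p
    assert h2_s == pytest.approx(h2_b, abs=1e-4)
    n_p = base.n_records - 1  # intercept only
    assert scaled.logL == pytest.approx(base.logL - n_p * math.log(c),
                                        abs=1e-3)


def test_location_invariance(sim_small, sim_fit):
    """Adding a constant to y leaves REML variance estimates unchanged."""
    data = sim_small.phenotypes.copy()
    data["T"] = data["T"] + 1000.0
    shifted = fit_univariate(sim_small.pedigree, data, "T", 1, options=FAST)
    assert shifted.components.sigma2_a == pytest.approx(
        sim_fit.components.sigma2_a, rel=1e-3)
    assert shifted.logL == pytest.approx(sim_fit.logL, abs=1e-3)


def test_nesting_monotonicity(sim_small):
    """A super-model's maximised logL can never be lower."""
    fits = {m: fit_univariate(sim_small.pedigree, sim_small.phenotypes,
                              "T", m, options=FAST)
            for m in (1, 2, 4, 5)}
    # tolerance reflects the convergence rule: var(-2 logL) < 1e-8 over
    # the simplex resolves logL only to about 1e-4
    for small, large in ((1, 2), (1, 4), (1, 5), (2, 5), (4, 5)):
        assert fits[large].logL >= fits[small].logL - 1e-3


def test_warm_start_agrees(sim_small, sim_fit):
    warm = fit_univariate(sim_small.pedigree, sim_small.phenotypes, "T", 1,
                          start=sim_fit.components, options=FAST)
    assert warm.logL == pytest.approx(sim_fit.logL, abs=1e-5)
    assert warm.components.sigma2_a == pytest.approx(
        sim_fit.components.sigma2_a, rel=1e-2)


def test_standard_errors_table(sim_small):
    fit = fit_univariate(sim_small.pedigree, sim_small.phenotypes, "T", 1)
    table = standard_errors(fit)
    assert list(table["parameter"]) == ["sigma2_a", "sigma2_e"]
    if not fit.boundary:
        assert (table["se"] > 0).all()
        # SE cannot exceed the estimate by orders of magnitude here
        assert (table["se"] < 5 * table["estimate"] + 1).all()


def test_unrelated_founders_not_identifiable():
    ped = pedigree_from_frame(pd.DataFrame(
        {"animal": [str(i) for i in range(1, 9)],
         "sire": ["0"] * 8, "dam": ["0"] * 8}))
    data = pd.DataFrame({"animal": [str(i) for i in range(1, 9)],
                         "T": np.arange(8.0)})
    with pytest.raises(NonIdentifiableError):
        fit_univariate(ped, data, "T", 1, options=FAST)


def test_pe_without_repeat_dams_not_identifiable(toy_ped):
    data = pd.DataFrame({"animal": ["5", "7", "10"],
                         "dam": ["2", "3", "6"],
                         "T": [1.0, 2.0, 3.0]})
    with pytest.raises(NonIdentifiableError):
        fit_univariate(toy_ped, data, "T", 4, options=FAST)


def test_missing_trait_rejected(toy_ped):
    data = pd.DataFrame({"animal": ["5"], "T": [np.nan]})
    with pytest.raises(ModelError, match="non-missing"):
        fit_univariate(toy_ped, data, "T", 1, options=FAST)


def test_animal_absent_from_pedigree(toy_ped):
    data = pd.DataFrame({"animal": ["zz"], "T": [1.0]})
    with pytest.raises(ModelError, match="absent"):
        fit_univariate(toy_ped, data, "T", 1, options=FAST)


def test_nested_in_lattice():
    nests = {(s, l) for s in MODEL_SPECS for l in MODEL_SPECS
             if MODEL_SPECS[s].nested_in(MODEL_SPECS[l])}
    assert nests == {(1, 2), (1, 3), (1, 4), (1, 5), (1, 6),
                     (2, 3), (2, 5), (2, 6), (3, 6), (4, 5), (4, 6),
                     (5, 6)}


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

def bivariate_dense_minus2logl(ped, data, tx, ty, blocks):
    """Stacked two-trait likelihood from the dense covariance (model 1)."""
    df = data.loc[data[tx].notna() & data[ty].notna()]
    from amreml.pedigree import additive_relationship
    A = additive_relationship(ped)
    ai = df["animal"].astype(str).map(ped.id_index).to_numpy()
    n = len(df)
    Za = np.zeros((n, ped.n))
    Za[np.arange(n), ai] = 1.0
    K = Za @ A @ Za.T
    Ba, Be = blocks["additive"], blocks["residual"]
    V = np.block([[Ba[0, 0] * K + Be[0, 0] * np.eye(n),
                   Ba[0, 1] * K + Be[0, 1] * np.eye(n)],
                  [Ba[1, 0] * K + Be[1, 0] * np.eye(n),
                   Ba[1, 1] * K + Be[1, 1] * np.eye(n)]])
    y = np.concatenate([df[tx].to_numpy(float), df[ty].to_numpy(float)])
    X = np.zeros((2 * n, 2))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    return ((2 * n - 2) * LOG2PI + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtVX)[1] + float(r @ Vinv @ r))


@pytest.fixture(scope="module")
def biv_data(sim_small):
    """Second trait correlated with T through shared residual noise."""
    rng = np.random.default_rng(77)
    data = sim_small.phenotypes.copy()
    data["U"] = 0.6 * data["T"] + rng.normal(0, 2.0, size=len(data))
    return data


def test_bivariate_logl_matches_dense(sim_small, biv_data):
    biv = fit_bivariate(sim_small.pedigree, biv_data, "T", "U", 1, 1,
                        options=FAST)
    want = bivariate_dense_minus2logl(sim_small.pedigree, biv_data,
                                      "T", "U", biv.blocks)
    assert -2.0 * biv.logL == pytest.approx(want, abs=1e-6)
    assert biv.converged


def test_bivariate_constraint_reduces_logl(sim_small, biv_data):
    free = fit_bivariate(sim_small.pedigree, biv_data, "T", "U", 1, 1,
                         options=FAST)
    pinned = fit_bivariate(sim_small.pedigree, biv_data, "T", "U", 1, 1,
                           constraints={"r_a": 0.0}, options=FAST)
    assert pinned.logL <= free.logL + 1e-4
    assert pinned.constraints == {"r_a": 0.0}
    assert pinned.correlation("additive") == pytest.approx(0.0, abs=1e-12)


def test_bivariate_blocks_valid(sim_small, biv_data):
    biv = fit_bivariate(sim_small.pedigree, biv_data, "T", "U", 1, 1,
                        options=FAST)
    for B in biv.blocks.values():
        assert B[0, 1] == B[1, 0]
        assert np.linalg.det(B) >= -1e-10
    for effect in ("additive", "residual"):
        r = biv.correlation(effect)
        assert -1.0 <= r <= 1.0
    assert -1.0 <= biv.r_p <= 1.0
    # strong positive construction: phenotypic correlation clearly > 0
    assert biv.r_p > 0.3
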