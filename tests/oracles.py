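"""Dense-matrix oracles for the sparse REML/BLUP machinery.

Everything here is deliberately naive: the restricted likelihood is
evaluated straight from the phenotypic covariance V = Z G Z' + R, and
BLUPs from Cov(u, y) V^-1 (y - X beta_GLS).  These are O(n^3) dense
computations that only work on toy problems, which is the point — they
share no code path with the sparse mixed-model-equations implementation
they check.
"""

from __future__ import annotations

import math

import numpy as np

from amreml.pedigree import additive_relationship
from amreml.varcomp import ModelSpec, VarianceComponents

LOG2PI = math.log(2.0 * math.pi)


def incidence(ped, data, trait):
    """(y, X, Za, Zm, Zpe, record frame) for a plain intercept model."""
    df = data.loc[data[trait].notna()].copy()
    n = len(df)
    ai = df["animal"].astype(str).map(ped.id_index).to_numpy()
    if "dam" in df.columns:
        di = df["dam"].astype(str).map(
            lambda t: ped.id_index.get(t, -1)).to_numpy()
    else:
        di = ped.dam[ai]
    y = df[trait].to_numpy(dtype=float)
    X = np.ones((n, 1))
    Za = np.zeros((n, ped.n))
    Za[np.arange(n), ai] = 1.0
    Zm = np.zeros((n, ped.n))
    ok = di >= 0
    Zm[np.flatnonzero(ok), di[ok]] = 1.0
    dams = np.unique(di[ok])
    Zpe = np.zeros((n, len(dams)))
    pos = {d: j for j, d in enumerate(dams)}
    for r in np.flatnonzero(ok):
        Zpe[r, pos[di[r]]] = 1.0
    return y, X, Za, Zm, Zpe, df


def dense_v(ped, Za, Zm, Zpe, model: ModelSpec, theta: VarianceComponents):
    A = additive_relationship(ped)
    n = Za.shape[0]
    V = theta.sigma2_e * np.eye(n)
    V += theta.sigma2_a * Za @ A @ Za.T
    if model.maternal:
        V += theta.sigma2_m * Zm @ A @ Zm.T
    if model.cov_am:
        V += theta.sigma_am * (Za @ A @ Zm.T + Zm @ A @ Za.T)
    if model.pe:
        V += theta.sigma2_c * Zpe @ Zpe.T
    return V


def dense_restricted_loglik(ped, data, trait, model: ModelSpec,
                            theta: VarianceComponents) -> float:
    """logL from the phenotypic covariance, no mixed-model equations."""
    y, X, Za, Zm, Zpe, _ = incidence(ped, data, trait)
    V = dense_v(ped, Za, Zm, Zpe, model, theta)
    n, p = X.shape
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    m2 = ((n - p) * LOG2PI
          + np.linalg.slogdet(V)[1]
          + np.linalg.slogdet(XtVX)[1]
          + float(r @ Vinv @ r))
    return -0.5 * m2


def dense_blup(ped, data, trait, model: ModelSpec,
               theta: VarianceComponents):
    """(direct BV, maternal BV or None) for every pedigree member."""
    y, X, Za, Zm, Zpe, _ = incidence(ped, data, trait)
    A = additive_relationship(ped)
    V = dense_v(ped, Za, Zm, Zpe, model, theta)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = Vinv @ (y - X @ beta)

    C_ay = theta.sigma2_a * A @ Za.T
    if model.cov_am:
        C_ay += theta.sigma_am * A @ Zm.T
    a_hat = C_ay @ resid
    m_hat = None
    if model.maternal:
        C_my = theta.sigma2_m * A @ Zm.T
        if model.cov_am:
            C_my += theta.sigma_am * A @ Za.T
        m_hat = C_my @ resid
    return a_hat, m_hat
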