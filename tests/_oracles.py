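"""Independent oracles used by the tests.

These deliberately avoid the package's fast code paths: likelihoods are
evaluated through dense covariance matrices and optimised directly, so they
can certify the structured implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def dense_twin_loglik(
    y,
    X,
    cohort,
    starts=(
        (-1, -1, 0), (-3, -3, 0), (0, 0, -1),
        (-8, -8, 0), (0, -8, -1), (-8, 0, -1), (-1, -4, -1),
    ),
):
    """ML loglik (and fixed effects) of the twin mixed model via the full
    n x n covariance matrix and direct optimisation over (s2_fam, s2_mz, s2)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    tab = cohort.table.set_index("sample_id").loc[cohort.samples]
    fam = tab["family_id"].to_numpy()
    zyg = tab["zygosity"].to_numpy()
    n = len(y)
    off = (fam[:, None] == fam[None, :]) & ~np.eye(n, dtype=bool)
    mz = off & (zyg[:, None] == "MZ")

    def build(vf, vm, vr):
        return np.eye(n) * (vf + vm + vr) + off * vf + mz * vm

    def nll(log_v):
        vf, vm, vr = np.exp(log_v)
        V = build(vf, vm, vr)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        r = y - X @ beta
        return 0.5 * (
            n * np.log(2 * np.pi)
            + 2 * np.log(np.diag(L)).sum()
            + r @ np.linalg.solve(V, r)
        )

    best = None
    for s in starts:
        res = optimize.minimize(
            nll, s, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 6000},
        )
        if best is None or res.fun < best.fun:
            best = res
    vf, vm, vr = np.exp(best.x)
    V = build(vf, vm, vr)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    return -best.fun, beta


def dense_vc_loglik(y, R, comps=None):
    """ML loglik of the cis/trans/cis-x-trans model via dense matrices;
    if comps is given, evaluate there (profiling the intercept) instead of
    optimising."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    mats = [R.pi_cis, R.pi_trans, R.pi_cistrans, np.eye(n)]
    one = np.ones(n)

    def negll(c):
        V = sum(ci * M for ci, M in zip(c, mats))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi1 = np.linalg.solve(V, one)
        Viy = np.linalg.solve(V, y)
        mu = (one @ Viy) / (one @ Vi1)
        r = y - mu
        return 0.5 * (
            n * np.log(2 * np.pi)
            + 2 * np.log(np.diag(L)).sum()
            + r @ np.linalg.solve(V, r)
        )

    if comps is not None:
        return -negll(np.asarray(comps, dtype=float))
    best = None
    for s in [(-1.5,) * 4, (-3, -3, -3, -0.2), (-1, -1, -2, -2)]:
        res = optimize.minimize(
            lambda x: negll(np.exp(x)), s, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def class_mean_distances(y, genotype):
    """Squared deviations from hard-genotype class means (the saturated-model
    reading of the eQTL-removal regression)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype)
    out = np.empty_like(y)
    for k in np.unique(g):
        m = g == k
        out[m] = (y[m] - y[m].mean()) ** 2
    return out
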