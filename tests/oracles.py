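"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: dense linear
algebra instead of Cholesky identities, explicit refits instead of
closed forms, full EP instead of sparse ADF, exhaustive enumeration
instead of vectorised ECDFs.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def se_kernel(X1, X2, sf2, ls):
    X1, X2 = np.atleast_2d(X1), np.atleast_2d(X2)
    d = np.sum(((X1[:, None, :] - X2[None, :, :]) / ls) ** 2, axis=2)
    return sf2 * np.exp(-0.5 * d)


def gp_predict_dense(X, y, ybar, Xs, sf2, sn2, ls):
    """GP predictive mean/variance via an explicit matrix inverse."""
    K = se_kernel(X, X, sf2, ls) + sn2 * np.eye(len(X))
    Kinv = np.linalg.inv(K)
    Ks = se_kernel(X, Xs, sf2, ls)
    mean = ybar + Ks.T @ Kinv @ (y - ybar)
    var = sf2 + sn2 - np.einsum("ij,ik,kj->j", Ks, Kinv, Ks)
    return mean, var


def gp_loo_refit(X, y, ybar, sf2, sn2, ls):
    """LOO predictions by literally refitting the posterior without point i."""
    n = len(y)
    mu = np.empty(n)
    var = np.empty(n)
    for i in range(n):
        keep = np.array([j for j in range(n) if j != i])
        m, v = gp_predict_dense(X[keep], y[keep], ybar, X[i : i + 1], sf2, sn2, ls)
        mu[i], var[i] = m[0], v[0]
    return mu, var


def ks_statistic_brute(a, b):
    """sup |ECDF_a − ECDF_b| by evaluating both ECDFs at every sample point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


def ep_probit_dense(K, y_pm, max_sweeps=60, tol=1e-9):
    """Full expectation propagation for probit GP classification.

    Standard parallel-free EP with rank-one posterior updates; returns the
    site natural parameters (tau_tilde, nu_tilde).
    """
    n = K.shape[0]
    tau = np.zeros(n)
    nu = np.zeros(n)
    Sigma = K.copy()
    mu = np.zeros(n)
    for _ in range(max_sweeps):
        tau_old = tau.copy()
        for i in range(n):
            tau_cav = 1.0 / Sigma[i, i] - tau[i]
            nu_cav = mu[i] / Sigma[i, i] - nu[i]
            if tau_cav <= 0:
                continue
            mu_c, var_c = nu_cav / tau_cav, 1.0 / tau_cav
            s = np.sqrt(1.0 + var_c)
            z = y_pm[i] * mu_c / s
            ratio = norm.pdf(z) / max(norm.cdf(z), 1e-300)
            mu_hat = mu_c + y_pm[i] * var_c * ratio / s
            var_hat = var_c - var_c**2 * ratio * (ratio + z) / (1.0 + var_c)
            var_hat = max(var_hat, 1e-12)
            d_tau = 1.0 / var_hat - tau_cav - tau[i]
            tau[i] = tau[i] + d_tau
            nu[i] = mu_hat / var_hat - nu_cav
            si = Sigma[:, i].copy()
            Sigma = Sigma - (d_tau / (1.0 + d_tau * si[i])) * np.outer(si, si)
            mu = Sigma @ nu
        if np.max(np.abs(tau - tau_old)) < tol:
            break
    return tau, nu


def ep_probit_predict(X, y_pm, Xs, sf2, ls, jitter=1e-8):
    """Dense-EP predictive success probabilities at rows of Xs."""
    K = se_kernel(X, X, sf2, ls) + jitter * np.eye(len(X))
    tau, nu = ep_probit_dense(K, y_pm)
    S = np.diag(tau)
    A = np.linalg.inv(K + np.linalg.inv(S + 1e-12 * np.eye(len(X))))
    m = nu / np.maximum(tau, 1e-12)
    Ks = se_kernel(X, Xs, sf2, ls)
    mean = Ks.T @ A @ m
    var = sf2 - np.einsum("ij,ik,kj->j", Ks, A, Ks)
    var = np.maximum(var, 1e-12)
    return norm.cdf(mean / np.sqrt(1.0 + var))
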