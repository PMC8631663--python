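"""Independent reference implementations used only to cross-check the package.

Deliberately naive: plain loops and proximal gradient descent, sharing no
code with the implementation under test.
"""

import numpy as np
from scipy.special import expit


def brute_force_threshold(xi, xj, y, grid_values, u):
    """Exhaustive scan: impurity of z = 1(xi <= c*xj) at every c, ties -> smallest c."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    y = np.asarray(y)
    best_c, best_imp = None, np.inf
    for c in grid_values:
        z = np.zeros(len(xi), dtype=int)
        for k in range(len(xi)):
            if xi[k] == 0 and xj[k] == 0:
                z[k] = 1 if u[k] < 0.5 else 0
            elif xj[k] == 0:
                z[k] = 0
            else:
                z[k] = 1 if xi[k] / xj[k] <= c else 0
        n1 = z.sum()
        n0 = len(z) - n1
        imp = 0.0
        if n1:
            p1 = y[z == 1].mean()
            imp += (n1 / len(z)) * p1 * (1 - p1)
        if n0:
            p2 = y[z == 0].mean()
            imp += (n0 / len(z)) * p2 * (1 - p2)
        if imp < best_imp:
            best_imp, best_c = imp, c
    return best_c, best_imp


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


def lasso_logistic_objective(design, y, beta0, beta, lam):
    """-(1/n) loglik + lam * ||beta||_1 (intercept unpenalized)."""
    eta = beta0 + design @ beta
    ll = np.mean(y * eta - np.logaddexp(0.0, eta))
    return -ll + lam * np.abs(beta).sum()


def fit_lasso_ista(design, y, lam, n_iter=200_000, tol=1e-12):
    """Proximal-gradient (ISTA) minimizer of the penalized logistic objective."""
    design = np.asarray(design, float)
    y = np.asarray(y, float)
    n, p = design.shape
    lip = 0.25 * (np.linalg.norm(design, 2) ** 2 / n + 1.0)
    step = 1.0 / lip
    beta0, beta = 0.0, np.zeros(p)
    prev_obj = np.inf
    for it in range(n_iter):
        eta = beta0 + design @ beta
        resid = expit(eta) - y
        beta0 -= step * resid.mean()
        raw = beta - step * (design.T @ resid) / n
        beta = np.sign(raw) * np.maximum(np.abs(raw) - step * lam, 0.0)
        if it % 200 == 0:
            obj = lasso_logistic_objective(design, y, beta0, beta, lam)
            if prev_obj - obj < tol:
                break
            prev_obj = obj
    return beta0, beta
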