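"""Independent straight-line reimplementations used as oracles.

Deliberately written with explicit loops and textbook formulas (normal
equations, definitional Pearson sums) so they share no code path with
the package implementation they check.
"""

import numpy as np


def ols_residuals_loop(V, covariates):
    """Per-region OLS residuals on [1, age, sex, education, tiv] via the
    normal equations, one region at a time."""
    n = V.shape[0]
    X = np.hstack([np.ones((n, 1)), np.asarray(covariates, dtype=float)])
    XtX_inv = np.linalg.inv(X.T @ X)
    resid = np.empty_like(V, dtype=float)
    for r in range(V.shape[1]):
        y = V[:, r]
        beta = XtX_inv @ (X.T @ y)
        resid[:, r] = y - X @ beta
    return resid


def pearson_loop(M):
    """Definitional Pearson correlation of columns of M."""
    n, R = M.shape
    out = np.eye(R)
    for a in range(R):
        for b in range(a + 1, R):
            x, y = M[:, a], M[:, b]
            xm, ym = x - x.mean(), y - y.mean()
            r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            out[a, b] = out[b, a] = r
    return out


def idscn_z_loop(V_ref, cov_ref, v_k, cov_k):
    """Full template-perturbation Z matrix, straight-line:
    residualize reference -> Pearson -> residualize n+1 -> Pearson ->
    Z = (r_pert - r_ref) / ((1 - r_ref^2)/(n - 1)) element-wise."""
    n, R = V_ref.shape
    r_ref = pearson_loop(ols_residuals_loop(V_ref, cov_ref))
    V_all = np.vstack([V_ref, v_k.reshape(1, -1)])
    cov_all = np.vstack([np.asarray(cov_ref, dtype=float),
                         np.asarray(cov_k, dtype=float).reshape(1, -1)])
    r_pert = pearson_loop(ols_residuals_loop(V_all, cov_all))
    Z = np.zeros((R, R))
    for a in range(R):
        for b in range(R):
            if a == b:
                continue
            Z[a, b] = (r_pert[a, b] - r_ref[a, b]) / (
                (1.0 - r_ref[a, b] ** 2) / (n - 1)
            )
    return Z


def pooled_t_loop(x, y):
    """Textbook pooled two-sample t statistic and df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = ((x - x.mean()) ** 2).sum() / (nx - 1)
    vy = ((y - y.mean()) ** 2).sum() / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return t, nx + ny - 2


def chi2_2x2_closed_form(a, b, c, d):
    """n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
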