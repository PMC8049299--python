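"""Independent oracles used by the test suite.

These deliberately avoid the package's own solver path: the fused-LASSO
objective is restated as a smooth QP with auxiliary absolute-value
variables and handed to a generic constrained minimizer, and KKT
subgradient certificates are checked by bounded least squares over the
free subgradient intervals.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def oracle_objective(X, y, graph, l1, l2, maxiter=3000):
    """Optimal objective value from a generic convex minimizer.

    Variables [beta0, beta, t, s] with -t <= beta <= t and
    -s_e <= beta_i - beta_j <= s_e; minimized with trust-constr using the
    exact (constant) Hessian of the quadratic part.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    E = graph.edges
    ne = len(E)
    nv = 1 + 2 * p + ne

    A1 = np.column_stack([np.ones(n), X])  # maps [beta0, beta] to predictions
    H = np.zeros((nv, nv))
    H[:1 + p, :1 + p] = 2.0 * A1.T @ A1

    def f(v):
        r = y - A1 @ v[:1 + p]
        return r @ r + l1 * v[1 + p:1 + 2 * p].sum() + l2 * v[1 + 2 * p:].sum()

    def grad(v):
        g = np.zeros(nv)
        r = y - A1 @ v[:1 + p]
        g[:1 + p] = -2.0 * A1.T @ r
        g[1 + p:1 + 2 * p] = l1
        g[1 + 2 * p:] = l2
        return g

    rows = []
    for i in range(p):
        row = np.zeros(nv); row[1 + i] = 1; row[1 + p + i] = -1; rows.append(row)
        row = np.zeros(nv); row[1 + i] = -1; row[1 + p + i] = -1; rows.append(row)
    for e, (i, j) in enumerate(E):
        row = np.zeros(nv); row[1 + i] = 1; row[1 + j] = -1
        row[1 + 2 * p + e] = -1; rows.append(row)
        row = np.zeros(nv); row[1 + i] = -1; row[1 + j] = 1
        row[1 + 2 * p + e] = -1; rows.append(row)
    con = optimize.LinearConstraint(np.array(rows), -np.inf, 0.0)
    res = optimize.minimize(f, np.zeros(nv), jac=grad, hess=lambda v: H,
                            method="trust-constr", constraints=[con],
                            options=dict(maxiter=maxiter, gtol=1e-12,
                                         xtol=1e-14))
    return f(res.x)


def kkt_residual(X, y, beta0, beta, graph, l1, l2, tol=1e-7):
    """Minimum attainable infinity-norm of a subgradient of the objective
    at (beta0, beta): a linear program over the free subgradient intervals
    (inactive coefficients and fused edges).

    Returns (stationarity residual over beta, intercept residual).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    p = X.shape[1]
    r = y - beta0 - X @ beta
    s = -2.0 * X.T @ r  # smooth part gradient wrt beta
    g0 = -2.0 * r.sum()

    E = graph.edges
    scale = max(1.0, float(np.max(np.abs(beta))) if p else 1.0)
    fixed = s.copy()
    free_cols = []
    # l1 subgradient
    for i in range(p):
        if abs(beta[i]) > tol * scale:
            fixed[i] += l1 * np.sign(beta[i])
        elif l1 > 0:
            col = np.zeros(p); col[i] = 1.0
            free_cols.append((col, l1))
    # fusion subgradient: D^T v with v_e in [-l2, l2]
    for (i, j) in E:
        d = beta[j] - beta[i]
        if abs(d) > tol * scale:
            fixed[i] += -l2 * np.sign(d)
            fixed[j] += l2 * np.sign(d)
        elif l2 > 0:
            col = np.zeros(p); col[i] = -1.0; col[j] = 1.0
            free_cols.append((col, l2))
    if not free_cols:
        return float(np.max(np.abs(fixed))), abs(g0)
    A = np.column_stack([c for c, _ in free_cols])
    nf = A.shape[1]
    # minimize t  s.t.  -t <= A w + fixed <= t,  |w_e| <= bound_e
    A_ub = np.vstack([np.column_stack([A, -np.ones(p)]),
                      np.column_stack([-A, -np.ones(p)])])
    b_ub = np.concatenate([-fixed, fixed])
    var_bounds = [(-b, b) for _, b in free_cols] + [(0, None)]
    c = np.zeros(nf + 1)
    c[-1] = 1.0
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds,
                           method="highs")
    if res.status != 0:  # pragma: no cover - LP should always solve
        return float(np.max(np.abs(fixed))), abs(g0)
    return float(res.x[-1]), abs(g0)


def random_small_instance(rng, max_genes=30, max_features=12):
    """One random instance for oracle comparison."""
    from cpgfuse.fused import FeatureChainGraph

    m = int(rng.integers(1, 5))
    k = int(rng.integers(1, 5))
    while m * k > max_features:
        k = max(1, k - 1)
    n = int(rng.integers(5, max_genes + 1))
    g = FeatureChainGraph(m, k)
    X = rng.uniform(0, 1, (n, m * k))
    y = rng.normal(0, 1, n)
    l1 = float(rng.choice([0.0, rng.uniform(0, 2)]))
    l2 = float(rng.choice([0.0, rng.uniform(0, 2)]))
    return X, y, g, l1, l2
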