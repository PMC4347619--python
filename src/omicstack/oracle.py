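"""Independent reference implementations used only for verification.

Nothing in the pipeline calls this module; tests and the acceptance script use
it to cross-check the production code paths against brute force or a
general-purpose convex solver on the identical objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "reference_lasso_objective_min",
    "brute_force_auc",
    "brute_force_global_test_p",
]


def reference_lasso_objective_min(
    X: np.ndarray, y: np.ndarray, lam: float, *, tol: float = 1e-12
) -> float:
    """Minimum of (1/m) sum log-loss + lam*||beta||_1 (unpenalized intercept)
    via L-BFGS-B on the split formulation beta = b+ - b- with b+, b- >= 0,
    which makes the objective smooth on a box."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m, p = X.shape

    def fun(theta):
        b0 = theta[0]
        bp = theta[1 : 1 + p]
        bm = theta[1 + p :]
        beta = bp - bm
        eta = b0 + X @ beta
        sig = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        f = np.mean(np.logaddexp(0.0, eta) - y * eta) + lam * (bp.sum() + bm.sum())
        r = (sig - y) / m
        g_beta = X.T @ r
        grad = np.concatenate(([r.sum()], g_beta + lam, -g_beta + lam))
        return f, grad

    x0 = np.zeros(1 + 2 * p)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20_000, "ftol": tol, "gtol": 1e-12},
    )
    return float(res.fun)


def brute_force_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by exhaustive positive-negative pair counting; ties score 1/2."""
    y = np.asarray(y).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_global_test_p(
    X: np.ndarray, y: np.ndarray, n_permutations: int, seed: int
) -> float:
    """Plain-loop permutation p-value for the score statistic
    Q = ||X^T(y-ybar)||^2 / p, mirroring the vectorized implementation's
    random stream one permutation at a time is NOT possible (the production
    code draws blocks), so this uses its own seed and is compared in
    distribution, not permutation-by-permutation."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p = X.shape[1]
    yc = y - y.mean()
    q_obs = ((X.T @ yc) ** 2).sum() / p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        q = ((X.T @ rng.permutation(yc)) ** 2).sum() / p
        if q >= q_obs:
            count += 1
    return (1 + count) / (1 + n_permutations)
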