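"""L1-penalized logistic regression: standardization, coordinate-descent fitting,
regularization path with inner-CV selection, posterior prediction.

The solver minimizes

    (1/m) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ] + lambda * ||beta||_1,
    eta = beta0 + X beta,

with an unpenalized intercept, by an outer iteratively-reweighted least squares
(IRLS) loop around cyclic coordinate descent with soft-thresholding on the
weighted quadratic approximation (the glmnet scheme).  A backtracking step on
the true composite objective guarantees a monotone objective trace, and a full
Karush-Kuhn-Tucker sweep over all features after every outer iteration makes
active-set screening exact.

Features are expected to be standardized to zero mean and *unit second central
moment* (population variance, denominator m) before fitting, so that each
coordinate is penalized on the same scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .folds import FoldAssignment

__all__ = [
    "StandardizationParams",
    "LassoLogisticModel",
    "LambdaPath",
    "fit_standardization",
    "apply_standardization",
    "lambda_max",
    "fit_lasso_logistic",
    "fit_lambda_path",
    "predict_posterior",
]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-feature centering/scaling to unit second central moment.

    ``scale`` is sqrt(mean squared deviation) with denominator m (population
    form), not m-1.  Constant columns get scale 1 and are flagged so the
    transformed column is identically zero.
    """

    center: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # boolean mask of constant (zero-variance) columns

    def to_dict_for(self, idx: np.ndarray) -> dict:
        return {
            "center": [float(c) for c in self.center[idx]],
            "scale": [float(s) for s in self.scale[idx]],
        }


def fit_standardization(X: np.ndarray) -> StandardizationParams:
    """Column means and population-SD scales from a training matrix.

    Raises on an empty matrix or fewer than 2 samples.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.size == 0:
        raise ValueError("cannot standardize an empty matrix")
    if X.shape[0] < 2:
        raise ValueError("standardization requires at least 2 samples")
    center = X.mean(axis=0)
    # second central moment with denominator m
    scale = np.sqrt(np.mean((X - center) ** 2, axis=0))
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    return StandardizationParams(center=center, scale=scale, constant=constant)


def apply_standardization(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(X, dtype=np.float64) - params.center) / params.scale


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class LassoLogisticModel:
    """Fitted sparse logistic model: intercept, coefficients, penalty and the
    standardization under which the coefficients live."""

    intercept: float
    coef: np.ndarray
    lam: float
    standardization: StandardizationParams | None
    feature_ids: list[str]
    converged: bool = True
    n_sweeps: int = 0
    objective_history: list[float] = field(default_factory=list, repr=False)

    @property
    def nonzero_index(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))

    def selected_features(self) -> list[str]:
        return [self.feature_ids[j] for j in self.nonzero_index]

    def to_json_dict(self) -> dict:
        """Compact serialization: only nonzero coefficients (with their
        standardization parameters) are stored; floats keep full precision."""
        nz = self.nonzero_index
        d = {
            "intercept": float(self.intercept),
            "lambda": float(self.lam),
            "coef": {self.feature_ids[j]: float(self.coef[j]) for j in nz},
        }
        if self.standardization is not None:
            d["standardization"] = {
                self.feature_ids[j]: [
                    float(self.standardization.center[j]),
                    float(self.standardization.scale[j]),
                ]
                for j in nz
            }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "LassoLogisticModel":
        fids = sorted(d["coef"])
        coef = np.array([d["coef"][f] for f in fids], dtype=np.float64)
        std = None
        if "standardization" in d:
            center = np.array([d["standardization"][f][0] for f in fids])
            scale = np.array([d["standardization"][f][1] for f in fids])
            std = StandardizationParams(center, scale, np.zeros(len(fids), dtype=bool))
        return cls(
            intercept=float(d["intercept"]),
            coef=coef,
            lam=float(d["lambda"]),
            standardization=std,
            feature_ids=fids,
        )


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

_P_CLIP = 1e-5  # probability clip for IRLS weights, as in glmnet


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _objective(eta: np.ndarray, y: np.ndarray, coef: np.ndarray, lam: float) -> float:
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta) + lam * np.abs(coef).sum())


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero coefficient vector is optimal:
    max_j |X_j^T (y - ybar)| / m."""
    y = np.asarray(y, dtype=np.float64)
    m = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / m)


def _cd_kernel_py(
    Xat: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    beta0: float,
    lam: float,
    tol: float,
    max_sweeps: int,
) -> tuple[float, int]:
    """Pure-numpy cyclic coordinate descent on the weighted lasso
    least-squares subproblem; ``Xat`` holds the active columns transposed
    (a, m).  Fallback for environments without a JIT."""
    a, m = Xat.shape
    r = z - beta0 - beta @ Xat
    wsum = w.sum()
    wXat = Xat * w
    denom = (wXat * Xat).sum(axis=1) / m
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_d = 0.0
        d0 = float(w @ r) / wsum
        if d0 != 0.0:
            beta0 += d0
            r -= d0
            max_d = abs(d0)
        for k in range(a):
            dk = denom[k]
            if dk <= 0.0:
                continue
            g = float(wXat[k] @ r) / m + dk * beta[k]
            bn = math.copysign(max(abs(g) - lam, 0.0), g) / dk
            d = bn - beta[k]
            if d != 0.0:
                beta[k] = bn
                r -= d * Xat[k]
                if abs(d) > max_d:
                    max_d = abs(d)
        if max_d < tol:
            break
    return beta0, sweeps


try:  # JIT-compiled kernel; the numpy fallback is semantically identical
    from numba import njit

    @njit(cache=True)
    def _cd_kernel_nb(Xat, w, z, beta, beta0, lam, tol, max_sweeps):  # pragma: no cover
        a, m = Xat.shape
        r = np.empty(m)
        for i in range(m):
            s = 0.0
            for k in range(a):
                s += beta[k] * Xat[k, i]
            r[i] = z[i] - beta0 - s
        wsum = 0.0
        for i in range(m):
            wsum += w[i]
        denom = np.empty(a)
        for k in range(a):
            s = 0.0
            for i in range(m):
                s += w[i] * Xat[k, i] * Xat[k, i]
            denom[k] = s / m
        sweeps = 0
        for _sweep in range(max_sweeps):
            sweeps += 1
            max_d = 0.0
            d0 = 0.0
            for i in range(m):
                d0 += w[i] * r[i]
            d0 /= wsum
            if d0 != 0.0:
                beta0 += d0
                for i in range(m):
                    r[i] -= d0
                max_d = abs(d0)
            for k in range(a):
                dk = denom[k]
                if dk <= 0.0:
                    continue
                g = 0.0
                for i in range(m):
                    g += w[i] * Xat[k, i] * r[i]
                g = g / m + dk * beta[k]
                if g > lam:
                    bn = (g - lam) / dk
                elif g < -lam:
                    bn = (g + lam) / dk
                else:
                    bn = 0.0
                d = bn - beta[k]
                if d != 0.0:
                    beta[k] = bn
                    for i in range(m):
                        r[i] -= d * Xat[k, i]
                    if abs(d) > max_d:
                        max_d = abs(d)
            if max_d < tol:
                break
        return beta0, sweeps

    _cd_kernel = _cd_kernel_nb
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    coef_init: np.ndarray | None = None,
    intercept_init: float | None = None,
    active_init: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
    standardization: StandardizationParams | None = None,
    context: str = "",
) -> LassoLogisticModel:
    """Fit the L1-penalized logistic model at one penalty value.

    ``X`` must already be standardized.  ``y`` is binary {0,1} and must
    contain both classes.  Convergence: maximum absolute coefficient change
    below ``tol`` with no remaining KKT violations.  On hitting the sweep
    budget a warning is raised and the current iterate is returned flagged
    ``converged=False``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        where = f" ({context})" if context else ""
        raise ValueError(f"response contains a single class{where}")

    beta = np.zeros(p) if coef_init is None else np.array(coef_init, dtype=np.float64)
    beta0 = math.log(ybar / (1.0 - ybar)) if intercept_init is None else float(intercept_init)
    active = beta != 0.0
    if active_init is not None:
        active = active | np.asarray(active_init, dtype=bool)

    eta = beta0 + X @ beta
    obj = _objective(eta, y, beta, lam)
    history = [obj]
    sweeps_total = 0
    converged = False
    act_idx = np.flatnonzero(active)
    Xat = np.ascontiguousarray(X[:, act_idx].T)

    for _ in range(1000):
        pr = _sigmoid(eta)
        # full KKT sweep: pull in any violating coordinate before solving
        grad = X.T @ (pr - y) / m
        viol = (np.abs(grad) > lam * (1 + 1e-9) + 1e-12) & ~active
        if viol.any():
            active |= viol
            act_idx = np.flatnonzero(active)
            Xat = np.ascontiguousarray(X[:, act_idx].T)
        prc = np.clip(pr, _P_CLIP, 1.0 - _P_CLIP)
        w = prc * (1.0 - prc)
        z = eta + (y - pr) / w

        budget = max_sweeps - sweeps_total
        if budget <= 0:
            break
        ba = np.ascontiguousarray(beta[act_idx])
        nb0, sw = _cd_kernel(Xat, w, z, ba, beta0, lam, tol, min(budget, 10_000))
        sweeps_total += int(sw)
        nb = beta.copy()
        nb[act_idx] = ba

        # backtracking on the true composite objective keeps the trace monotone
        t = 1.0
        accepted = False
        for _bt in range(30):
            cba = beta[act_idx] + t * (ba - beta[act_idx])
            cb0 = beta0 + t * (nb0 - beta0)
            ceta = cb0 + cba @ Xat
            cobj = float(
                np.mean(np.logaddexp(0.0, ceta) - y * ceta) + lam * np.abs(cba).sum()
            )
            if cobj <= obj + 1e-12:
                accepted = True
                break
            t *= 0.5
        if accepted:
            cb = beta.copy()
            cb[act_idx] = cba
        else:
            cb, cb0, ceta, cobj = beta, beta0, eta, obj

        delta = max(np.max(np.abs(cb - beta), initial=0.0), abs(cb0 - beta0))
        beta, beta0, eta, obj = cb, cb0, ceta, cobj
        history.append(obj)

        if delta < tol:
            pr = _sigmoid(eta)
            grad = X.T @ (pr - y) / m
            if not ((np.abs(grad) > lam * (1 + 1e-9) + 1e-12) & ~active).any():
                converged = True
                break
        if sweeps_total >= max_sweeps:
            break

    if not converged:
        warnings.warn(
            f"lasso logistic solver hit the sweep budget before converging"
            f"{' (' + context + ')' if context else ''}; returning current iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    return LassoLogisticModel(
        intercept=float(beta0),
        coef=beta,
        lam=float(lam),
        standardization=standardization,
        feature_ids=feature_ids if feature_ids is not None else [str(j) for j in range(p)],
        converged=converged,
        n_sweeps=sweeps_total,
        objective_history=history,
    )


def kkt_residuals(model: LassoLogisticModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature score |(1/m) X_j^T (y - p_hat)| at the fitted model; for an
    exact solution this is <= lambda everywhere and = lambda on the support."""
    eta = model.intercept + X @ model.coef
    return np.abs(X.T @ (np.asarray(y, float) - _sigmoid(eta))) / X.shape[0]


# ---------------------------------------------------------------------------
# regularization path with inner-CV selection
# ---------------------------------------------------------------------------

@dataclass
class LambdaPath:
    """Warm-started penalty path with per-lambda inner-CV binomial deviance.

    The grid is strictly decreasing and starts at lambda_max, so the first
    model on the path has an all-zero coefficient vector.  The selected
    lambda minimizes mean inner-CV deviance, ties broken toward the larger
    (sparser) penalty.
    """

    grid: np.ndarray
    models: list[LassoLogisticModel]
    cv_deviance: np.ndarray
    selected_index: int
    null_deviance: float
    warnings_log: list[str] = field(default_factory=list)

    @property
    def selected_lambda(self) -> float:
        return float(self.grid[self.selected_index])

    @property
    def selected_model(self) -> LassoLogisticModel:
        return self.models[self.selected_index]


def _deviance(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample binomial deviance contributions -2 log-lik."""
    return 2.0 * (np.logaddexp(0.0, eta) - y * eta)


def _warm_path(
    Xs: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    tol: float,
    max_sweeps: int,
    feature_ids: list[str] | None,
    standardization: StandardizationParams | None,
    context: str,
) -> list[LassoLogisticModel]:
    """Fit the whole decreasing grid with warm starts and strong-rule
    screening (sequential rule; exactness restored by the solver's full KKT
    sweep)."""
    m, p = Xs.shape
    models: list[LassoLogisticModel] = []
    beta = np.zeros(p)
    beta0 = None
    lam_prev = None
    for lam in grid:
        if lam_prev is None:
            screen = None
        else:
            eta = (beta0 if beta0 is not None else 0.0) + Xs @ beta
            score = np.abs(Xs.T @ (y - _sigmoid(eta))) / m
            screen = score >= (2.0 * lam - lam_prev)
        model = fit_lasso_logistic(
            Xs,
            y,
            float(lam),
            tol=tol,
            max_sweeps=max_sweeps,
            coef_init=beta,
            intercept_init=beta0,
            active_init=screen,
            feature_ids=feature_ids,
            standardization=standardization,
            context=context,
        )
        models.append(model)
        beta = model.coef.copy()
        beta0 = model.intercept
        lam_prev = float(lam)
    return models


def _merge_degenerate_inner_folds(
    fold: np.ndarray, y: np.ndarray, k: int, log: list[str]
) -> tuple[np.ndarray, int]:
    """If removing one inner fold leaves a single-class training set, merge
    that fold into its neighbor (with a warning)."""
    fold = fold.copy()
    changed = True
    while changed and len(np.unique(fold)) > 2:
        changed = False
        labels = np.unique(fold)
        for f in labels:
            rest = y[fold != f]
            if rest.size == 0 or rest.min() == rest.max():
                neighbor = labels[(list(labels).index(f) + 1) % len(labels)]
                msg = (
                    f"inner fold {f} leaves a single-class training set; "
                    f"merged into fold {neighbor}"
                )
                warnings.warn(msg, RuntimeWarning, stacklevel=3)
                log.append(msg)
                fold[fold == f] = neighbor
                changed = True
                break
    # relabel to 0..k'-1
    labels = np.unique(fold)
    remap = {old: new for new, old in enumerate(labels)}
    return np.array([remap[f] for f in fold]), len(labels)


def fit_lambda_path(
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: FoldAssignment,
    *,
    grid_size: int = 50,
    grid_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 100_000,
    feature_ids: list[str] | None = None,
    context: str = "",
) -> LambdaPath:
    """Regularization path on raw training data with k-fold inner-CV penalty
    selection.

    Standardization is refit inside every inner-CV split (and once on the full
    training set for the returned models) so the held-in folds never see
    held-out statistics.  The deviance curve pools per-sample deviances over
    all inner validation folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    m = X.shape[0]
    if len(inner_folds.fold) != m:
        raise ValueError("inner fold assignment does not match training set size")

    std = fit_standardization(X)
    Xs = apply_standardization(X, std)
    lmax = lambda_max(Xs, y)
    if lmax <= 0:
        lmax = 1e-12
    exponents = np.arange(grid_size) / max(grid_size - 1, 1)
    grid = lmax * grid_ratio**exponents

    log: list[str] = []
    fold, k = _merge_degenerate_inner_folds(inner_folds.fold, y, inner_folds.k, log)

    dev_sum = np.zeros(grid_size)
    n_eval = 0
    for f in range(k):
        test = fold == f
        train = ~test
        Xtr, ytr = X[train], y[train]
        if ytr.size == 0 or ytr.min() == ytr.max():
            msg = f"inner fold {f}: single-class training set, fold unusable for CV"
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            log.append(msg)
            continue
        n_eval += int(test.sum())
        stdf = fit_standardization(Xtr)
        models_f = _warm_path(
            apply_standardization(Xtr, stdf), ytr, grid, tol, max_sweeps, None, None,
            context=f"{context} inner fold {f}" if context else f"inner fold {f}",
        )
        Xte = apply_standardization(X[test], stdf)
        for i, mod in enumerate(models_f):
            eta = mod.intercept + Xte @ mod.coef
            dev_sum[i] += _deviance(eta, y[test]).sum()
    if n_eval == 0:
        raise ValueError("no usable inner fold: cannot select a penalty")
    cv_deviance = dev_sum / n_eval

    models = _warm_path(Xs, y, grid, tol, max_sweeps, feature_ids, std, context=context)
    # ties broken toward larger lambda: argmin returns the first (largest) one
    selected = int(np.argmin(cv_deviance))
    ybar = y.mean()
    eta0 = math.log(ybar / (1 - ybar))
    null_dev = float(_deviance(np.full(m, eta0), y).mean())
    return LambdaPath(
        grid=grid,
        models=models,
        cv_deviance=cv_deviance,
        selected_index=selected,
        null_deviance=null_dev,
        warnings_log=log,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_posterior(
    model: LassoLogisticModel,
    X: np.ndarray,
    feature_ids: list[str] | None = None,
) -> np.ndarray:
    """Posterior probabilities sigmoid(beta0 + x beta) on raw (unstandardized)
    data.

    When ``feature_ids`` is given, columns of ``X`` are aligned to the model's
    features by identifier; extra columns are ignored and missing ones raise.
    """
    X = np.asarray(X, dtype=np.float64)
    if feature_ids is not None and list(feature_ids) != list(model.feature_ids):
        pos = {f: i for i, f in enumerate(feature_ids)}
        missing = [f for f in model.feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features missing from input matrix: {missing}")
        X = X[:, [pos[f] for f in model.feature_ids]]
    elif X.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects {len(model.feature_ids)}"
        )
    if model.standardization is not None:
        X = apply_standardization(X, model.standardization)
    return _sigmoid(model.intercept + X @ model.coef)
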