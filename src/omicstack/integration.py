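"""The three integration strategies over paired omics platforms.

* **no integration** — an L1-logistic classifier per platform (``gep`` /
  ``dmp`` strategy tags);
* **early integration** — one classifier on the column-concatenated feature
  space, every column standardized to the same scale;
* **late integration** — a two-layer stack: per-platform L1-logistic
  first layer, then a nearest-mean classifier (NMC) on the 2-D space of the
  two posterior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import OmicsMatrix
from .folds import FoldAssignment
from .lasso import (
    LambdaPath,
    LassoLogisticModel,
    apply_standardization,
    fit_lambda_path,
    fit_standardization,
    predict_posterior,
)

__all__ = [
    "STRATEGIES",
    "EarlyMatrix",
    "NMCModel",
    "LateStackModel",
    "concat_features",
    "fit_nmc",
    "nmc_score",
    "train_strategy",
    "count_selected_features",
]

STRATEGIES = ("gep", "dmp", "early", "late")


# ---------------------------------------------------------------------------
# early integration
# ---------------------------------------------------------------------------

@dataclass
class EarlyMatrix:
    """Concatenated samples x (GEP ++ DMP) matrix with per-column origin tags.

    Feature identifiers are prefixed with their platform tag so the combined
    id space stays collision-free.
    """

    matrix: OmicsMatrix
    origins: np.ndarray  # per-column platform tag

    @property
    def n_features(self) -> int:
        return self.matrix.n_features

    def subset_by_origin(self, origin: str) -> OmicsMatrix:
        idx = np.flatnonzero(self.origins == origin)
        return OmicsMatrix(
            self.matrix.values[:, idx],
            self.matrix.sample_ids,
            [self.matrix.feature_ids[j].split(":", 1)[1] for j in idx],
            origin,
        )


def concat_features(gep: OmicsMatrix, dmp: OmicsMatrix) -> EarlyMatrix:
    """Column-wise concatenation, first platform first.

    Requires identical sample sets *and order*; align by id upstream if
    needed.  Raises with the symmetric difference on a sample mismatch.
    """
    if gep.sample_ids != dmp.sample_ids:
        a, b = set(gep.sample_ids), set(dmp.sample_ids)
        diff = sorted(a.symmetric_difference(b))
        if diff:
            raise ValueError(f"sample sets differ between platforms: {diff}")
        raise ValueError("platforms contain the same samples in different orders")
    tag_a = gep.platform or "GEP"
    tag_b = dmp.platform or "DMP"
    values = np.concatenate([gep.values, dmp.values], axis=1)
    fids = [f"{tag_a}:{f}" for f in gep.feature_ids] + [f"{tag_b}:{f}" for f in dmp.feature_ids]
    origins = np.array([tag_a] * gep.n_features + [tag_b] * dmp.n_features)
    return EarlyMatrix(
        matrix=OmicsMatrix(values, list(gep.sample_ids), fids, "early"),
        origins=origins,
    )


# ---------------------------------------------------------------------------
# nearest-mean second layer
# ---------------------------------------------------------------------------

@dataclass
class NMCModel:
    """Nearest-mean classifier in the 2-D posterior space (p_gep, p_dmp).

    Class means are unweighted; the decision boundary is the perpendicular
    bisector of the segment joining them.
    """

    mean_positive: np.ndarray
    mean_negative: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "mean_positive": [float(v) for v in self.mean_positive],
            "mean_negative": [float(v) for v in self.mean_negative],
        }


def fit_nmc(points: np.ndarray, y: np.ndarray) -> NMCModel:
    """Unweighted class means of the posterior points; both classes required."""
    points = np.asarray(points, dtype=np.float64)
    y = np.asarray(y)
    if points.ndim != 2:
        raise ValueError("points must be 2-D")
    pos = points[y == 1]
    neg = points[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("nearest-mean classifier requires both classes")
    return NMCModel(mean_positive=pos.mean(axis=0), mean_negative=neg.mean(axis=0))


def nmc_score(model: NMCModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed score ``||x - mu_neg||^2 - ||x - mu_pos||^2`` (affine in x) and
    the binary prediction ``score >= 0`` (ties go to the positive class)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d_neg = ((points - model.mean_negative) ** 2).sum(axis=1)
    d_pos = ((points - model.mean_positive) ** 2).sum(axis=1)
    score = d_neg - d_pos
    return score, (score >= 0).astype(np.int8)


# ---------------------------------------------------------------------------
# fitted strategy containers
# ---------------------------------------------------------------------------

@dataclass
class SinglePlatformFit:
    strategy: str  # "gep" | "dmp"
    path: LambdaPath
    model: LassoLogisticModel
    platform: str

    def predict(self, gep: OmicsMatrix, dmp: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
        X = gep if self.strategy == "gep" else dmp
        post = predict_posterior(self.model, X.values, X.feature_ids)
        return post, (post >= 0.5).astype(np.int8)

    def selected_counts(self) -> dict[str, int]:
        n = self.model.n_selected
        return {"GEP": n, "DMP": 0} if self.strategy == "gep" else {"GEP": 0, "DMP": n}

    def selected_lambdas(self) -> dict[str, float]:
        return {self.strategy: self.path.selected_lambda}

    def models_json(self) -> dict:
        return {self.strategy: self.model.to_json_dict()}


@dataclass
class EarlyFit:
    path: LambdaPath
    model: LassoLogisticModel
    origins: np.ndarray

    def predict(self, gep: OmicsMatrix, dmp: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
        em = concat_features(gep, dmp)
        post = predict_posterior(self.model, em.matrix.values, em.matrix.feature_ids)
        return post, (post >= 0.5).astype(np.int8)

    def selected_counts(self) -> dict[str, int]:
        nz = self.model.nonzero_index
        tags, counts = np.unique(self.origins[nz], return_counts=True) if len(nz) else ((), ())
        out = {"GEP": 0, "DMP": 0}
        for t, c in zip(tags, counts):
            out[str(t)] = int(c)
        return out

    def selected_lambdas(self) -> dict[str, float]:
        return {"early": self.path.selected_lambda}

    def models_json(self) -> dict:
        return {"early": self.model.to_json_dict()}


@dataclass
class LateStackModel:
    """Two first-layer per-platform lasso-logistic models plus the NMC second
    layer trained on their posterior pairs."""

    first_layer_gep: LassoLogisticModel
    first_layer_dmp: LassoLogisticModel
    second_layer: NMCModel

    def posterior_points(self, gep: OmicsMatrix, dmp: OmicsMatrix) -> np.ndarray:
        p_g = predict_posterior(self.first_layer_gep, gep.values, gep.feature_ids)
        p_d = predict_posterior(self.first_layer_dmp, dmp.values, dmp.feature_ids)
        return np.column_stack([p_g, p_d])

    def predict(self, gep: OmicsMatrix, dmp: OmicsMatrix) -> tuple[np.ndarray, np.ndarray]:
        return nmc_score(self.second_layer, self.posterior_points(gep, dmp))

    def selected_counts(self) -> dict[str, int]:
        return {
            "GEP": self.first_layer_gep.n_selected,
            "DMP": self.first_layer_dmp.n_selected,
        }

    def selected_lambdas(self) -> dict[str, float]:
        return {
            "gep": self.first_layer_gep.lam,
            "dmp": self.first_layer_dmp.lam,
        }

    def models_json(self) -> dict:
        return {
            "late_gep": self.first_layer_gep.to_json_dict(),
            "late_dmp": self.first_layer_dmp.to_json_dict(),
            "late_nmc": self.second_layer.to_json_dict(),
        }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _fit_platform(
    X: OmicsMatrix,
    y: np.ndarray,
    inner_folds: FoldAssignment,
    *,
    grid_size: int,
    grid_ratio: float,
    tol: float,
    context: str,
) -> LambdaPath:
    return fit_lambda_path(
        X.values,
        y,
        inner_folds,
        grid_size=grid_size,
        grid_ratio=grid_ratio,
        tol=tol,
        feature_ids=X.feature_ids,
        context=context,
    )


def _out_of_fold_posteriors(
    X: OmicsMatrix,
    y: np.ndarray,
    inner_folds: FoldAssignment,
    lam: float,
    tol: float,
) -> np.ndarray:
    """Posteriors of per-inner-fold refits at the selected penalty, each
    sample scored by the fold that held it out (less optimistic NMC input)."""
    from .lasso import fit_lasso_logistic  # local import to keep module top light

    post = np.empty(len(y))
    for f in np.unique(inner_folds.fold):
        test = inner_folds.fold == f
        train = ~test
        if y[train].min() == y[train].max():
            post[test] = y[train].mean()
            continue
        std = fit_standardization(X.values[train])
        Xs = apply_standardization(X.values[train], std)
        model = fit_lasso_logistic(Xs, y[train], lam, tol=tol)
        Xt = apply_standardization(X.values[test], std)
        from .lasso import _sigmoid

        post[test] = _sigmoid(model.intercept + Xt @ model.coef)
    return post


def train_strategy(
    strategy: str,
    gep: OmicsMatrix,
    dmp: OmicsMatrix,
    y: np.ndarray,
    inner_folds: FoldAssignment,
    *,
    grid_size: int = 50,
    grid_ratio: float = 1e-3,
    tol: float = 1e-7,
    nmc_posteriors: str = "in_sample",
    platform_paths: dict[str, LambdaPath] | None = None,
    context: str = "",
):
    """Fit one strategy on an outer-training set.

    ``platform_paths`` lets a caller share the per-platform regularization
    paths between the single-platform and late strategies (they are identical
    by construction under a common fold assignment).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    cache = platform_paths if platform_paths is not None else {}

    def platform_path(tag: str) -> LambdaPath:
        if tag not in cache:
            X = gep if tag == "gep" else dmp
            cache[tag] = _fit_platform(
                X, y, inner_folds,
                grid_size=grid_size, grid_ratio=grid_ratio, tol=tol,
                context=f"{context} {tag}".strip(),
            )
        return cache[tag]

    if strategy in ("gep", "dmp"):
        path = platform_path(strategy)
        platform = (gep if strategy == "gep" else dmp).platform
        return SinglePlatformFit(strategy, path, path.selected_model, platform)

    if strategy == "early":
        em = concat_features(gep, dmp)
        path = _fit_platform(
            em.matrix, y, inner_folds,
            grid_size=grid_size, grid_ratio=grid_ratio, tol=tol,
            context=f"{context} early".strip(),
        )
        return EarlyFit(path, path.selected_model, em.origins)

    # late
    path_g = platform_path("gep")
    path_d = platform_path("dmp")
    model_g = path_g.selected_model
    model_d = path_d.selected_model
    if nmc_posteriors == "in_sample":
        p_g = predict_posterior(model_g, gep.values, gep.feature_ids)
        p_d = predict_posterior(model_d, dmp.values, dmp.feature_ids)
    elif nmc_posteriors == "out_of_fold":
        p_g = _out_of_fold_posteriors(gep, y, inner_folds, model_g.lam, tol)
        p_d = _out_of_fold_posteriors(dmp, y, inner_folds, model_d.lam, tol)
    else:
        raise ValueError("nmc_posteriors must be 'in_sample' or 'out_of_fold'")
    nmc = fit_nmc(np.column_stack([p_g, p_d]), y)
    return LateStackModel(model_g, model_d, nmc)


def count_selected_features(fit) -> dict[str, int]:
    """Nonzero-coefficient counts split by platform origin for any fitted
    strategy object."""
    return fit.selected_counts()
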