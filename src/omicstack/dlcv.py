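"""Double-loop cross-validation over one-vs-all subtype tasks.

The outer loop splits the samples into five (near-)equal validation subsets,
shared across every subtype and every integration strategy so comparisons are
paired.  For each outer iteration a classifier is trained on the remaining
four subsets, with a 5-fold inner loop selecting the lasso penalty, and then
scores the held-out validation subset.  Validation samples are never touched
during standardization, penalty selection, or second-layer training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import LabelMatrix, OmicsMatrix
from .folds import FoldAssignment, make_inner_folds, make_outer_folds
from .integration import STRATEGIES, train_strategy

__all__ = [
    "FoldAssignment",
    "make_outer_folds",
    "make_inner_folds",
    "OneVsAllTask",
    "FoldResult",
    "DLCVResult",
    "derive_inner_seed",
    "run_dlcv",
]

logger = logging.getLogger(__name__)


@dataclass
class OneVsAllTask:
    """One subtype against all remaining samples.

    Samples carrying multiple abnormalities are positive for each of their
    subtypes' tasks and negative in every other task.
    """

    subtype: str
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("task response must be binary")


def tasks_from_labels(labels: LabelMatrix) -> list[OneVsAllTask]:
    """One task per subtype column; all-zero (or all-one) columns are skipped
    with a warning since no classifier can be trained for them."""
    out = []
    for s in labels.subtypes:
        y = labels.y(s)
        if y.min() == y.max():
            logger.warning("subtype %r has a single class; task skipped", s)
            continue
        out.append(OneVsAllTask(subtype=s, y=y))
    return out


@dataclass
class FoldResult:
    """Held-out predictions and bookkeeping for one (task, strategy, fold)."""

    fold: int
    val_sample_ids: list[str]
    y_true: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    count_gep: int
    count_dmp: int
    selected_lambda: dict[str, float] = field(default_factory=dict)
    skipped: bool = False
    reason: str = ""
    models_json: dict = field(default_factory=dict)

    @classmethod
    def skipped_fold(cls, fold: int, reason: str) -> "FoldResult":
        return cls(
            fold=fold, val_sample_ids=[], y_true=np.array([]), scores=np.array([]),
            predictions=np.array([]), count_gep=0, count_dmp=0,
            skipped=True, reason=reason,
        )


@dataclass
class DLCVResult:
    """All per-fold results keyed by (subtype, strategy), plus the shared
    outer fold assignment."""

    outer: FoldAssignment
    sample_ids: list[str]
    strategies: list[str]
    subtypes: list[str]
    folds: dict[tuple[str, str], list[FoldResult]]

    def get(self, subtype: str, strategy: str) -> list[FoldResult]:
        return self.folds[(subtype, strategy)]


def derive_inner_seed(master_seed: int, outer_fold: int, task_index: int) -> int:
    """Deterministic, independent inner-fold seed per (outer fold, task)."""
    ss = np.random.SeedSequence([int(master_seed), int(outer_fold), int(task_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_dlcv(
    tasks: list[OneVsAllTask],
    gep: OmicsMatrix,
    dmp: OmicsMatrix,
    strategies: list[str],
    *,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    grid_size: int = 50,
    grid_ratio: float = 1e-3,
    tol: float = 1e-7,
    nmc_posteriors: str = "in_sample",
    outer: FoldAssignment | None = None,
    keep_models: bool = True,
) -> DLCVResult:
    """Run the double-loop protocol for every task and strategy.

    A single outer fold assignment is shared by all tasks and strategies.
    Tasks with fewer than two positives (or negatives) in an outer-training
    set are skipped for that fold and recorded as such.
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    if gep.sample_ids != dmp.sample_ids:
        raise ValueError("platforms must be sample-aligned (same ids, same order)")
    n = gep.n_samples
    if outer is None:
        outer = make_outer_folds(n, k_outer, seed)

    folds: dict[tuple[str, str], list[FoldResult]] = {
        (t.subtype, s): [] for t in tasks for s in strategies
    }

    for of in range(outer.k):
        val_idx = outer.indices(of)
        train_idx = np.flatnonzero(outer.fold != of)
        gep_tr, dmp_tr = gep.subset_samples(train_idx), dmp.subset_samples(train_idx)
        gep_va, dmp_va = gep.subset_samples(val_idx), dmp.subset_samples(val_idx)
        val_ids = [gep.sample_ids[i] for i in val_idx]

        for ti, task in enumerate(tasks):
            y_tr = task.y[train_idx]
            y_va = task.y[val_idx]
            n_pos, n_neg = int(y_tr.sum()), int(len(y_tr) - y_tr.sum())
            if n_pos < 2 or n_neg < 2:
                reason = (
                    f"outer fold {of}: task {task.subtype!r} has "
                    f"{n_pos} positives / {n_neg} negatives in training"
                )
                logger.warning("%s; skipped", reason)
                for s in strategies:
                    folds[(task.subtype, s)].append(FoldResult.skipped_fold(of, reason))
                continue

            inner_seed = derive_inner_seed(seed, of, ti)
            inner = make_inner_folds(y_tr, k_inner, inner_seed)
            shared_paths: dict = {}
            for s in strategies:
                fit = train_strategy(
                    s, gep_tr, dmp_tr, y_tr, inner,
                    grid_size=grid_size, grid_ratio=grid_ratio, tol=tol,
                    nmc_posteriors=nmc_posteriors,
                    platform_paths=shared_paths,
                    context=f"{task.subtype} fold {of}",
                )
                scores, preds = fit.predict(gep_va, dmp_va)
                counts = fit.selected_counts()
                lambdas = {k: float(v) for k, v in fit.selected_lambdas().items()}
                folds[(task.subtype, s)].append(
                    FoldResult(
                        fold=of,
                        val_sample_ids=val_ids,
                        y_true=y_va,
                        scores=np.asarray(scores, dtype=np.float64),
                        predictions=np.asarray(preds, dtype=np.int8),
                        count_gep=counts.get("GEP", 0),
                        count_dmp=counts.get("DMP", 0),
                        selected_lambda=lambdas,
                        models_json=fit.models_json() if keep_models else {},
                    )
                )

    return DLCVResult(
        outer=outer,
        sample_ids=list(gep.sample_ids),
        strategies=list(strategies),
        subtypes=[t.subtype for t in tasks],
        folds=folds,
    )
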