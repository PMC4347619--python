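"""Cross-validation fold construction for the double-loop protocol.

Outer folds are a single random equal partition shared by every subtype task
and every integration strategy, so that strategy comparisons are paired on
identical validation subsets.  Inner folds are stratified on the one-vs-all
response when both classes are large enough; with very few positives they are
spread round-robin so no inner fold hoards them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldAssignment", "make_outer_folds", "make_inner_folds"]


@dataclass
class FoldAssignment:
    """Per-sample fold indices in ``{0..k-1}`` forming a balanced partition."""

    fold: np.ndarray
    k: int
    seed: int
    level: str  # "outer" | "inner"

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=np.int64)
        sizes = np.bincount(self.fold, minlength=self.k)
        if len(sizes) != self.k or (self.fold < 0).any() or (self.fold >= self.k).any():
            raise ValueError("fold indices must cover {0..k-1}")
        if sizes.max() - sizes.min() > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes.tolist()}")

    def indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def to_tsv(self, sample_ids: list[str]) -> str:
        lines = ["sample\tfold"]
        lines += [f"{s}\t{int(f)}" for s, f in zip(sample_ids, self.fold)]
        return "\n".join(lines) + "\n"


def make_outer_folds(n_samples: int, k: int = 5, seed: int = 0) -> FoldAssignment:
    """One random partition of ``n_samples`` into ``k`` (near-)equal subsets."""
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    fold = np.empty(n_samples, dtype=np.int64)
    fold[perm] = np.arange(n_samples) % k
    return FoldAssignment(fold=fold, k=k, seed=seed, level="outer")


def make_inner_folds(
    y: np.ndarray, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Fold assignment for one outer-training set.

    Stratified on ``y`` when each class has at least ``k`` members; otherwise
    the minority positives are dealt round-robin across folds (never
    co-located while there are fewer positives than folds) and negatives fill
    the folds back to balance.
    """
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    fold = np.empty(n, dtype=np.int64)
    # positives dealt round-robin over shuffled order: per-fold counts differ
    # by at most one (exact stratification), and fewer positives than folds
    # are never co-located
    p_idx = rng.permutation(pos)
    fold[p_idx] = np.arange(len(p_idx)) % k
    # shuffled negatives fill each fold up to its balanced target size
    sizes_pos = np.bincount(fold[p_idx] if len(p_idx) else np.array([], dtype=int), minlength=k)
    target = _balanced_sizes(n, k)
    deficit = target - sizes_pos
    if (deficit < 0).any() or deficit.sum() != len(neg):
        # only reachable when one class nearly fills the data; fall back to
        # plain balanced dealing of the negatives
        deficit = _balanced_sizes(len(neg), k)
    slots = np.repeat(np.arange(k), deficit)
    fold[rng.permutation(neg)] = slots
    return FoldAssignment(fold=fold, k=k, seed=seed, level="inner")


def _balanced_sizes(n: int, k: int) -> np.ndarray:
    base = n // k
    sizes = np.full(k, base, dtype=np.int64)
    sizes[: n % k] += 1
    return sizes
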