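"""Evaluation: F-score at the fixed 0.5 posterior threshold, ROC-AUC over all
thresholds, the permutation global association test, and per-fold aggregation
into strategy reports.

F-score and AUC are delegated to scikit-learn behind this surface
(``f1_score`` with ``zero_division=0`` implements the declared
precision+recall = 0 -> 0 rule; ``roc_auc_score`` is the Mann-Whitney
statistic with ties counted one half).  The global test statistic

    Q = (y - ybar)^T X X^T (y - ybar) / p

is the score statistic for the null hypothesis that the variance of the
regression coefficients of all input features is zero; its p-value comes from
a label-permutation null with add-one correction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "GlobalTestResult",
    "StrategyReport",
    "confusion",
    "f_score",
    "roc_auc",
    "global_test",
    "aggregate_report",
]


# ---------------------------------------------------------------------------
# threshold metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    y = np.asarray(y_true).astype(int)
    p = np.asarray(predictions).astype(int)
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def f_score(
    y_true: np.ndarray, posteriors: np.ndarray, threshold: float = 0.5
) -> float:
    """F = 2PR/(P+R) with positives called at posterior >= threshold.

    Degenerate cases with precision + recall = 0 are defined as 0.
    """
    y = np.asarray(y_true)
    p = np.asarray(posteriors)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("length mismatch")
    pred = (p >= threshold).astype(int)
    return float(f1_score(y.astype(int), pred, zero_division=0))


def f_score_from_predictions(y_true: np.ndarray, predictions: np.ndarray) -> float:
    """F-score from pre-thresholded binary predictions (used for the NMC
    second layer, whose threshold is learned rather than fixed at 0.5)."""
    y = np.asarray(y_true).astype(int)
    if len(y) == 0:
        raise ValueError("empty input")
    return float(f1_score(y, np.asarray(predictions).astype(int), zero_division=0))


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC = P(score+ > score-) + 0.5 P(score+ = score-); both classes
    required (single-class folds are flagged upstream and excluded from
    means)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for a single-class response")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# global association test
# ---------------------------------------------------------------------------

@dataclass
class GlobalTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def global_test(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GlobalTestResult:
    """Association between a (column-standardized) feature set and a binary
    label.

    The statistic ``Q = ||X^T (y - ybar)||^2 / p`` grows when many features
    co-vary with the label; its null distribution is obtained by permuting
    ``y``, and the p-value uses the add-one (permutation-inclusive)
    correction, so the attainable floor is 1/(n_permutations + 1).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be samples x features aligned with y")
    if y.min() == y.max():
        raise ValueError("global test requires both classes")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give a coarse p-value resolution",
            RuntimeWarning,
            stacklevel=2,
        )
    n, p = X.shape
    if p == 0:
        return GlobalTestResult(0.0, 1.0, n_permutations, seed)
    yc = y - y.mean()
    q_obs = float(((X.T @ yc) ** 2).sum() / p)
    rng = np.random.default_rng(seed)
    # permute in vectorized blocks to bound memory at ~blocks x n doubles
    block = max(1, min(n_permutations, int(2e7 // max(n, 1))))
    count = 0
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        q_perm = ((yc[idx] @ X) ** 2).sum(axis=1) / p
        count += int((q_perm >= q_obs).sum())
        done += b
    p_value = (1 + count) / (1 + n_permutations)
    return GlobalTestResult(q_obs, float(p_value), n_permutations, seed)


# ---------------------------------------------------------------------------
# report aggregation
# ---------------------------------------------------------------------------

@dataclass
class TaskStrategyEntry:
    subtype: str
    strategy: str
    fold_f: list[float | None]
    fold_auc: list[float | None]
    fold_count_gep: list[int | None]
    fold_count_dmp: list[int | None]
    fold_skipped: list[bool]
    skip_reasons: list[str]
    mean_f: float | None
    mean_auc: float | None
    mean_count_gep: float | None
    mean_count_dmp: float | None
    global_p: float | None = None
    global_statistic: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class StrategyReport:
    """Per-(subtype, strategy) means with full per-fold detail, plus the
    cross-subtype Pearson correlation of GEP/DMP selected-feature counts per
    strategy (the platform-proportion similarity summary)."""

    entries: list[TaskStrategyEntry]
    platform_count_correlations: dict[str, float | None] = field(default_factory=dict)

    def entry(self, subtype: str, strategy: str) -> TaskStrategyEntry:
        for e in self.entries:
            if e.subtype == subtype and e.strategy == strategy:
                return e
        raise KeyError((subtype, strategy))

    def to_json(self) -> str:
        payload = {
            "entries": [e.to_dict() for e in self.entries],
            "platform_count_correlations": self.platform_count_correlations,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StrategyReport":
        payload = json.loads(text)
        entries = [TaskStrategyEntry(**d) for d in payload["entries"]]
        return cls(entries, payload.get("platform_count_correlations", {}))

    def to_tsv(self) -> str:
        cols = [
            "subtype", "strategy", "mean_f", "mean_auc",
            "mean_count_gep", "mean_count_dmp", "global_p", "n_valid_folds",
        ]
        lines = ["\t".join(cols)]
        for e in self.entries:
            n_valid = sum(1 for s in e.fold_skipped if not s)
            row = [
                e.subtype, e.strategy,
                _fmt(e.mean_f), _fmt(e.mean_auc),
                _fmt(e.mean_count_gep), _fmt(e.mean_count_dmp),
                _fmt(e.global_p), str(n_valid),
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    return "NA" if v is None else repr(float(v))


def _mean_or_none(values: list) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def aggregate_report(result) -> StrategyReport:
    """Fold results -> per-task arithmetic means (skipped folds excluded and
    flagged; single-class validation folds excluded from the AUC mean only)
    and per-strategy cross-subtype platform-count correlations."""
    from .dlcv import DLCVResult  # typing/documentation only

    assert isinstance(result, DLCVResult)
    entries: list[TaskStrategyEntry] = []
    for subtype in result.subtypes:
        for strategy in result.strategies:
            frs = result.get(subtype, strategy)
            fold_f: list[float | None] = []
            fold_auc: list[float | None] = []
            cg: list[int | None] = []
            cd: list[int | None] = []
            skipped: list[bool] = []
            reasons: list[str] = []
            for fr in frs:
                skipped.append(bool(fr.skipped))
                if fr.skipped:
                    fold_f.append(None)
                    fold_auc.append(None)
                    cg.append(None)
                    cd.append(None)
                    reasons.append(fr.reason)
                    continue
                if strategy == "late":
                    fold_f.append(f_score_from_predictions(fr.y_true, fr.predictions))
                else:
                    fold_f.append(f_score(fr.y_true, fr.scores))
                try:
                    fold_auc.append(roc_auc(fr.y_true, fr.scores))
                except ValueError:
                    fold_auc.append(None)
                    reasons.append(
                        f"fold {fr.fold}: single-class validation subset, AUC undefined"
                    )
                cg.append(fr.count_gep)
                cd.append(fr.count_dmp)
            entries.append(
                TaskStrategyEntry(
                    subtype=subtype,
                    strategy=strategy,
                    fold_f=fold_f,
                    fold_auc=fold_auc,
                    fold_count_gep=cg,
                    fold_count_dmp=cd,
                    fold_skipped=skipped,
                    skip_reasons=reasons,
                    mean_f=_mean_or_none(fold_f),
                    mean_auc=_mean_or_none(fold_auc),
                    mean_count_gep=_mean_or_none(cg),
                    mean_count_dmp=_mean_or_none(cd),
                )
            )

    report = StrategyReport(entries=entries)
    report.platform_count_correlations = _platform_correlations(report, result)
    return report


def _corr(a: list, b: list) -> float | None:
    pairs = [(x, y) for x, y in zip(a, b) if x is not None and y is not None]
    if len(pairs) < 2:
        return None
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if x.std() == 0 and y.std() == 0:
        # both profiles constant across subtypes: declared correlation 1
        return 1.0
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _platform_correlations(report: StrategyReport, result) -> dict[str, float | None]:
    """Two families of cross-subtype Pearson correlations:

    * per strategy, the GEP-side vs DMP-side mean selected-feature counts
      (keys ``none``/``early``/``late``) — similarity of platform usage
      within a strategy;
    * per strategy pair, the GEP-count proportion profiles
      (keys like ``none_vs_early``) — similarity of platform balance across
      strategies.
    """
    out: dict[str, float | None] = {}
    subtypes = result.subtypes

    def counts(strat: str) -> tuple[list, list]:
        if strat == "none":
            return (
                [report.entry(s, "gep").mean_count_gep for s in subtypes],
                [report.entry(s, "dmp").mean_count_dmp for s in subtypes],
            )
        return (
            [report.entry(s, strat).mean_count_gep for s in subtypes],
            [report.entry(s, strat).mean_count_dmp for s in subtypes],
        )

    available = []
    if "gep" in result.strategies and "dmp" in result.strategies:
        available.append("none")
    available += [s for s in ("early", "late") if s in result.strategies]

    profiles: dict[str, list] = {}
    for strat in available:
        a, b = counts(strat)
        out[strat] = _corr(a, b)
        profiles[strat] = [
            (x / (x + y) if x is not None and y is not None and (x + y) > 0 else None)
            for x, y in zip(a, b)
        ]
    for i, s1 in enumerate(available):
        for s2 in available[i + 1 :]:
            out[f"{s1}_vs_{s2}"] = _corr(profiles[s1], profiles[s2])
    return out
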