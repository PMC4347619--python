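"""Canned synthetic experiments exercising the pipeline's headline claims.

Each function generates its own data at a documented problem size, runs the
production code paths, and returns plain dictionaries of measured quantities.
The sizes are chosen so a full experiment battery runs on one CPU in minutes:
200 samples (the reduced study scale) and 500 features per platform, which
keeps the p >> n regime that motivates the lasso while staying tractable.
"""

from __future__ import annotations

import numpy as np

from .dlcv import run_dlcv, tasks_from_labels
from .folds import make_inner_folds
from .integration import concat_features
from .lasso import fit_lambda_path
from .metrics import aggregate_report, global_test
from .synth import SubtypeSpec, SyntheticConfig, generate_dataset

__all__ = [
    "early_dimensionality",
    "strategy_comparison",
    "synergy_experiment",
    "recovery_experiment",
    "shuffled_label_experiment",
    "global_test_calibration",
]

# study-scale platform widths used for the concatenation arithmetic check
N_GEP_STUDY = 21678
N_DMP_STUDY = 22725


def early_dimensionality(
    n_gep: int = N_GEP_STUDY, n_dmp: int = N_DMP_STUDY
) -> int:
    """Width of the early-integration feature space for given platform widths,
    measured on an actual concatenated matrix (one sample suffices)."""
    from .datatypes import OmicsMatrix

    gep = OmicsMatrix(np.zeros((1, n_gep)), ["s0"], [f"g{j}" for j in range(n_gep)], "GEP")
    dmp = OmicsMatrix(np.zeros((1, n_dmp)), ["s0"], [f"m{j}" for j in range(n_dmp)], "DMP")
    return concat_features(gep, dmp).n_features


def _one_subtype_config(
    mode: str,
    *,
    n_samples: int = 200,
    n_features: int = 500,
    n_signal: int = 30,
    effect: float = 2.5,
    prevalence: float = 0.25,
    seed: int = 0,
) -> SyntheticConfig:
    n_g = n_signal if mode in ("gep_only", "redundant", "split") else 0
    n_d = n_signal if mode in ("dmp_only", "redundant", "split") else 0
    e_g = effect if n_g else 0.0
    e_d = effect if n_d else 0.0
    return SyntheticConfig(
        n_samples=n_samples,
        n_features_gep=n_features,
        n_features_dmp=n_features,
        subtypes=[SubtypeSpec("target", prevalence, n_g, n_d, e_g, e_d, mode)],
        seed=seed,
    )


def strategy_comparison(
    mode: str,
    *,
    seed: int = 0,
    strategies: tuple[str, ...] = ("gep", "dmp", "late"),
    n_samples: int = 200,
    n_features: int = 500,
    n_signal: int = 30,
    effect: float = 2.5,
    grid_size: int = 50,
) -> dict:
    """One generated dataset, one DLCV run; per-strategy mean and per-fold
    F/AUC for the planted subtype."""
    cfg = _one_subtype_config(
        mode, n_samples=n_samples, n_features=n_features,
        n_signal=n_signal, effect=effect, seed=seed,
    )
    gep, dmp, labels, _ = generate_dataset(cfg)
    res = run_dlcv(
        tasks_from_labels(labels), gep, dmp, list(strategies),
        seed=seed, grid_size=grid_size, keep_models=False,
    )
    rep = aggregate_report(res)
    out: dict = {"seed": seed, "mode": mode}
    for s in strategies:
        e = rep.entry("target", s)
        out[s] = {
            "mean_auc": e.mean_auc,
            "mean_f": e.mean_f,
            "fold_auc": e.fold_auc,
            "fold_f": e.fold_f,
            "mean_count_gep": e.mean_count_gep,
            "mean_count_dmp": e.mean_count_dmp,
        }
    return out


def synergy_experiment(
    n_repeats: int = 10, master_seed: int = 0, mode: str = "split", **kw
) -> dict:
    """Repeated strategy comparison on one planted subtype.

    For ``mode='split'`` the quantity of interest is how often the late
    two-layer stack beats the better single platform; for ``mode='redundant'``
    it is the paired per-fold AUC difference between late and a single
    platform (which should vanish)."""
    runs = [
        strategy_comparison(mode, seed=master_seed + r, **kw) for r in range(n_repeats)
    ]
    wins = sum(
        1
        for r in runs
        if r["late"]["mean_auc"] > max(r["gep"]["mean_auc"], r["dmp"]["mean_auc"])
    )
    paired_diffs = [
        la - max(g, d)
        for r in runs
        for la, g, d in zip(r["late"]["fold_auc"], r["gep"]["fold_auc"], r["dmp"]["fold_auc"])
        if la is not None and g is not None and d is not None
    ]
    return {
        "runs": runs,
        "n_repeats": n_repeats,
        "late_wins": wins,
        "mean_auc": {
            s: float(np.mean([r[s]["mean_auc"] for r in runs]))
            for s in ("gep", "dmp", "late")
        },
        "mean_f": {
            s: float(np.mean([r[s]["mean_f"] for r in runs]))
            for s in ("gep", "dmp", "late")
        },
        "paired_fold_auc_diff": {
            "mean": float(np.mean(paired_diffs)),
            "se": float(np.std(paired_diffs, ddof=1) / np.sqrt(len(paired_diffs))),
            "n": len(paired_diffs),
        },
    }


def recovery_experiment(
    n_repeats: int = 10,
    master_seed: int = 100,
    *,
    n_samples: int = 200,
    n_features: int = 1000,
    n_signal: int = 50,
    effect: float = 3.0,
    grid_size: int = 50,
) -> dict:
    """Planted-feature recovery of the inner-CV-selected lasso on one
    platform: recall and precision of the selected set against the truth."""
    recalls, precisions = [], []
    for r in range(n_repeats):
        cfg = _one_subtype_config(
            "gep_only", n_samples=n_samples, n_features=n_features,
            n_signal=n_signal, effect=effect, seed=master_seed + r,
        )
        gep, _, labels, truth = generate_dataset(cfg)
        y = labels.y("target")
        path = fit_lambda_path(
            gep.values, y, make_inner_folds(y, 5, master_seed + r), grid_size=grid_size
        )
        sel = set(path.selected_model.nonzero_index.tolist())
        planted = set(truth.planted_gep["target"])
        recalls.append(len(sel & planted) / len(planted))
        precisions.append(len(sel & planted) / max(len(sel), 1))
    return {
        "recalls": recalls,
        "precisions": precisions,
        "median_recall": float(np.median(recalls)),
        "median_precision": float(np.median(precisions)),
    }


def shuffled_label_experiment(
    *,
    seed: int = 0,
    n_samples: int = 100,
    n_features: int = 150,
    grid_size: int = 20,
) -> dict:
    """DLCV on labels permuted independently of the data: validation AUC must
    be indistinguishable from chance."""
    cfg = SyntheticConfig(
        n_samples=n_samples,
        n_features_gep=n_features,
        n_features_dmp=n_features,
        subtypes=[
            SubtypeSpec("s1", 0.30, 10, 0, 2.5, 0.0, "gep_only"),
            SubtypeSpec("s2", 0.25, 10, 10, 2.0, 2.0, "redundant"),
            SubtypeSpec("s3", 0.35, 8, 8, 2.5, 2.5, "split"),
        ],
        seed=seed,
    )
    gep, dmp, labels, _ = generate_dataset(cfg)
    rng = np.random.default_rng(seed + 777)
    perm = rng.permutation(labels.n_samples)
    shuffled = labels.subset_samples(perm)
    shuffled.sample_ids = list(labels.sample_ids)  # detach labels from rows
    res = run_dlcv(
        tasks_from_labels(shuffled), gep, dmp, ["gep"],
        seed=seed, grid_size=grid_size, keep_models=False,
    )
    rep = aggregate_report(res)
    aucs = [
        a
        for e in rep.entries
        for a in e.fold_auc
        if a is not None
    ]
    return {
        "fold_aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "se": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))),
    }


def global_test_calibration(
    n_datasets: int = 200,
    master_seed: int = 0,
    *,
    n_samples: int = 60,
    n_features: int = 40,
    n_permutations: int = 400,
) -> dict:
    """Permutation p-values of the global test on signal-free synthetic data:
    uniform on [0,1] up to the permutation lattice."""
    from .lasso import apply_standardization, fit_standardization

    pvals = []
    for d in range(n_datasets):
        cfg = SyntheticConfig(
            n_samples=n_samples,
            n_features_gep=n_features,
            n_features_dmp=n_features,
            subtypes=[SubtypeSpec("null", 0.30, 0, 0, 0.0, 0.0, "redundant")],
            seed=master_seed + d,
        )
        gep, _, labels, _ = generate_dataset(cfg)
        y = labels.y("null")
        Xs = apply_standardization(gep.values, fit_standardization(gep.values))
        res = global_test(Xs, y, n_permutations=n_permutations, seed=master_seed + d)
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    return {
        "p_values": pvals.tolist(),
        "type_i_at_05": float(np.mean(pvals <= 0.05)),
        "n_datasets": n_datasets,
    }
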