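"""Synthetic paired-omics generator with planted, per-platform subtype signal.

Emulates the structure of a sample-matched expression/methylation cohort with
partially overlapping subtype labels: Gaussian background on both platforms
and, per subtype, an additive mean shift on a disjoint set of planted feature
columns.  The placement mode controls where the discriminative signal lives:

* ``gep_only`` / ``dmp_only`` — all planted features on one platform;
* ``redundant`` — the same positives shifted on both platforms;
* ``split`` — positives partitioned ~50/50, each carrying signal on exactly
  one platform (the configuration in which late integration has something to
  gain over either platform alone).

All randomness flows from one integer seed through a documented
``SeedSequence`` stream split, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .datatypes import LabelMatrix, OmicsMatrix

__all__ = [
    "SubtypeSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_subtypes",
    "generate_dataset",
]

MODES = ("gep_only", "dmp_only", "redundant", "split")

# feasibility floor: every outer fold of the default 5-fold protocol should be
# able to contain positives, so expected positives must reach 2 x 5
_MIN_EXPECTED_POSITIVES = 10


class ConfigurationError(ValueError):
    pass


@dataclass
class SubtypeSpec:
    """One subtype's prevalence, planted-feature counts and effect sizes.

    Effects are mean shifts in background-SD units applied to the planted
    columns of positive samples.
    """

    name: str
    prevalence: float
    n_signal_gep: int = 0
    n_signal_dmp: int = 0
    effect_gep: float = 0.0
    effect_dmp: float = 0.0
    mode: str = "redundant"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError(
                f"subtype {self.name!r}: prevalence must be in (0,1)"
            )
        if self.mode not in MODES:
            raise ConfigurationError(
                f"subtype {self.name!r}: mode must be one of {MODES}"
            )
        if min(self.n_signal_gep, self.n_signal_dmp) < 0:
            raise ConfigurationError(f"subtype {self.name!r}: negative feature count")
        if min(self.effect_gep, self.effect_dmp) < 0:
            raise ConfigurationError(f"subtype {self.name!r}: negative effect size")
        if self.mode == "gep_only" and self.n_signal_dmp != 0:
            raise ConfigurationError(
                f"subtype {self.name!r}: gep_only mode forbids DMP signal features"
            )
        if self.mode == "dmp_only" and self.n_signal_gep != 0:
            raise ConfigurationError(
                f"subtype {self.name!r}: dmp_only mode forbids GEP signal features"
            )
        if self.mode == "split" and (self.n_signal_gep == 0 or self.n_signal_dmp == 0):
            raise ConfigurationError(
                f"subtype {self.name!r}: split mode needs signal on both platforms"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def default_subtypes() -> list[SubtypeSpec]:
    """Six subtypes spanning the signal-placement modes the pipeline must
    distinguish, at effect sizes where lasso recovery is hard but possible."""
    return [
        SubtypeSpec("gep_strong", 0.20, 40, 0, 2.5, 0.0, "gep_only"),
        SubtypeSpec("dmp_strong", 0.20, 0, 40, 0.0, 2.5, "dmp_only"),
        SubtypeSpec("both_redundant", 0.15, 30, 30, 2.0, 2.0, "redundant"),
        SubtypeSpec("split_signal", 0.25, 30, 30, 2.5, 2.5, "split"),
        SubtypeSpec("gep_weak", 0.15, 30, 0, 1.0, 0.0, "gep_only"),
        SubtypeSpec("no_signal", 0.15, 0, 0, 0.0, 0.0, "redundant"),
    ]


@dataclass
class SyntheticConfig:
    """Shape and signal structure of one generated dataset.

    Defaults mirror a reduced-scale paired cohort: 200 samples, 2000 features
    per platform, 6 partially overlapping subtypes on a unit-SD Gaussian
    background.
    """

    n_samples: int = 200
    n_features_gep: int = 2000
    n_features_dmp: int = 2000
    subtypes: list[SubtypeSpec] = field(default_factory=default_subtypes)
    overlap_matrix: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        names = [s.name for s in self.subtypes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate subtype names")
        for s in self.subtypes:
            expected = s.prevalence * self.n_samples
            if expected < _MIN_EXPECTED_POSITIVES:
                raise ConfigurationError(
                    f"subtype {s.name!r}: expected positives "
                    f"{expected:.1f} < {_MIN_EXPECTED_POSITIVES}; prevalence too low "
                    f"for every outer fold to contain positives"
                )
            if (1 - s.prevalence) * self.n_samples < _MIN_EXPECTED_POSITIVES:
                raise ConfigurationError(
                    f"subtype {s.name!r}: prevalence too high, almost no negatives"
                )
        if sum(s.n_signal_gep for s in self.subtypes) > self.n_features_gep:
            raise ConfigurationError("planted GEP features exceed n_features_gep")
        if sum(s.n_signal_dmp for s in self.subtypes) > self.n_features_dmp:
            raise ConfigurationError("planted DMP features exceed n_features_dmp")
        if self.overlap_matrix is not None:
            M = np.asarray(self.overlap_matrix, dtype=float)
            k = len(self.subtypes)
            if M.shape != (k, k) or not np.allclose(M, M.T) or not np.allclose(np.diag(M), 1.0):
                raise ConfigurationError(
                    "overlap_matrix must be a symmetric correlation matrix with unit diagonal"
                )
            self.overlap_matrix = M

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_features_gep": self.n_features_gep,
            "n_features_dmp": self.n_features_dmp,
            "subtypes": [s.to_dict() for s in self.subtypes],
            "overlap_matrix": (
                None if self.overlap_matrix is None else np.asarray(self.overlap_matrix).tolist()
            ),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "subtypes" in d and d["subtypes"] is not None:
            d["subtypes"] = [
                s if isinstance(s, SubtypeSpec) else SubtypeSpec(**s) for s in d["subtypes"]
            ]
        else:
            d.pop("subtypes", None)
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted feature indices per subtype and, for split-mode subtypes, the
    per-positive-sample platform assignment."""

    planted_gep: dict[str, list[int]]
    planted_dmp: dict[str, list[int]]
    split_assignment: dict[str, dict[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_gep": self.planted_gep,
                "planted_dmp": self.planted_dmp,
                "split_assignment": self.split_assignment,
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(d["planted_gep"], d["planted_dmp"], d["split_assignment"])


def _draw_labels(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample subtype membership: independent Bernoulli draws at the
    stated prevalences, or a Gaussian copula thresholded at the prevalence
    quantiles when an overlap (latent correlation) matrix is given."""
    n = config.n_samples
    k = len(config.subtypes)
    prev = np.array([s.prevalence for s in config.subtypes])
    if config.overlap_matrix is None:
        return (rng.random((n, k)) < prev).astype(np.int8)
    M = np.asarray(config.overlap_matrix)
    # jitter keeps marginally-PSD inputs factorizable
    L = np.linalg.cholesky(M + 1e-10 * np.eye(k))
    z = rng.standard_normal((n, k)) @ L.T
    thresholds = norm.ppf(1.0 - prev)
    return (z > thresholds).astype(np.int8)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, LabelMatrix, SyntheticTruth]:
    """Generate the paired matrices, the multi-label membership matrix and the
    ground truth of planted signal.

    Stream split: ``SeedSequence(seed)`` spawns four child streams, in order:
    labels, GEP background, DMP background, signal placement (planted column
    choice and split-mode platform assignment).  Same seed, same output,
    bit for bit.
    """
    ss = np.random.SeedSequence(config.seed)
    s_labels, s_gep, s_dmp, s_plant = [np.random.default_rng(c) for c in ss.spawn(4)]

    n = config.n_samples
    labels = _draw_labels(config, s_labels)
    for j, spec in enumerate(config.subtypes):
        n_pos = int(labels[:, j].sum())
        if n_pos == 0 or n_pos == n:
            raise ConfigurationError(
                f"subtype {spec.name!r}: drawn membership has "
                f"{n_pos} positives of {n} samples; no classifier can be trained"
            )

    gep = s_gep.normal(0.0, config.noise_sd, size=(n, config.n_features_gep))
    dmp = s_dmp.normal(0.0, config.noise_sd, size=(n, config.n_features_dmp))

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gep_ids = [f"G{j:05d}" for j in range(config.n_features_gep)]
    dmp_ids = [f"M{j:05d}" for j in range(config.n_features_dmp)]

    pool_gep = list(s_plant.permutation(config.n_features_gep))
    pool_dmp = list(s_plant.permutation(config.n_features_dmp))
    planted_gep: dict[str, list[int]] = {}
    planted_dmp: dict[str, list[int]] = {}
    split_assignment: dict[str, dict[str, str]] = {}

    for j, spec in enumerate(config.subtypes):
        idx_g = sorted(int(pool_gep.pop()) for _ in range(spec.n_signal_gep))
        idx_d = sorted(int(pool_dmp.pop()) for _ in range(spec.n_signal_dmp))
        planted_gep[spec.name] = idx_g
        planted_dmp[spec.name] = idx_d
        pos = np.flatnonzero(labels[:, j] == 1)
        shift_g = spec.effect_gep * config.noise_sd
        shift_d = spec.effect_dmp * config.noise_sd
        if spec.mode == "split":
            carriers = s_plant.permutation(pos)
            half = len(carriers) // 2
            on_gep, on_dmp = carriers[:half], carriers[half:]
            split_assignment[spec.name] = {
                **{sample_ids[i]: "gep" for i in sorted(on_gep)},
                **{sample_ids[i]: "dmp" for i in sorted(on_dmp)},
            }
            if idx_g:
                gep[np.ix_(on_gep, idx_g)] += shift_g
            if idx_d:
                dmp[np.ix_(on_dmp, idx_d)] += shift_d
        else:
            if idx_g and shift_g:
                gep[np.ix_(pos, idx_g)] += shift_g
            if idx_d and shift_d:
                dmp[np.ix_(pos, idx_d)] += shift_d

    truth = SyntheticTruth(planted_gep, planted_dmp, split_assignment)
    return (
        OmicsMatrix(gep, sample_ids, gep_ids, "GEP"),
        OmicsMatrix(dmp, sample_ids, dmp_ids, "DMP"),
        LabelMatrix(labels, sample_ids, [s.name for s in config.subtypes]),
        truth,
    )
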