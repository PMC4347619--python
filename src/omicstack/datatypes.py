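"""Core in-memory containers: per-platform feature matrices and multi-label subtype matrices.

Both containers are thin, validated wrappers around a dense ``numpy`` array plus
row/column identifiers, convertible to and from :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "LabelMatrix"]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """One platform's samples x features real-valued matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_features)``; coerced to float64.
    sample_ids, feature_ids
        Row and column identifiers; must be unique.
    platform
        Free-text platform tag, e.g. ``"GEP"`` or ``"DMP"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: np.ndarray) -> "OmicsMatrix":
        """Row subset by positional index, preserving order of ``index``."""
        index = np.asarray(index)
        return OmicsMatrix(
            self.values[index],
            [self.sample_ids[i] for i in index],
            self.feature_ids,
            self.platform,
        )

    def align_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Reorder rows to ``sample_ids``; every requested id must be present."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not present in {self.platform or 'matrix'}: {missing}")
        return self.subset_samples(np.array([pos[s] for s in sample_ids], dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, platform: str = "") -> "OmicsMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.index), list(df.columns), platform)


@dataclass
class LabelMatrix:
    """Samples x subtypes binary membership matrix (multi-label).

    A sample may carry several subtypes, or none at all.
    """

    values: np.ndarray
    sample_ids: list[str]
    subtypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x subtypes)")
        if not np.isin(self.values, (0, 1)).all():
            bad = sorted(set(np.unique(self.values)) - {0, 1})
            raise ValueError(f"label values outside {{0,1}}: {bad}")
        self.values = self.values.astype(np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.subtypes = [str(s) for s in self.subtypes]
        n, s = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.subtypes) != s:
            raise ValueError(f"{len(self.subtypes)} subtype names for {s} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.subtypes, "subtype")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def y(self, subtype: str) -> np.ndarray:
        """Binary one-vs-all response vector for one subtype."""
        try:
            j = self.subtypes.index(subtype)
        except ValueError:
            raise KeyError(f"unknown subtype: {subtype!r}") from None
        return self.values[:, j].astype(np.float64)

    def subset_samples(self, index: np.ndarray) -> "LabelMatrix":
        index = np.asarray(index)
        return LabelMatrix(
            self.values[index], [self.sample_ids[i] for i in index], self.subtypes
        )

    def align_samples(self, sample_ids: list[str]) -> "LabelMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not present in label matrix: {missing}")
        return self.subset_samples(np.array([pos[s] for s in sample_ids], dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.subtypes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))
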