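"""Tab-separated text I/O for feature matrices, label matrices and fold files.

File layout: first row holds feature (or subtype) identifiers, first column
holds sample identifiers, cells are tab-separated.  Floats are written with
Python's shortest round-trip representation, so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import LabelMatrix, OmicsMatrix
from .synth import SyntheticTruth

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_truth",
    "read_truth",
    "align_by_sample_ids",
]


def _read_table(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    row_ids: list[str] = []
    cells: list[list[str]] = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}:{ln}: expected {len(header)} fields, found {len(parts)}"
            )
        row_ids.append(parts[0])
        cells.append(parts[1:])
    return col_ids, row_ids, cells


def _check_dupes(ids: list[str], what: str, path: Path) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"{path}: duplicate {what} id {i!r}")
        seen.add(i)


def read_matrix(path: str | Path, platform: str = "") -> OmicsMatrix:
    """Read a samples x features TSV into an :class:`OmicsMatrix`.

    Ragged rows, duplicate identifiers and non-numeric cells raise with the
    offending line number.
    """
    path = Path(path)
    col_ids, row_ids, cells = _read_table(path)
    _check_dupes(row_ids, "sample", path)
    _check_dupes(col_ids, "feature", path)
    values = np.empty((len(row_ids), len(col_ids)), dtype=np.float64)
    for i, row in enumerate(cells):
        try:
            values[i] = [float(c) for c in row]
        except ValueError:
            bad = next(c for c in row if not _is_float(c))
            raise ValueError(
                f"{path}:{i + 2}: non-numeric cell {bad!r}"
            ) from None
    return OmicsMatrix(values, row_ids, col_ids, platform)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(matrix.feature_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path: str | Path) -> LabelMatrix:
    """Read a samples x subtypes binary TSV; cells must be 0 or 1."""
    path = Path(path)
    col_ids, row_ids, cells = _read_table(path)
    _check_dupes(row_ids, "sample", path)
    _check_dupes(col_ids, "subtype", path)
    values = np.empty((len(row_ids), len(col_ids)), dtype=np.int8)
    for i, row in enumerate(cells):
        for j, c in enumerate(row):
            if c not in ("0", "1"):
                raise ValueError(f"{path}:{i + 2}: label cell {c!r} not in {{0,1}}")
            values[i, j] = int(c)
    return LabelMatrix(values, row_ids, col_ids)


def write_labels(labels: LabelMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(labels.subtypes) + "\n")
        for sid, row in zip(labels.sample_ids, labels.values):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def align_by_sample_ids(
    gep: OmicsMatrix,
    dmp: OmicsMatrix,
    labels: LabelMatrix,
    *,
    allow_subset: bool = False,
) -> tuple[OmicsMatrix, OmicsMatrix, LabelMatrix]:
    """Align the three inputs to a common sample order (the GEP order).

    By default every input must contain exactly the same samples (the study
    design is sample-matched); with ``allow_subset`` the intersection is used
    instead.
    """
    sets = [set(gep.sample_ids), set(dmp.sample_ids), set(labels.sample_ids)]
    common = sets[0] & sets[1] & sets[2]
    union = sets[0] | sets[1] | sets[2]
    if not common:
        raise ValueError("no samples shared between the three inputs")
    if common != union and not allow_subset:
        missing = sorted(union - common)
        raise ValueError(
            f"inputs are not sample-matched; {len(missing)} samples absent from at "
            f"least one input (first few: {missing[:5]}); pass allow_subset to use "
            f"the intersection"
        )
    order = [s for s in gep.sample_ids if s in common]
    return gep.align_samples(order), dmp.align_samples(order), labels.align_samples(order)
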