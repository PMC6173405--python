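"""Reading, validation and alignment of genomic feature matrices and drug-response tables.

Feature matrices are delimited text (TSV or CSV) with one axis of sample IDs and
one of feature IDs.  Three kinds of features are understood: continuous gene
``expression``, binary ``mutation`` status (strictly 0/1) and continuous copy
number variation (``cnv``).  A response table holds one continuous drug-response
value (activity area) per sample per drug, with blank/NA cells marking missing
responses.

``assemble_dataset`` intersects sample IDs across all sources, drops samples
without a response for the requested drug and concatenates the feature blocks
with kind prefixes (``expr:``, ``mut:``, ``cnv:``) so a gene measured on several
platforms keeps distinct feature IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureKind",
    "FeatureMatrix",
    "ResponseTable",
    "Dataset",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_response_table",
    "assemble_dataset",
]


class FeatureKind(str, Enum):
    expression = "expression"
    mutation = "mutation"
    cnv = "cnv"


#: feature-ID prefix per kind, used when blocks are concatenated
KIND_PREFIX = {
    FeatureKind.expression: "expr",
    FeatureKind.mutation: "mut",
    FeatureKind.cnv: "cnv",
}


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class FeatureMatrix:
    """A validated samples x features block of one feature kind."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: FeatureKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.kind = FeatureKind(self.kind)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample IDs x {len(self.feature_ids)} feature IDs"
            )
        for axis, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {axis} IDs: {dups}")
        if self.kind is FeatureKind.mutation:
            finite = self.values[np.isfinite(self.values)]
            bad = ~np.isin(finite, (0.0, 1.0))
            if bad.any():
                rows, cols = np.nonzero(
                    np.isfinite(self.values) & ~np.isin(self.values, (0.0, 1.0))
                )
                cells = [
                    f"({self.sample_ids[r]}, {self.feature_ids[c]})={self.values[r, c]:g}"
                    for r, c in list(zip(rows, cols))[:10]
                ]
                raise ValueError(
                    "mutation matrix must contain only 0/1 values; offending cells: "
                    + ", ".join(cells)
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class ResponseTable:
    """Drug responses (activity area), samples x drugs, NaN marking missing cells."""

    values: np.ndarray
    sample_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.drug_ids = [str(d) for d in self.drug_ids]
        if self.values.shape != (len(self.sample_ids), len(self.drug_ids)):
            raise ValueError("response table shape does not match ID lists")
        for axis, ids in (("sample", self.sample_ids), ("drug", self.drug_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {axis} IDs: {dups}")
        if np.isinf(self.values).any():
            raise ValueError("response table contains non-finite (inf) values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.drug_ids)

    def response(self, drug_id: str) -> pd.Series:
        if drug_id not in self.drug_ids:
            raise KeyError(f"drug {drug_id!r} not present; available: {self.drug_ids}")
        return self.to_frame()[drug_id]


@dataclass
class Dataset:
    """Aligned feature matrix X (n x M) and response vector y for one drug."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("X shape does not match ID lists")
        if self.n < 2:
            raise ValueError("a dataset needs at least 2 samples")
        if self.M < 1:
            raise ValueError("a dataset needs at least 1 feature")
        for axis, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {axis} IDs: {dups}")
        if not np.isfinite(self.X).all():
            r, c = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(
                f"X contains missing/non-finite values, e.g. at "
                f"({self.sample_ids[r]}, {self.feature_ids[c]})"
            )
        if not np.isfinite(self.y).all():
            raise ValueError("y contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.X.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "Dataset":
        """Restrict to the given features, in the given order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing[:5]}")
        idx = [pos[f] for f in feature_ids]
        return Dataset(self.X[:, idx], self.y, self.sample_ids, list(feature_ids))


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table with row/column ID headers, cells as strings."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else None
    df = pd.read_csv(
        path, sep=sep, engine="python", index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


_NA_STRINGS = {"", "na", "nan", "n/a", "null", "."}


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert string cells to floats, NA strings to NaN, erroring with the location."""
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        isna = raw.str.strip().str.lower().isin(_NA_STRINGS)
        num = pd.to_numeric(raw.where(~isna), errors="coerce")
        bad = num.isna() & ~isna
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw[row]!r}"
            )
        out[col] = num
    return out


def read_feature_matrix(
    path: str | Path,
    kind: FeatureKind | str,
    orientation: str = "samples_in_columns",
) -> FeatureMatrix:
    """Read a TSV/CSV feature matrix and return it in samples x features orientation.

    ``orientation`` declares how the file on disk is laid out; genomics matrices
    are conventionally genes x samples, hence the ``samples_in_columns`` default.
    """
    if orientation not in {"samples_in_columns", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _coerce_numeric(_read_table(path), path)
    if orientation == "samples_in_columns":
        df = df.T
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
        kind=FeatureKind(kind),
    )


def write_feature_matrix(
    matrix: FeatureMatrix,
    path: str | Path,
    orientation: str = "samples_in_columns",
) -> None:
    df = matrix.to_frame()
    if orientation == "samples_in_columns":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


def read_response_table(path: str | Path, orientation: str = "samples_in_rows") -> ResponseTable:
    """Read a response table; default layout is samples in rows, drugs in columns."""
    if orientation not in {"samples_in_columns", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _coerce_numeric(_read_table(path), path)
    if orientation == "samples_in_columns":
        df = df.T
    return ResponseTable(
        values=df.to_numpy(dtype=float),
        sample_ids=list(df.index),
        drug_ids=list(df.columns),
    )


def assemble_dataset(
    matrices: Iterable[FeatureMatrix],
    responses: ResponseTable,
    drug_id: str,
) -> Dataset:
    """Align feature blocks and the response column for one drug into a Dataset.

    Sample IDs are intersected across every block and the non-missing responses
    for ``drug_id``; the retained samples are ordered lexicographically so the
    result does not depend on input ordering.  Feature IDs are prefixed by kind.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one feature matrix")
    y_all = responses.response(drug_id)
    common = set(y_all.index[y_all.notna()])
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError(
            f"empty sample intersection between feature matrices and responses "
            f"for drug {drug_id!r}"
        )
    samples = sorted(common)
    if len(samples) < 20:
        logger.warning(
            "only %d samples retained after alignment for drug %s", len(samples), drug_id
        )

    blocks: list[pd.DataFrame] = []
    for m in matrices:
        df = m.to_frame().loc[samples]
        df.columns = [f"{KIND_PREFIX[m.kind]}:{f}" for f in df.columns]
        blocks.append(df)
    X = pd.concat(blocks, axis=1)
    dups = _find_duplicates(list(X.columns))
    if dups:
        raise ValueError(f"duplicate prefixed feature IDs across blocks: {dups[:10]}")
    return Dataset(
        X=X.to_numpy(dtype=float),
        y=y_all.loc[samples].to_numpy(dtype=float),
        sample_ids=samples,
        feature_ids=list(X.columns),
    )
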