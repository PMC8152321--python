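"""Data model and delimited-text I/O for multi-omics matrices and labels.

One drug's data is three co-indexed sample-by-feature matrices — gene
expression (continuous), somatic mutation (binary), copy-number aberration
(continuous or binary) — plus a binary response vector (1 = sensitive,
0 = resistant) and, optionally, a continuous ln(IC50) table.

Tables are exchanged as TSV (comma selectable): first column sample IDs,
header row feature IDs, rows = samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    OmicsFormatError,
    OmicsParseError,
    OmicsValidationError,
)

OMICS_KINDS = ("expression", "mutation", "cna")

_LABEL_ALIASES = {
    "1": 1, "s": 1, "sensitive": 1,
    "0": 0, "r": 0, "resistant": 0,
}


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        counts = Counter(ids)
        dup = sorted(i for i, c in counts.items() if c > 1)
        raise OmicsFormatError(f"duplicate {what} IDs: {dup[:5]}")
    return ids


@dataclass
class OmicsMatrix:
    """A samples x features numeric matrix for one omics layer."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise OmicsValidationError(f"unknown omics kind {self.kind!r}")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise OmicsFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise OmicsParseError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}"
            )
        if self.kind == "mutation" and not np.isin(self.values, (0.0, 1.0)).all():
            r, c = np.argwhere(~np.isin(self.values, (0.0, 1.0)))[0]
            raise OmicsValidationError(
                f"mutation value outside {{0,1}} at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(list(sample_ids), list(self.feature_ids), self.values[idx], self.kind)

    def take_samples(self, idx: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(
            [self.sample_ids[i] for i in idx], list(self.feature_ids),
            self.values[np.asarray(idx)], self.kind,
        )


@dataclass
class LabelVector:
    """Binary drug-response labels; 1 = sensitive, 0 = resistant."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise OmicsFormatError("label vector length does not match sample IDs")
        if not np.isin(self.labels, (0, 1)).all():
            raise OmicsValidationError("labels must be in {0, 1}")

    def subset(self, sample_ids: list[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return LabelVector(list(sample_ids), self.labels[[pos[s] for s in sample_ids]])

    def take(self, idx: np.ndarray) -> "LabelVector":
        idx = np.asarray(idx)
        return LabelVector([self.sample_ids[i] for i in idx], self.labels[idx])


@dataclass
class IC50Table:
    """Per-sample natural-log IC50 values."""

    sample_ids: list[str]
    ln_ic50: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.ln_ic50 = np.asarray(self.ln_ic50, dtype=float)
        if self.ln_ic50.shape != (len(self.sample_ids),):
            raise OmicsFormatError("ln(IC50) vector length does not match sample IDs")
        if not np.all(np.isfinite(self.ln_ic50)):
            raise OmicsParseError("non-finite ln(IC50) value")


@dataclass
class MultiOmicsDataset:
    """Co-indexed expression/mutation/CNA matrices plus labels for one drug."""

    expression: OmicsMatrix
    mutation: OmicsMatrix
    cna: OmicsMatrix
    labels: LabelVector
    drug_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.labels.sample_ids
        for layer in (self.expression, self.mutation, self.cna):
            if layer.sample_ids != ids:
                raise AlignmentError(
                    f"{layer.kind} sample order differs from labels; run align_samples first"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels.sample_ids)

    def layer(self, kind: str) -> OmicsMatrix:
        return {"expression": self.expression, "mutation": self.mutation, "cna": self.cna}[kind]

    def take(self, idx: np.ndarray) -> "MultiOmicsDataset":
        """Row-subset every component by positional indices (order kept)."""
        idx = np.asarray(idx)
        return MultiOmicsDataset(
            self.expression.take_samples(idx),
            self.mutation.take_samples(idx),
            self.cna.take_samples(idx),
            self.labels.take(idx),
            self.drug_name,
            dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# I/O


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise OmicsFormatError(f"cannot parse table {path}: {exc}") from exc
    return df


def read_omics_matrix(
    path: str | Path,
    kind: str,
    sep: str = "\t",
    transpose: bool = False,
    fill_missing: float | None = None,
) -> OmicsMatrix:
    """Load a delimited sample-by-feature table as an :class:`OmicsMatrix`.

    ``transpose=True`` accepts gene-by-sample layouts. Missing values are
    rejected unless ``fill_missing`` is given (intended for the mutation
    layer, where absent genes mean "no mutation observed").
    """
    df = _read_table(path, sep)
    if transpose:
        df = df.T
    if df.isna().any().any():
        if fill_missing is None:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise OmicsParseError(
                f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r} in {path}"
            )
        df = df.fillna(fill_missing)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise OmicsParseError(
            f"non-numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r} in {path}"
        )
    return OmicsMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), vals, kind)


def write_omics_matrix(m: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_labels(path: str | Path, sep: str = "\t") -> LabelVector:
    """Read a two-column (sample_id, response) table; accepts R/S,
    resistant/sensitive, or 0/1 responses, case-insensitive."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise OmicsFormatError(f"label table {path} needs two columns (sample_id, response)")
    raw = df.iloc[:, 1].astype(str).str.strip().str.lower()
    unknown = sorted(set(raw) - set(_LABEL_ALIASES))
    if unknown:
        raise OmicsValidationError(f"unrecognized response values {unknown} in {path}")
    return LabelVector(list(df.iloc[:, 0].astype(str)), raw.map(_LABEL_ALIASES).to_numpy())


def write_labels(labels: LabelVector, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "response": np.where(labels.labels == 1, "S", "R")}
    ).to_csv(path, sep=sep, index=False)


def read_ic50(path: str | Path, sep: str = "\t", natural_log: bool = True) -> IC50Table:
    """Read a two-column (sample_id, ln_ic50) table.

    With ``natural_log=False`` the second column holds raw IC50 values and
    the natural log is applied on load.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise OmicsFormatError(f"IC50 table {path} needs two columns")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise OmicsParseError(f"non-numeric IC50 value in {path}")
    if not natural_log:
        if (vals <= 0).any():
            raise OmicsValidationError("raw IC50 values must be positive to take the log")
        vals = np.log(vals)
    return IC50Table(list(df.iloc[:, 0].astype(str)), vals)


def write_ic50(table: IC50Table, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"sample_id": table.sample_ids, "ln_ic50": table.ln_ic50}).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Alignment


def align_samples(
    expression: OmicsMatrix,
    mutation: OmicsMatrix,
    cna: OmicsMatrix,
    labels: LabelVector,
    drug_name: str = "",
) -> MultiOmicsDataset:
    """Restrict all layers to the common samples, in lexicographic order.

    The canonical sort makes downstream fold assignment independent of the
    row order of the input files. IDs dropped from each layer are recorded
    in the result's ``metadata["dropped"]``.
    """
    sets: Mapping[str, set[str]] = {
        "expression": set(expression.sample_ids),
        "mutation": set(mutation.sample_ids),
        "cna": set(cna.sample_ids),
        "labels": set(labels.sample_ids),
    }
    common = set.intersection(*sets.values())
    if not common:
        raise AlignmentError("no samples shared by all omics layers and labels")
    order = sorted(common)
    dropped = {name: sorted(s - common) for name, s in sets.items()}
    return MultiOmicsDataset(
        expression.subset_samples(order),
        mutation.subset_samples(order),
        cna.subset_samples(order),
        labels.subset(order),
        drug_name,
        {"dropped": dropped},
    )
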