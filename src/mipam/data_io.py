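"""Core containers and CSV/TSV input-output for spectral matrices.

A spectral dataset is a subjects x wavenumbers absorbance matrix; each
wavenumber (cm^-1) is treated as one continuous random variable.  Pairwise
association structure between wavenumbers is carried by
:class:`PairwiseMatrix`, whose ``kind`` records which scale the entries live
on (raw mutual information in nats, normalized MI in [0, 1), or a
dissimilarity in [0, 1] with a null diagonal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DataError",
    "LabelError",
    "MatrixKind",
    "SpectralDataset",
    "PairwiseMatrix",
    "read_spectra",
    "write_spectra",
    "read_matrix",
    "write_matrix",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed as a spectral table or matrix."""


class DataError(ValueError):
    """Raised when parsed values violate a dataset or matrix invariant."""


class LabelError(ValueError):
    """Raised when the group-label column is missing or not binary."""


class MatrixKind(str, enum.Enum):
    """Scale of the entries of a :class:`PairwiseMatrix`."""

    MI = "mi"
    NORMALIZED_MI = "normalized_mi"
    DISSIMILARITY = "dissimilarity"
    PEARSON_DISSIMILARITY = "pearson_dissimilarity"


_SYMMETRY_TOL = 1e-12


@dataclass
class SpectralDataset:
    """Subjects x wavenumbers intensity matrix with optional binary labels.

    Parameters
    ----------
    intensities
        Real ``(n, p)`` array of absorbance values, rows are subjects.
    wavenumbers
        Strictly monotone array of ``p`` wavenumbers in cm^-1, in stored
        column order (ascending or descending).
    subject_ids
        ``n`` subject identifiers.
    labels
        Optional length-``n`` sequence with exactly two distinct group
        codes (e.g. ``"MS"`` / ``"HC"``).
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.intensities.ndim != 2:
            raise DataError("intensities must be a 2-D subjects x wavenumbers array")
        n, p = self.intensities.shape
        if p < 2 or n < 3:
            raise DataError(f"need at least 3 subjects and 2 wavenumbers, got n={n}, p={p}")
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("intensities contain missing or non-finite values")
        if self.wavenumbers.shape != (p,):
            raise DataError("wavenumbers length must match the number of columns")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise DataError("wavenumbers must be finite")
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataError("wavenumbers must be strictly monotone")
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != n:
            raise DataError("subject_ids length must match the number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise LabelError("labels length must match the number of subjects")
            if len(set(self.labels.tolist())) != 2:
                raise LabelError("labels must contain exactly two distinct group codes")

    @property
    def n_subjects(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    def classes(self) -> list:
        if self.labels is None:
            raise LabelError("dataset has no group labels")
        return sorted(set(self.labels.tolist()))

    def binary_labels(self, positive=None) -> tuple[np.ndarray, object]:
        """Encode labels as 0/1 with the case class mapped to 1.

        Unless ``positive`` is given, the lexicographically larger code is
        taken as the positive (case) class, so ``"MS" > "HC"`` maps MS
        patients to 1.
        """
        lo, hi = self.classes()
        if positive is None:
            positive = hi
        elif positive not in (lo, hi):
            raise LabelError(f"positive class {positive!r} not among label codes {lo!r}, {hi!r}")
        y = np.asarray([1 if v == positive else 0 for v in self.labels], dtype=int)
        return y, positive

    def select_wavenumbers(self, indices: Sequence[int]) -> "SpectralDataset":
        """Restrict to a subset of columns (e.g. the cluster medoids)."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            intensities=self.intensities[:, idx],
            wavenumbers=self.wavenumbers[idx],
        )


@dataclass
class PairwiseMatrix:
    """Symmetric p x p association matrix between wavenumbers."""

    values: np.ndarray
    kind: MatrixKind
    labels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.kind = MatrixKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError("pairwise matrix must be square")
        p = self.values.shape[0]
        if self.labels is None:
            self.labels = np.arange(p, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.shape != (p,):
            raise DataError("labels length must match the matrix dimension")
        if not np.all(np.isfinite(self.values)):
            raise DataError("pairwise matrix contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > _SYMMETRY_TOL:
            raise DataError("pairwise matrix is not symmetric within 1e-12")
        off = ~np.eye(p, dtype=bool)
        if self.kind is MatrixKind.MI:
            if np.any(self.values[off] < 0):
                raise DataError("MI matrix has negative off-diagonal entries")
        elif self.kind is MatrixKind.NORMALIZED_MI:
            if np.any(self.values[off] < 0) or np.any(self.values[off] >= 1):
                raise DataError("normalized-MI entries must lie in [0, 1)")
        else:  # dissimilarity kinds
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise DataError("dissimilarity entries must lie in [0, 1]")
            if np.any(np.diag(self.values) != 0):
                raise DataError("dissimilarity diagonal must be exactly 0")

    @property
    def p(self) -> int:
        return self.values.shape[0]


def _parse_wavenumber_headers(names: Sequence[str]) -> np.ndarray:
    out = []
    for name in names:
        try:
            out.append(float(str(name).strip()))
        except ValueError:
            raise FormatError(f"column header {name!r} is not parseable as a wavenumber")
    return np.asarray(out, dtype=float)


def read_spectra(
    path,
    label_column: str | None = None,
    id_column: str | None = None,
    transpose: bool = False,
    delimiter: str | None = None,
) -> SpectralDataset:
    """Read a subjects x wavenumbers CSV/TSV table.

    The header row carries the wavenumbers; ``id_column`` and
    ``label_column`` name optional metadata columns.  ``delimiter=None``
    sniffs "," vs tab.  With ``transpose=True`` the file stores wavenumbers
    as rows (first column) and subjects as columns; metadata columns are not
    supported in that layout.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python", index_col=0 if transpose else None)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from None
    if transpose:
        if label_column or id_column:
            raise LabelError("label/id columns are not supported with transpose=True")
        wavenumbers = _parse_wavenumber_headers(df.index)
        values = df.to_numpy(dtype=float).T
        subject_ids = [str(c) for c in df.columns]
        labels = None
    else:
        labels = None
        if label_column is not None:
            if label_column not in df.columns:
                raise LabelError(f"label column {label_column!r} not found")
            labels = df.pop(label_column).to_numpy()
        if id_column is not None:
            if id_column not in df.columns:
                raise FormatError(f"id column {id_column!r} not found")
            subject_ids = [str(v) for v in df.pop(id_column)]
        else:
            subject_ids = [f"S{i + 1:03d}" for i in range(len(df))]
        wavenumbers = _parse_wavenumber_headers(df.columns)
        if df.isna().to_numpy().any():
            raise DataError(f"{path} contains missing values")
        values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError(f"{path} contains missing values")
    return SpectralDataset(values, wavenumbers, subject_ids, labels)


def write_spectra(ds: SpectralDataset, path, delimiter: str = ",") -> None:
    """Write a dataset so that :func:`read_spectra` round-trips it exactly."""
    df = pd.DataFrame(ds.intensities, columns=[repr(float(w)) for w in ds.wavenumbers])
    df.insert(0, "subject_id", ds.subject_ids)
    if ds.labels is not None:
        df.insert(1, "group", ds.labels)
    df.to_csv(path, sep=delimiter, index=False)


def write_matrix(m: PairwiseMatrix, path) -> None:
    """Write a pairwise matrix as labelled CSV with the kind in a header comment."""
    lab = [repr(float(w)) for w in m.labels]
    df = pd.DataFrame(m.values, index=lab, columns=lab)
    with open(path, "w") as fh:
        fh.write(f"# kind: {m.kind.value}\n")
        df.to_csv(fh)


def read_matrix(path) -> PairwiseMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# kind:"):
        raise FormatError(f"{path} lacks the '# kind:' header comment")
    try:
        kind = MatrixKind(first.split(":", 1)[1].strip())
    except ValueError:
        raise FormatError(f"unknown matrix kind in {path}: {first!r}")
    df = pd.read_csv(path, skiprows=1, index_col=0)
    labels = _parse_wavenumber_headers(df.columns)
    return PairwiseMatrix(df.to_numpy(dtype=float), kind, labels)
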