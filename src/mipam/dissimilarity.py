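"""Normalized-MI similarity and the dissimilarities fed to PAM.

Raw MI is unbounded, so it is first mapped onto [0, 1) by the strictly
increasing transform

    I_norm = sqrt(1 - exp(-2 * I)),

which for a bivariate Gaussian with correlation rho returns exactly |rho|.
The PAM dissimilarity is its complement, d = 1 - I_norm: it lives in
[0, 1], is 1 exactly under independence, and has a null diagonal.  The
Pearson comparator uses d = 1 - |r| so that the two pipelines coincide in
the linear-Gaussian regime and differ only where dependence is
non-monotone.
"""

from __future__ import annotations

import numpy as np

from .data_io import DataError, MatrixKind, PairwiseMatrix, SpectralDataset

__all__ = ["normalize_mi", "mi_to_dissimilarity", "normalized_mi_matrix", "pearson_dissimilarity"]


def normalize_mi(i):
    """Map non-negative MI (nats) onto [0, 1) via sqrt(1 - exp(-2 I))."""
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MI must be non-negative (clamp negatives upstream)")
    out = np.sqrt(-np.expm1(-2.0 * arr))
    return float(out) if np.isscalar(i) or arr.ndim == 0 else out


def normalized_mi_matrix(m: PairwiseMatrix) -> PairwiseMatrix:
    """Apply the normalization entrywise; diagonal stays 0 by convention."""
    if m.kind is not MatrixKind.MI:
        raise DataError(f"expected an MI matrix, got kind={m.kind.value!r}")
    values = normalize_mi(m.values)
    np.fill_diagonal(values, 0.0)
    return PairwiseMatrix(values, MatrixKind.NORMALIZED_MI, m.labels)


def mi_to_dissimilarity(m: PairwiseMatrix) -> PairwiseMatrix:
    """Complement of the normalized similarity: d = 1 - I_norm.

    Equals 1 exactly for an independent pair and 0 in the limit of perfect
    dependence; the diagonal is exactly 0.
    """
    if m.kind is not MatrixKind.MI:
        raise DataError(f"expected an MI matrix, got kind={m.kind.value!r}")
    off = ~np.eye(m.p, dtype=bool)
    if np.any(m.values[off] < 0):
        raise DataError("MI matrix has negative entries; clamp before transforming")
    d = 1.0 - normalize_mi(m.values)
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(np.clip(d, 0.0, 1.0), MatrixKind.DISSIMILARITY, m.labels)


def pearson_dissimilarity(ds: SpectralDataset) -> PairwiseMatrix:
    """Linear-association comparator: d = 1 - |r| with r the Pearson correlation."""
    sds = ds.intensities.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DataError(
            f"zero-variance column(s) at wavenumber(s) {ds.wavenumbers[bad].tolist()}"
        )
    r = np.corrcoef(ds.intensities, rowvar=False)
    d = 1.0 - np.abs(r)
    d = 0.5 * (d + d.T)  # corrcoef is symmetric up to rounding
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(np.clip(d, 0.0, 1.0), MatrixKind.PEARSON_DISSIMILARITY, ds.wavenumbers)
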