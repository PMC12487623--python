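"""Pairwise mutual-information estimation with the Kraskov k-NN estimator.

Mutual information I(X, Y) between two continuous variables is the
Kullback-Leibler divergence between their joint density and the product of
the marginals; it is zero iff X and Y are independent and, unlike Pearson
correlation, detects non-monotone dependence.  All values are in nats.

The estimator is the first Kraskov-Stoegbauer-Grassberger (KSG) variant:
for each point, the Chebyshev (max-norm) distance eps_i to its k-th nearest
neighbour in the joint space is found, the numbers n_x(i) and n_y(i) of
marginal neighbours strictly within eps_i are counted, and

    I_hat = psi(k) + psi(n) - mean_i[ psi(n_x(i) + 1) + psi(n_y(i) + 1) ]

with psi the digamma function.  The estimator assumes continuous
(tie-free) data; absorbances recorded at finite precision may tie, so a
deterministic, seeded jitter far below the data scale is added before
estimation.  Finite-sample estimates can come out slightly negative; since
MI is non-negative by definition they are clamped to zero by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .data_io import MatrixKind, PairwiseMatrix, SpectralDataset

__all__ = ["KSGSettings", "ksg_mi", "gaussian_mi", "mi_matrix"]


@dataclass(frozen=True)
class KSGSettings:
    """Settings of the KSG estimator.

    ``k`` is the neighbour count (small k trades variance for bias; 3 is
    the customary default).  ``jitter_scale`` scales the tie-breaking
    noise, whose amplitude is ``jitter_scale * sd(v) * 1e-10`` per
    variable — ten orders of magnitude below the data scale, so it only
    resolves exact ties.  ``seed`` makes the jitter reproducible.
    """

    k: int = 3
    jitter_scale: float = 1.0
    seed: int = 0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be non-negative")


def gaussian_mi(rho: float) -> float:
    """Closed-form MI of a bivariate normal with correlation ``rho`` (nats).

    ``-0.5 * ln(1 - rho^2)``; serves as the validation oracle for the KSG
    estimator.
    """
    rho = float(rho)
    if not abs(rho) < 1:
        raise ValueError("|rho| must be strictly less than 1")
    return -0.5 * np.log1p(-rho * rho)


def _count_strictly_within(v: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """For each i, count j != i with |v_j - v_i| < eps_i.

    Distances are formed with the same floating-point subtraction the
    KD-tree used to define eps, so the point whose marginal distance
    *equals* eps (the k-th joint neighbour's binding coordinate) is
    excluded exactly, not up to rounding.
    """
    n = v.size
    out = np.empty(n, dtype=np.int64)
    chunk = max(1, 10_000_000 // n)
    for start in range(0, n, chunk):
        block = slice(start, min(start + chunk, n))
        d = np.abs(v[block, None] - v[None, :])
        out[block] = (d < eps[block, None]).sum(axis=1) - 1  # drop self
    return np.maximum(out, 0)


def ksg_mi(x, y, settings: KSGSettings | None = None) -> float:
    """KSG (variant 1) mutual information between two samples, in nats.

    The jitter streams are keyed to the unordered pair — the
    lexicographically smaller vector always receives the first stream — so
    ``ksg_mi(x, y) == ksg_mi(y, x)`` exactly.  A constant input carries no
    distinguishable information and returns 0 with a warning.
    """
    s = settings or KSGSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n <= s.k:
        raise ValueError(f"need more than k={s.k} samples, got n={n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input vector: returning MI = 0", stacklevel=2)
        return 0.0

    # MI is invariant under increasing affine maps of either marginal, but
    # the max-norm neighbour structure is not; standardizing each marginal
    # (Kraskov's own recommendation) restores that invariance up to
    # floating-point rounding and jitter.
    x = (x - x.mean()) / sx
    y = (y - y.mean()) / sy

    if s.jitter_scale > 0:
        stream_a, stream_b = np.random.SeedSequence(s.seed).spawn(2)
        x_first = np.round(x, 6).tobytes() <= np.round(y, 6).tobytes()
        rx = np.random.default_rng(stream_a if x_first else stream_b)
        ry = np.random.default_rng(stream_b if x_first else stream_a)
        x = x + rx.uniform(0.0, s.jitter_scale * 1e-10, size=n)
        y = y + ry.uniform(0.0, s.jitter_scale * 1e-10, size=n)

    joint = np.column_stack([x, y])
    tree = cKDTree(joint)
    dist, _ = tree.query(joint, k=s.k + 1, p=np.inf)
    eps = dist[:, s.k]
    nx = _count_strictly_within(x, eps)
    ny = _count_strictly_within(y, eps)
    est = float(
        digamma(s.k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )
    if s.clamp_negative:
        est = max(est, 0.0)
    return est


def pair_settings(settings: KSGSettings, i: int, j: int) -> KSGSettings:
    """Settings whose jitter stream is keyed by the unordered column pair.

    Keying each pair independently makes the full matrix reproducible
    regardless of the order (or parallelism) in which pairs are computed.
    """
    a, b = (i, j) if i <= j else (j, i)
    seed = int(np.random.SeedSequence([settings.seed, a, b]).generate_state(1)[0])
    return KSGSettings(settings.k, settings.jitter_scale, seed, settings.clamp_negative)


def mi_matrix(ds: SpectralDataset, settings: KSGSettings | None = None) -> PairwiseMatrix:
    """Symmetric matrix of pairwise KSG MI over all wavenumber pairs.

    The diagonal is set to 0 by convention: the self-MI of a continuous
    variable is unbounded and unused, and a zero diagonal lets the
    downstream dissimilarity transform produce its null diagonal without a
    special case.
    """
    s = settings or KSGSettings()
    x = ds.intensities
    p = ds.n_wavenumbers
    if ds.n_subjects <= s.k:
        raise ValueError("sample size must exceed the neighbour count k")
    values = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            est = ksg_mi(x[:, i], x[:, j], pair_settings(s, i, j))
            values[i, j] = values[j, i] = est
    return PairwiseMatrix(values, MatrixKind.MI, ds.wavenumbers)
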