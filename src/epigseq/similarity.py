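"""Count-level CY similarity between gene expression profiles.

The CY index originates in ecological species-abundance comparison and is
adopted here to correlate RNA-Seq count profiles sample by sample.  For two
profiles ``x`` and ``y`` the observed dissimilarity over the samples where at
least one profile has reads is

    observed CY_d = sum_j [ (x_j + y_j) ln((x_j + y_j)/2)
                            - x_j ln(y_j) - y_j ln(x_j) ] / (x_j + y_j)

with natural logarithms.  Zero counts (where the partner profile is nonzero)
are replaced by a small positive constant before evaluation, following the
species-abundance literature the index comes from.  The similarity is the
observed dissimilarity standardised by its maximum,

    CY_s = 1 - observed CY_d / maximum CY_d,

where the maximum reallocates each sample's total reads entirely to one
profile (the completely dissimilar allocation preserving per-sample totals).
CY_s is 1 for identical profiles and 0 for profiles with disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

__all__ = [
    "CySimilarity",
    "UndefinedSimilarityError",
    "observed_cy_d",
    "max_cy_d",
    "cy_similarity",
    "cy_matrix",
    "pairwise_cy",
]

#: Default substitution for zero counts inside the log terms.
DEFAULT_ZERO_SUB = 0.1

#: Floating-point guard when clamping CY_s into [0, 1].
_CLAMP_TOL = 1e-12


class UndefinedSimilarityError(ValueError):
    """Raised when CY similarity is undefined (both profiles identically zero)."""


@dataclass(frozen=True)
class CySimilarity:
    """CY_s similarity value together with the number of samples it used.

    Attributes
    ----------
    value : float
        Similarity in [0, 1]; 1 for identical profiles, 0 for profiles with
        disjoint support.
    n_samples_used : int
        Number of samples where at least one of the two profiles has reads
        (the ``a`` in the dissimilarity sum).
    """

    value: float
    n_samples_used: int


def _included(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mask of samples entering the sum: at least one profile has reads."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D arrays of equal length")
    mask = (x != 0) | (y != 0)
    if not mask.any():
        raise UndefinedSimilarityError(
            "CY similarity undefined: both profiles are zero in every sample"
        )
    return mask


def _cy_term(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-sample CY dissimilarity term for strictly positive a, b."""
    t = a + b
    return (t * np.log(t / 2.0) - a * np.log(b) - b * np.log(a)) / t


def observed_cy_d(x, y, zero_sub: float = DEFAULT_ZERO_SUB) -> float:
    """Observed CY dissimilarity between two count profiles.

    Samples where both profiles are zero are excluded; remaining zeros are
    replaced by ``zero_sub``.  Returns 0 for identical profiles.
    """
    if zero_sub <= 0:
        raise ValueError("zero_sub must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = _included(x, y)
    xs = np.where(x == 0, zero_sub, x)[mask]
    ys = np.where(y == 0, zero_sub, y)[mask]
    return float(np.sum(_cy_term(xs, ys)))


def max_cy_d(x, y, zero_sub: float = DEFAULT_ZERO_SUB) -> float:
    """Maximum CY dissimilarity given the observed per-sample totals.

    For each included sample the pair is replaced by ``(t_j, zero_sub)`` where
    ``t_j = x_j + y_j`` (raw totals): all reads on one side, the completely
    dissimilar allocation.  Always >= the observed dissimilarity.
    """
    if zero_sub <= 0:
        raise ValueError("zero_sub must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = _included(x, y)
    t = (x + y)[mask]
    return float(np.sum(_cy_term(t, np.full_like(t, zero_sub))))


def cy_similarity(x, y, zero_sub: float = DEFAULT_ZERO_SUB) -> CySimilarity:
    """CY_s similarity = 1 - observed CY_d / maximum CY_d, clamped to [0, 1].

    The degenerate case maximum = 0 (profiles identical and at the
    substitution floor) is defined as similarity 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = _included(x, y)
    a = int(mask.sum())
    obs = observed_cy_d(x, y, zero_sub)
    mx = max_cy_d(x, y, zero_sub)
    if mx <= _CLAMP_TOL:
        return CySimilarity(1.0, a)
    value = 1.0 - obs / mx
    # snap floating-point excursions onto the exact bounds
    if value < _CLAMP_TOL:
        value = 0.0
    elif value > 1.0 - _CLAMP_TOL:
        value = 1.0
    return CySimilarity(float(value), a)


def _cy_row_block(X: np.ndarray, rows: np.ndarray, zero_sub: float) -> np.ndarray:
    """CY_s of each row in ``rows`` against every row of ``X`` (vectorised)."""
    out = np.empty((len(rows), X.shape[0]))
    Xsub = np.where(X == 0, zero_sub, X)
    for pos, i in enumerate(rows):
        x = X[i]
        mask = (x != 0) | (X != 0)  # per-pair inclusion masks
        xs = np.where(x == 0, zero_sub, x)
        t_obs = xs + Xsub
        obs_terms = (
            t_obs * np.log(t_obs / 2.0) - xs * np.log(Xsub) - Xsub * np.log(xs)
        ) / t_obs
        t_raw = x + X
        t_max = t_raw + zero_sub
        with np.errstate(divide="ignore", invalid="ignore"):
            max_terms = (
                t_max * np.log(t_max / 2.0)
                - t_raw * np.log(zero_sub)
                - zero_sub * np.log(t_raw)
            ) / t_max
        obs = np.where(mask, obs_terms, 0.0).sum(axis=1)
        mx = np.where(mask, max_terms, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = 1.0 - obs / mx
        val = np.where(mx <= _CLAMP_TOL, 1.0, val)
        val = np.where(val < _CLAMP_TOL, 0.0, val)
        val = np.where(val > 1.0 - _CLAMP_TOL, 1.0, val)
        out[pos] = np.clip(val, 0.0, 1.0)
    return out


def cy_matrix(X, zero_sub: float = DEFAULT_ZERO_SUB, threads: int = 1) -> np.ndarray:
    """Symmetric CY_s matrix over the rows of a counts array.

    Parameters
    ----------
    X : array-like, shape (n_profiles, n_samples)
        Count profiles; no row may be identically zero.
    zero_sub : float
        Zero-count substitution used inside the log terms.
    threads : int
        joblib workers; the result is identical for any thread count (rows
        are partitioned into fixed blocks and reassembled in order).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if np.any((X == 0).all(axis=1)):
        raise UndefinedSimilarityError("all-zero profile passed to cy_matrix")
    rows = np.arange(n)
    if threads <= 1 or n < 8:
        S = _cy_row_block(X, rows, zero_sub)
    else:
        blocks = np.array_split(rows, threads)
        parts = Parallel(n_jobs=threads, prefer="threads")(
            delayed(_cy_row_block)(X, b, zero_sub) for b in blocks if len(b)
        )
        S = np.vstack(parts)
    # enforce exact symmetry and unit diagonal against round-off
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def pairwise_cy(counts, eligible, zero_sub: float = DEFAULT_ZERO_SUB,
                threads: int = 1) -> np.ndarray:
    """CY_s similarity table over a subset of genes of a count matrix.

    ``counts`` is the genes x samples array and ``eligible`` the gene indices
    to correlate (>= 2).  Returns the symmetric, unit-diagonal matrix ordered
    as ``eligible``.
    """
    eligible = np.asarray(eligible, dtype=int)
    if eligible.size < 2:
        raise ValueError("need at least 2 eligible genes for pairwise CY")
    X = np.asarray(counts, dtype=float)[eligible]
    return cy_matrix(X, zero_sub=zero_sub, threads=threads)
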