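"""Step 1: extraction of pattern-seed gene profiles.

A gene qualifies for pattern consideration when it is responsive (its
magnitude of change clears St1 in at least one treated group) and its
quasi-Poisson dispersion is not in the extreme tails of the empirical
dispersion distribution.  Among qualifying genes, a seed candidate is one
with at least Mt - 1 neighbours — genes whose CY_s similarity reaches Rt1 and
whose direction signature does not conflict (the CY index is blind to
anticorrelation, so directionality is enforced through the signs of the
magnitude statistics).  Redundant candidates are weeded greedily: a candidate
too similar (CY_s >= the weed-out correlation) to an already selected seed is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeedCandidate",
    "PatternSeed",
    "NoEligibleGenesError",
    "eligible_genes",
    "sign_compatible_matrix",
    "find_candidates",
    "weed_redundant",
]


class NoEligibleGenesError(ValueError):
    """No gene passed the magnitude and dispersion filters."""


@dataclass(frozen=True)
class SeedCandidate:
    """A gene qualifying as a potential pattern seed."""

    gene: int                 # index into the eligible-gene ordering
    neighbor_count: int
    median_neighbor_cy: float


@dataclass(frozen=True)
class PatternSeed:
    """A selected pattern template (selection order = pattern number)."""

    gene: int
    neighbor_count: int
    median_neighbor_cy: float


def eligible_genes(stats, st1: float = 2.0, pct: float = 5.0) -> np.ndarray:
    """Gene indices passing the St1 magnitude filter and the dispersion band.

    Keeps genes with |magnitude| >= ``st1`` in at least one treated group and
    dispersion within the [pct, 100 - pct] percentile band of the empirical
    dispersion distribution (computed over genes with a finite dispersion).
    """
    if not 0 <= pct < 50:
        raise ValueError("pct must be in [0, 50)")
    mags = stats.magnitudes
    with np.errstate(invalid="ignore"):
        responsive = (np.abs(mags) >= st1).any(axis=1)
    theta = stats.dispersion
    have_theta = np.isfinite(theta)
    keep = responsive & have_theta
    if have_theta.any() and pct > 0:
        lo, hi = np.percentile(theta[have_theta], [pct, 100.0 - pct])
        keep &= (theta >= lo) & (theta <= hi)
    idx = np.where(keep)[0]
    if idx.size == 0:
        raise NoEligibleGenesError(
            "no gene passes the magnitude and dispersion filters"
        )
    return idx


def sign_compatible_matrix(signs: np.ndarray) -> np.ndarray:
    """Boolean matrix: profiles conflict iff some treated group has strictly
    opposite nonzero signs; zeros are compatible with anything."""
    signs = np.asarray(signs)
    # product is -1 exactly when signs are nonzero and opposite
    conflict = np.einsum("ig,kg->ikg", signs, signs) == -1
    return ~conflict.any(axis=2)


def find_candidates(cy: np.ndarray, signs: np.ndarray,
                    rt1: float = 0.8, mt: int = 5) -> list:
    """Seed candidates from the pairwise CY table over eligible genes.

    A neighbour of gene i is a different gene with CY_s >= ``rt1`` and a
    sign-compatible signature.  Candidates need at least ``mt - 1`` neighbours
    and are sorted by neighbour count (descending), then median neighbour
    CY_s (descending), then input order.
    """
    cy = np.asarray(cy, dtype=float)
    n = cy.shape[0]
    if signs.shape[0] != n:
        raise ValueError("signs and cy tables must cover the same genes")
    compat = sign_compatible_matrix(signs)
    neigh = (cy >= rt1) & compat
    np.fill_diagonal(neigh, False)
    counts = neigh.sum(axis=1)
    candidates = []
    for i in range(n):
        if counts[i] >= mt - 1:
            med = float(np.median(cy[i, neigh[i]]))
            candidates.append(SeedCandidate(i, int(counts[i]), med))
    candidates.sort(key=lambda c: (-c.neighbor_count, -c.median_neighbor_cy, c.gene))
    return candidates


def weed_redundant(candidates, cy: np.ndarray, weed_r: float = 0.9) -> list:
    """Greedy weed-out of redundant candidates.

    Candidates are taken in sorted order; one whose CY_s to any already
    selected seed reaches ``weed_r`` is discarded.  The selection order sets
    the pattern numbering.  ``weed_r = 1.0`` disables weeding (every
    candidate is kept).
    """
    cy = np.asarray(cy, dtype=float)
    seeds = []
    for cand in candidates:
        if weed_r >= 1.0 or all(cy[cand.gene, s.gene] < weed_r for s in seeds):
            seeds.append(PatternSeed(cand.gene, cand.neighbor_count,
                                     cand.median_neighbor_cy))
    return seeds
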