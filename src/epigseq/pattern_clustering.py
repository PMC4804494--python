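"""Step 2: iterative clustering of genes to pattern seeds.

Every gene clearing the St2 magnitude filter is assigned to the
sign-compatible pattern representative to which it is most similar, provided
that similarity reaches Rt2.  After each assignment pass the representative
of every pattern is recomputed as the member with the highest median CY_s to
the other members (the pattern correlation score, PCS).  Assignment and
representative updates alternate until the fraction of genes changing
assignment between successive passes falls below 1e-4 or 100 iterations are
reached.  Patterns that lose all members are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternCluster",
    "EpigSeqResult",
    "assign_genes",
    "pattern_correlation_score",
    "cluster",
]

MAX_ITERATIONS = 100
CONVERGENCE_FRACTION = 1e-4

UNASSIGNED = -1


@dataclass
class PatternCluster:
    """One extracted pattern of co-expressed genes.

    ``members`` and ``representative`` are gene indices into the original
    count matrix.  ``pcs`` is the representative's median CY_s to the other
    members (1.0 for a degenerate singleton pattern, flagged by
    ``singleton``).  ``bootstrap_p`` is filled in by the significance module.
    """

    number: int
    members: list
    representative: int
    pcs: float
    bootstrap_p: float | None = None

    @property
    def singleton(self) -> bool:
        return len(self.members) == 1


@dataclass
class EpigSeqResult:
    """Full clustering outcome: patterns, unassigned genes and run metadata."""

    clusters: list
    unassigned: list
    iterations: int
    converged: bool
    parameters: dict = field(default_factory=dict)
    rng_seed: int | None = None
    #: CY_s of every clustered gene to its pattern representative (NaN for
    #: genes outside any pattern), indexed like the count matrix.
    cy_to_representative: np.ndarray | None = None

    @property
    def n_clustered(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def assign_genes(cy: np.ndarray, genes: np.ndarray, representatives,
                 rt2: float, signs: np.ndarray) -> np.ndarray:
    """Assign each gene to the best sign-compatible representative.

    Parameters are in a common gene indexing: ``cy`` is the pairwise CY_s
    table, ``genes`` the (row) indices eligible for clustering,
    ``representatives`` the current representative of each pattern in pattern
    order, ``signs`` the per-gene direction signatures.  A gene joins the
    pattern with the highest CY_s among compatible representatives when that
    CY_s reaches ``rt2``; ties go to the lower pattern number.  Returns an
    array over ``genes`` with the pattern position or -1 for unassigned.
    """
    reps = np.asarray(representatives, dtype=int)
    sub = cy[np.ix_(genes, reps)]                       # (n_genes, n_patterns)
    # conflict iff some treated group has strictly opposite nonzero signs
    conflict = np.einsum("ig,kg->ikg", signs[genes], signs[reps]) == -1
    compatible = ~conflict.any(axis=2)
    score = np.where(compatible & (sub >= rt2), sub, -np.inf)
    best = np.argmax(score, axis=1)                     # first max -> lower number
    assignment = np.where(np.isfinite(score[np.arange(len(genes)), best]),
                          best, UNASSIGNED)
    return assignment


def pattern_correlation_score(members, cy: np.ndarray):
    """Representative and PCS of a member set.

    For each member the median CY_s to all other members is computed; the
    representative is the argmax (ties to the lower gene index) and the PCS is
    that maximum median.  A singleton pattern has PCS 1.0 by convention.
    """
    members = np.asarray(sorted(members), dtype=int)
    if members.size == 0:
        raise ValueError("pattern has no members")
    if members.size == 1:
        return int(members[0]), 1.0
    sub = cy[np.ix_(members, members)].copy()
    n = members.size
    # median over the other members only
    off = sub[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    medians = np.median(off, axis=1)
    best = int(np.argmax(medians))  # first max -> lowest gene index
    return int(members[best]), float(medians[best])


def cluster(cy: np.ndarray, genes, seeds, rt2: float, signs: np.ndarray,
            parameters: dict | None = None) -> EpigSeqResult:
    """Iterate assignment and representative updates to a fixed point.

    ``cy`` and ``signs`` are indexed by original gene index; ``genes`` are the
    step-2 eligible gene indices (non-all-zero, clearing St2); ``seeds`` is
    the ordered list of :class:`~epigseq.pattern_extraction.PatternSeed`.
    """
    genes = np.asarray(genes, dtype=int)
    if len(seeds) == 0:
        raise ValueError("at least one pattern seed is required")
    reps = [s.gene for s in seeds]
    # stable pattern identities so movement is measured across drops
    ids = list(range(len(seeds)))

    def _drop_empty(assignment, reps, ids):
        kept = [k for k in range(len(reps)) if (assignment == k).any()]
        if len(kept) == len(reps):
            return assignment, reps, ids
        remap = {old: new for new, old in enumerate(kept)}
        assignment = np.array([remap.get(a, UNASSIGNED) for a in assignment], dtype=int)
        return assignment, [reps[k] for k in kept], [ids[k] for k in kept]

    def _as_ids(assignment, ids):
        lookup = np.array(ids + [UNASSIGNED])
        return lookup[assignment]  # UNASSIGNED (-1) maps to the appended slot

    iterations = 0
    converged = False
    if len(genes):
        assignment = assign_genes(cy, genes, reps, rt2, signs)
        assignment, reps, ids = _drop_empty(assignment, reps, ids)
        while iterations < MAX_ITERATIONS and reps:
            iterations += 1
            reps = [
                pattern_correlation_score(genes[assignment == k], cy)[0]
                for k in range(len(reps))
            ]
            new_assignment = assign_genes(cy, genes, reps, rt2, signs)
            prev_ids = _as_ids(assignment, ids)
            new_assignment, reps, ids = _drop_empty(new_assignment, reps, ids)
            changed = float(np.mean(_as_ids(new_assignment, ids) != prev_ids))
            assignment = new_assignment
            if changed < CONVERGENCE_FRACTION:
                converged = True
                break
        if not reps:
            converged = True  # nothing left to move
    else:
        assignment = np.full(0, UNASSIGNED)
        reps, ids = [], []
        converged = True

    clusters = []
    for k in range(len(reps)):
        members = [int(g) for g in genes[assignment == k]]
        rep, pcs = pattern_correlation_score(members, cy)
        clusters.append(PatternCluster(number=len(clusters) + 1, members=members,
                                       representative=rep, pcs=pcs))
    unassigned = [int(g) for g in genes[assignment == UNASSIGNED]]
    cy_to_rep = np.full(cy.shape[0], np.nan)
    for cl in clusters:
        cy_to_rep[cl.members] = cy[cl.members, cl.representative]
    return EpigSeqResult(
        clusters=clusters, unassigned=unassigned, iterations=iterations,
        converged=converged, parameters=dict(parameters or {}),
        cy_to_representative=cy_to_rep,
    )
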