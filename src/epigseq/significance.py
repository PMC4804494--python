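"""Bootstrap significance of extracted patterns.

For a pattern of P member genes, B random sets of P distinct gene profiles
are drawn from the analysed gene pool and the pattern correlation score (PCS)
of each random set is computed.  The pattern's p-value is the fraction of
random sets whose PCS exceeds the observed PCS: p = n / B, so p takes values
on the lattice {0, 1/B, ..., 1} and p = 0 is attainable.

Randomness is controlled by one master seed; each pattern gets its own
deterministic substream, so per-pattern p-values do not depend on the order
in which patterns are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern_clustering import pattern_correlation_score
from .similarity import DEFAULT_ZERO_SUB, cy_matrix

__all__ = [
    "BootstrapConfig",
    "bootstrap_pcs_samples",
    "bootstrap_pattern_pvalue",
    "add_bootstrap_pvalues",
]

DEFAULT_BOOTSTRAPS = 500


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: number of draws, master seed and the gene pool
    (indices into the count matrix) random profiles are drawn from."""

    B: int = DEFAULT_BOOTSTRAPS
    rng_seed: int = 0
    pool: np.ndarray | None = None
    zero_sub: float = DEFAULT_ZERO_SUB

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _random_pcs(counts: np.ndarray, pool: np.ndarray, size: int,
                rng: np.random.Generator, zero_sub: float) -> float:
    idx = rng.choice(pool.size, size=size, replace=False)
    sub = cy_matrix(counts[pool[idx]], zero_sub=zero_sub)
    _, pcs = pattern_correlation_score(np.arange(size), sub)
    return pcs


def bootstrap_pcs_samples(counts, pattern_size: int, config: BootstrapConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """B bootstrapped PCS values for random gene sets of ``pattern_size``."""
    counts = np.asarray(counts, dtype=float)
    pool = np.asarray(config.pool, dtype=int)
    if pattern_size > pool.size:
        raise ValueError(
            f"pattern size {pattern_size} exceeds pool size {pool.size}"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if pattern_size == 1:
        # PCS of any singleton is 1 by convention
        return np.ones(config.B)
    return np.array([
        _random_pcs(counts, pool, pattern_size, rng, config.zero_sub)
        for _ in range(config.B)
    ])


def bootstrap_pattern_pvalue(observed_pcs: float, pattern_size: int, counts,
                             config: BootstrapConfig,
                             rng: np.random.Generator | None = None) -> float:
    """p = (# bootstrapped PCS strictly greater than observed) / B."""
    samples = bootstrap_pcs_samples(counts, pattern_size, config, rng=rng)
    return float(np.sum(samples > observed_pcs) / config.B)


def add_bootstrap_pvalues(result, counts, config: BootstrapConfig) -> None:
    """Fill ``bootstrap_p`` on every cluster of an :class:`EpigSeqResult`.

    Each pattern uses a substream spawned from the master seed and indexed by
    its pattern number, making results independent of evaluation order.
    """
    for cl in result.clusters:
        stream = np.random.SeedSequence(config.rng_seed, spawn_key=(cl.number,))
        rng = np.random.default_rng(stream)
        cl.bootstrap_p = bootstrap_pattern_pvalue(
            cl.pcs, len(cl.members), counts, config, rng=rng
        )
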