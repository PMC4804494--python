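"""Synthetic RNA-Seq count matrices with planted co-expression patterns.

The generator emulates the data regimes the clustering method targets:
groups of biological replicates with a control, planted co-expression blocks
with distinct group-response signatures, overdispersed counts
(gamma-Poisson mixing calibrated to the quasi-Poisson variance V = mu*theta),
inflated zeros (mean-dependent dropout, concentrated in low-abundance genes
as in real RNA-Seq), unequal library sizes, and one correlated-but-
non-responsive "noisy" cluster that exercises the magnitude filter.

Gene means are parameterised on the reads-per-million (RPM) scale:
``mu_ij = baseline_rpm_i * 2^signature[group(j)] * library_size_j / 1e6``.
Pattern-member baselines are drawn within a 3-fold band because the CY index
is abundance-sensitive: profiles at very different expression levels are
dissimilar under CY no matter how parallel their responses, so a planted
co-expression block must share similar abundance to be a block at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_counts import CountMatrix

__all__ = [
    "SimulationSpec",
    "FIVE_PATTERN_SIGNATURES",
    "simulate_counts",
    "default_five_pattern_spec",
]

#: Labels in the truth vector returned by :func:`simulate_counts`.
BACKGROUND = 0
NOISE = -1

#: The five planted group-response signatures (log2 fold change per treated
#: group).  Sign structure: five length-5 codewords; since a binary code with
#: pairwise Hamming distance >= 3 admits only 4 codewords of length 5, two
#: pairs share all but two groups and carry the strongest (16-fold)
#: oppositions there.  Every signature contains a 4-fold (|log2FC| = 2) entry
#: as the minimum planted responsiveness, and stronger entries so members
#: clear the default magnitude threshold with margin.  Pairwise template
#: CY_s <= 0.85, within-signature CY_s >= 0.95 across the baseline band.
FIVE_PATTERN_SIGNATURES = (
    (+4.0, +4.0, -4.0, -4.0, +2.0),
    (-4.0, -4.0, +4.0, +4.0, +2.0),
    (+4.0, -2.0, +4.0, -4.0, -4.0),
    (-4.0, +2.0, -4.0, +4.0, -4.0),
    (+4.0, -4.0, -4.0, +4.0, +2.0),
)


@dataclass
class SimulationSpec:
    """Parameters of a planted-pattern count simulation.

    ``signatures`` holds one log2 fold-change vector per planted pattern
    (length ``n_groups - 1``, ordered as the treated groups).  ``theta`` is
    the quasi-Poisson dispersion (variance = mean * theta).  Zeros are
    inflated by mean-dependent dropout with probability
    ``zero_inflation * exp(-mu / zero_inflation_mean_scale)``, so dropout
    concentrates in low-abundance genes.  ``noise_jitter_sd`` is the standard
    deviation (log2 scale) of the per-sample multiplier shared by all genes
    of the noisy cluster: it correlates them without making any group
    responsive.
    """

    n_groups: int = 6
    replicates: int = 3
    signatures: tuple = FIVE_PATTERN_SIGNATURES
    genes_per_pattern: int = 40
    n_noise: int = 40
    n_background: int = 1000
    theta: float = 2.0
    zero_inflation: float = 0.05
    zero_inflation_mean_scale: float = 20.0
    library_size_range: tuple = (5_000_000, 20_000_000)
    pattern_baseline_rpm: tuple = (100.0, 300.0)
    noise_baseline_rpm: tuple = (100.0, 300.0)
    background_baseline_rpm: tuple = (0.5, 1000.0)
    noise_jitter_sd: float = 0.5
    rng_seed: int = 0

    @property
    def n_patterns(self) -> int:
        return len(self.signatures)

    def validate(self):
        if self.n_groups < 2 or self.replicates < 2:
            raise ValueError("need >= 2 groups and >= 2 replicates")
        if any(len(s) != self.n_groups - 1 for s in self.signatures):
            raise ValueError("each signature needs one entry per treated group")
        if self.theta < 1.0:
            raise ValueError("theta < 1 (underdispersion) is not supported")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")


def _overdispersed_counts(mu: np.ndarray, theta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu * theta (moment-matched); pure
    Poisson at theta = 1."""
    if theta <= 1.0:
        return rng.poisson(mu)
    shape = mu / (theta - 1.0)
    lam = np.where(mu > 0, rng.gamma(np.where(shape > 0, shape, 1.0),
                                     theta - 1.0), 0.0)
    return rng.poisson(np.where(mu > 0, lam, 0.0))


def _loguniform(rng, lo, hi, size):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_counts(spec: SimulationSpec):
    """Generate ``(CountMatrix, truth)``.

    ``truth`` labels each gene with its pattern (1-based), ``0`` for
    background or ``-1`` for the correlated-but-non-responsive noisy cluster.
    Gene order is pattern blocks, then the noisy cluster, then background.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n_treated = spec.n_groups - 1
    n_samples = spec.n_groups * spec.replicates
    group_labels = ["Control"] * spec.replicates
    for g in range(1, spec.n_groups):
        group_labels += [f"G{g}"] * spec.replicates
    lib = np.round(_loguniform(rng, *spec.library_size_range, n_samples)).astype(np.int64)

    sample_fc = np.zeros(n_samples)  # per-sample log2 effect, filled per gene class
    rows, truth, gene_ids = [], [], []

    def add_gene(baseline_rpm, log2_effect_per_sample, label, name):
        mu = baseline_rpm * 2.0 ** log2_effect_per_sample * lib / 1e6
        counts = _overdispersed_counts(mu, spec.theta, rng)
        drop_p = spec.zero_inflation * np.exp(-mu / spec.zero_inflation_mean_scale)
        counts = np.where(rng.random(n_samples) < drop_p, 0, counts)
        rows.append(counts)
        truth.append(label)
        gene_ids.append(name)

    # planted pattern blocks
    for p, sig in enumerate(spec.signatures, start=1):
        per_group = np.concatenate([[0.0], np.asarray(sig, dtype=float)])
        effects = np.repeat(per_group, spec.replicates)
        baselines = _loguniform(rng, *spec.pattern_baseline_rpm, spec.genes_per_pattern)
        for g in range(spec.genes_per_pattern):
            add_gene(baselines[g], effects, p, f"P{p}_{g + 1}")

    # correlated but non-responsive cluster: a shared per-sample jitter
    jitter = rng.normal(0.0, spec.noise_jitter_sd, size=n_samples)
    noise_baselines = _loguniform(rng, *spec.noise_baseline_rpm, spec.n_noise)
    for g in range(spec.n_noise):
        add_gene(noise_baselines[g], jitter, NOISE, f"N_{g + 1}")

    # independent flat background
    bg_baselines = _loguniform(rng, *spec.background_baseline_rpm, spec.n_background)
    for g in range(spec.n_background):
        add_gene(bg_baselines[g], sample_fc, BACKGROUND, f"B_{g + 1}")

    cm = CountMatrix(
        gene_ids=gene_ids,
        counts=np.asarray(rows, dtype=np.int64),
        group_labels=group_labels,
        control_label="Control",
        library_sizes=lib,
        allow_few_groups=spec.n_groups < 4,
    )
    return cm, np.asarray(truth, dtype=int)


def default_five_pattern_spec(rng_seed: int = 0) -> SimulationSpec:
    """The default five-pattern study: 6 groups (1 control + 5 treated) of 3
    replicates, 5 planted 40-gene patterns with distinct signatures, one
    40-gene correlated-but-non-responsive cluster, 1,000 background genes,
    theta = 2, 5 % zero inflation."""
    return SimulationSpec(rng_seed=rng_seed)
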