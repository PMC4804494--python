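"""End-to-end analysis pipeline.

Mirrors the tool's workflow: per-gene magnitude statistics, pairwise CY_s
correlation, step-1 pattern extraction with redundancy weed-out, step-2
iterative clustering of genes to the pattern seeds, per-gene GLM p-values and
per-pattern bootstrap p-values, then tables and figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io_counts, pattern_clustering, pattern_extraction
from .gene_stats import DEFAULT_SMALL_N_CUTOFF, compute_gene_stats
from .io_counts import CountMatrix
from .pattern_clustering import EpigSeqResult
from .significance import DEFAULT_BOOTSTRAPS, BootstrapConfig, add_bootstrap_pvalues
from .similarity import DEFAULT_ZERO_SUB, pairwise_cy

log = logging.getLogger("epigseq")

__all__ = ["RunConfig", "run_pipeline", "analyze"]


@dataclass
class RunConfig:
    """Full parameterisation of a run (serialised for provenance)."""

    input: str | None = None
    control_label: str = "Control"
    rt1: float = 0.8
    rt2: float = 0.8
    st1: float = 2.0
    st2: float = 2.0
    mt: int = 5
    weed_r: float = 0.9
    pct: float = 5.0
    bootstraps: int = DEFAULT_BOOTSTRAPS
    threads: int = 1
    seed: int = 0
    outdir: str | None = None
    zero_sub: float = DEFAULT_ZERO_SUB
    pseudocount: float = 1.0
    small_n_cutoff: int = DEFAULT_SMALL_N_CUTOFF
    allow_few_groups: bool = False
    min_total_count: int = 0
    plots: bool = True

    def validate(self):
        if not (0 < self.rt1 <= 1 and 0 < self.rt2 <= 1 and 0 < self.weed_r <= 1):
            raise ValueError("rt1, rt2 and weed_r must be in (0, 1]")
        if self.st1 < 0 or self.st2 < 0:
            raise ValueError("st1 and st2 must be >= 0")
        if self.mt < 2:
            raise ValueError("mt (minimum genes per pattern) must be >= 2")
        if not 0 <= self.pct < 50:
            raise ValueError("pct must be in [0, 50)")
        if self.bootstraps < 1 or self.threads < 1:
            raise ValueError("bootstraps and threads must be >= 1")
        if self.zero_sub <= 0:
            raise ValueError("zero_sub must be positive")


def analyze(cm: CountMatrix, config: RunConfig):
    """Run the two-step analysis on a count matrix.

    Returns ``(result, stats)`` where ``result`` is an
    :class:`~epigseq.pattern_clustering.EpigSeqResult` with bootstrap
    p-values filled in and ``stats`` the per-gene statistics table.
    """
    config.validate()
    analyzable = cm.analyzable()
    if config.min_total_count > 0:
        totals = cm.counts.sum(axis=1)
        analyzable = analyzable[totals[analyzable] >= config.min_total_count]
    log.info("step 0: %d genes, %d analyzable (all-zero or low-count rows excluded)",
             cm.n_genes, analyzable.size)

    # 1. magnitude statistics (Z or Hodges-Lehmann) + dispersion + gene p-values
    stats = compute_gene_stats(cm, small_n_cutoff=config.small_n_cutoff,
                               st=config.st1, gene_subset=analyzable)
    log.info("step 1: per-gene magnitudes computed (method=%s)", stats.method)

    empty = EpigSeqResult(clusters=[], unassigned=[], iterations=0, converged=True,
                          parameters=asdict(config), rng_seed=config.seed,
                          cy_to_representative=np.full(cm.n_genes, np.nan))

    # step-1 eligibility: St1 + dispersion percentile band
    try:
        elig1 = pattern_extraction.eligible_genes(stats, st1=config.st1, pct=config.pct)
    except pattern_extraction.NoEligibleGenesError:
        log.warning("no genes pass the St1 magnitude / dispersion filters; "
                    "returning an empty result")
        return empty, stats
    elig1 = elig1[np.isin(elig1, analyzable)]
    with np.errstate(invalid="ignore"):
        pass2 = (np.abs(stats.magnitudes) >= config.st2).any(axis=1)
    elig2 = analyzable[pass2[analyzable]]
    log.info("step 2: %d genes eligible for pattern extraction, %d for clustering",
             elig1.size, elig2.size)
    if elig1.size < 2:
        log.warning("fewer than 2 step-1 eligible genes; returning an empty result")
        return empty, stats

    # 2. pairwise CY_s over the union of step-1 and step-2 eligible genes
    universe = np.union1d(elig1, elig2)
    cy = pairwise_cy(cm.counts, universe, zero_sub=config.zero_sub,
                     threads=config.threads)
    upos = {g: i for i, g in enumerate(universe)}
    signs_u = stats.signs[universe]
    log.info("step 3: pairwise CY_s computed over %d genes", universe.size)

    # 3-4. extract patterns, weed redundant ones
    elig1_pos = np.array([upos[g] for g in elig1])
    cy1 = cy[np.ix_(elig1_pos, elig1_pos)]
    candidates = pattern_extraction.find_candidates(
        cy1, stats.signs[elig1], rt1=config.rt1, mt=config.mt
    )
    log.info("step 4: %d seed candidates", len(candidates))
    seeds_local = pattern_extraction.weed_redundant(candidates, cy1, weed_r=config.weed_r)
    seeds = [
        pattern_extraction.PatternSeed(upos[elig1[s.gene]], s.neighbor_count,
                                       s.median_neighbor_cy)
        for s in seeds_local
    ]
    log.info("step 5: %d pattern seeds after weed-out", len(seeds))
    if not seeds:
        log.warning("no pattern seeds extracted; returning an empty result")
        return empty, stats

    # 5-7. cluster genes to the seeds
    elig2_pos = np.array([upos[g] for g in elig2], dtype=int)
    if elig2_pos.size == 0:
        log.warning("no genes pass the St2 magnitude filter; clusters are empty")
    # recompute signs at the St2 threshold for clustering directionality
    with np.errstate(invalid="ignore"):
        signs2 = np.where(np.abs(stats.magnitudes[universe]) >= config.st2,
                          np.sign(stats.magnitudes[universe]), 0).astype(int)
    result = pattern_clustering.cluster(
        cy, elig2_pos, seeds, rt2=config.rt2, signs=signs2,
        parameters=asdict(config),
    )
    log.info("step 6-7: clustering finished in %d iteration(s), converged=%s, "
             "%d gene(s) in %d pattern(s)",
             result.iterations, result.converged, result.n_clustered,
             len(result.clusters))

    # map universe positions back to original gene indices
    for cl in result.clusters:
        cl.members = [int(universe[m]) for m in cl.members]
        cl.representative = int(universe[cl.representative])
    result.unassigned = [int(universe[g]) for g in result.unassigned]
    cy_full = np.full(cm.n_genes, np.nan)
    cy_full[universe] = result.cy_to_representative[: universe.size]
    result.cy_to_representative = cy_full
    result.rng_seed = config.seed

    # 8. bootstrap significance of each pattern
    pool = analyzable
    add_bootstrap_pvalues(
        result, cm.counts,
        BootstrapConfig(B=config.bootstraps, rng_seed=config.seed, pool=pool,
                        zero_sub=config.zero_sub),
    )
    log.info("step 8: bootstrap p-values computed (B=%d)", config.bootstraps)
    return result, stats


def run_pipeline(config: RunConfig, cm: CountMatrix | None = None):
    """Execute a full run: analysis plus output files and figures.

    ``cm`` may be supplied directly; otherwise ``config.input`` is read.
    Writes into ``config.outdir``: ``config.json``, ``gene_table.tsv``,
    ``pattern_summary.tsv`` and (unless disabled) the profile/heatmap/PCA
    figures.  Returns ``(result, stats, cm)``.
    """
    from pathlib import Path

    config.validate()
    if cm is None:
        if config.input is None:
            raise ValueError("either a CountMatrix or config.input is required")
        cm = io_counts.read_counts(config.input, config.control_label,
                                   allow_few_groups=config.allow_few_groups)
    result, stats = analyze(cm, config)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(config), fh, indent=2, sort_keys=True)
            fh.write("\n")
        io_counts.write_gene_table(result, stats, cm, outdir / "gene_table.tsv")
        io_counts.write_pattern_summary(result, cm, outdir / "pattern_summary.tsv")
        if config.plots and result.clusters:
            from . import plots

            ratio = io_counts.log2_rpm_ratio(cm, pseudocount=config.pseudocount)
            plots.plot_pattern_profiles(result, ratio, outdir)
            plots.plot_heatmap(result, ratio, outdir)
            if result.n_clustered >= 3:
                plots.plot_pca(result, cm, outdir, zero_sub=config.zero_sub)
        log.info("step 9: results written to %s", outdir)
    return result, stats, cm
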