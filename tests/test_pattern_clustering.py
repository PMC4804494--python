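"""Iterative clustering to pattern seeds: assignment rules, PCS
representative search, convergence and stability."""

import numpy as np
import pytest

from epigseq.pattern_clustering import (
    UNASSIGNED,
    assign_genes,
    cluster,
    pattern_correlation_score,
)
from epigseq.pattern_extraction import PatternSeed


def block_cy(sizes, within=0.95, between=0.5, rng=None, jitter=0.0):
    n = sum(sizes)
    cy = np.full((n, n), between)
    start = 0
    for s in sizes:
        cy[start:start + s, start:start + s] = within
        start += s
    if jitter:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        cy = np.clip(cy + noise, 0.0, 0.999)
    np.fill_diagonal(cy, 1.0)
    return cy


class TestAssignGenes:
    def test_seed_assigns_to_its_own_pattern(self):
        cy = block_cy([4, 4], within=0.9, between=0.3)
        signs = np.zeros((8, 1), dtype=int)
        genes = np.arange(8)
        a = assign_genes(cy, genes, [0, 4], rt2=0.8, signs=signs)
        assert a[0] == 0 and a[4] == 1

    def test_below_threshold_is_unassigned(self):
        cy = np.array([[1.0, 0.75], [0.75, 1.0]])
        signs = np.zeros((2, 1), dtype=int)
        a = assign_genes(cy, np.array([1]), [0], rt2=0.8, signs=signs)
        assert a[0] == UNASSIGNED

    def test_sign_conflict_blocks_assignment(self):
        cy = np.array([[1.0, 0.95], [0.95, 1.0]])
        signs = np.array([[1], [-1]])
        a = assign_genes(cy, np.array([1]), [0], rt2=0.8, signs=signs)
        assert a[0] == UNASSIGNED

    def test_tie_goes_to_lower_pattern_number(self):
        cy = np.array([
            [1.0, 0.5, 0.9],
            [0.5, 1.0, 0.9],
            [0.9, 0.9, 1.0],
        ])
        signs = np.zeros((3, 1), dtype=int)
        a = assign_genes(cy, np.array([2]), [0, 1], rt2=0.8, signs=signs)
        assert a[0] == 0

    def test_planted_blocks_assign_to_their_seed(self):
        rng = np.random.default_rng(0)
        cy = block_cy([10, 10], within=0.93, between=0.4, rng=rng, jitter=0.03)
        signs = np.array([[1]] * 10 + [[-1]] * 10)
        genes = np.arange(20)
        a = assign_genes(cy, genes, [0, 10], rt2=0.8, signs=signs)
        assert np.all(a[:10] == 0) and np.all(a[10:] == 1)


class TestPatternCorrelationScore:
    def test_highest_median_member_is_representative(self):
        # A has CY {0.9, 0.9}; B and C have {0.9, 0.5}
        cy = np.array([
            [1.0, 0.9, 0.9],
            [0.9, 1.0, 0.5],
            [0.9, 0.5, 1.0],
        ])
        rep, pcs = pattern_correlation_score([0, 1, 2], cy)
        assert rep == 0 and pcs == pytest.approx(0.9)

    def test_tie_breaks_to_lowest_gene_index(self):
        cy = np.full((4, 4), 0.7)
        np.fill_diagonal(cy, 1.0)
        rep, pcs = pattern_correlation_score([2, 1, 3], cy)
        assert rep == 1 and pcs == pytest.approx(0.7)

    def test_singleton_is_degenerate_with_unit_pcs(self):
        cy = np.eye(2)
        rep, pcs = pattern_correlation_score([1], cy)
        assert rep == 1 and pcs == 1.0

    def test_exhaustive_search_oracle(self):
        rng = np.random.default_rng(99)
        n = 20
        cy = rng.uniform(0.2, 1.0, (n, n))
        cy = (cy + cy.T) / 2
        np.fill_diagonal(cy, 1.0)
        members = list(rng.choice(n, 12, replace=False))
        rep, pcs = pattern_correlation_score(members, cy)
        best = None
        for m in sorted(members):
            med = np.median([cy[m, o] for o in members if o != m])
            if best is None or med > best[1] + 1e-15:
                best = (m, med)
        assert (rep, pcs) == (best[0], pytest.approx(best[1]))


class TestCluster:
    def test_exact_centroids_converge_in_one_iteration(self):
        cy = block_cy([6, 6], within=0.9, between=0.3)
        signs = np.zeros((12, 1), dtype=int)
        seeds = [PatternSeed(0, 5, 0.9), PatternSeed(6, 5, 0.9)]
        res = cluster(cy, np.arange(12), seeds, rt2=0.8, signs=signs)
        assert res.converged and res.iterations == 1
        assert sorted(len(c.members) for c in res.clusters) == [6, 6]

    def test_fixed_point_is_stable(self):
        rng = np.random.default_rng(4)
        cy = block_cy([8, 8, 8], within=0.92, between=0.45, rng=rng, jitter=0.05)
        signs = np.vstack([np.tile(s, (8, 1)) for s in ([1], [1], [-1])])
        seeds = [PatternSeed(0, 7, 0.9), PatternSeed(8, 7, 0.9), PatternSeed(16, 7, 0.9)]
        res1 = cluster(cy, np.arange(24), seeds, rt2=0.7, signs=signs)
        seeds2 = [PatternSeed(c.representative, 0, 0.0) for c in res1.clusters]
        res2 = cluster(cy, np.arange(24), seeds2, rt2=0.7, signs=signs)
        assert [sorted(c.members) for c in res2.clusters] == \
               [sorted(c.members) for c in res1.clusters]
        assert res2.iterations == 1 and res2.converged

    def test_iterations_capped_on_adversarial_data(self):
        rng = np.random.default_rng(123)
        n = 60
        cy = rng.uniform(0.0, 1.0, (n, n))
        cy = (cy + cy.T) / 2
        np.fill_diagonal(cy, 1.0)
        signs = rng.integers(-1, 2, size=(n, 1))
        seeds = [PatternSeed(i, 0, 0.0) for i in range(5)]
        res = cluster(cy, np.arange(n), seeds, rt2=0.0, signs=signs)
        assert res.iterations <= 100

    def test_empty_gene_set_yields_empty_result(self):
        cy = np.eye(3)
        res = cluster(cy, np.array([], dtype=int), [PatternSeed(0, 0, 0.0)],
                      rt2=0.8, signs=np.zeros((3, 1), dtype=int))
        assert res.clusters == [] and res.converged

    def test_emptied_patterns_are_dropped(self):
        # the second seed attracts nothing at rt2 = 0.8
        cy = np.array([
            [1.0, 0.95, 0.2],
            [0.95, 1.0, 0.2],
            [0.2, 0.2, 1.0],
        ])
        signs = np.zeros((3, 1), dtype=int)
        seeds = [PatternSeed(0, 1, 0.9), PatternSeed(2, 1, 0.9)]
        res = cluster(cy, np.array([0, 1]), seeds, rt2=0.8, signs=signs)
        assert len(res.clusters) == 1
        assert sorted(res.clusters[0].members) == [0, 1]

    def test_membership_invariant_to_gene_order(self, five_pattern_data):
        from epigseq import RunConfig, analyze

        cm, truth = five_pattern_data
        rng = np.random.default_rng(7)
        perm = rng.permutation(cm.n_genes)
        from epigseq.io_counts import CountMatrix

        cm_perm = CountMatrix(
            [cm.gene_ids[i] for i in perm], cm.counts[perm],
            cm.group_labels, cm.control_label, cm.library_sizes,
        )
        cfg = RunConfig(bootstraps=1, seed=0)
        res_a, _ = analyze(cm, cfg)
        res_b, _ = analyze(cm_perm, cfg)
        sets_a = sorted(sorted(cm.gene_ids[g] for g in c.members)
                        for c in res_a.clusters)
        sets_b = sorted(sorted(cm_perm.gene_ids[g] for g in c.members)
                        for c in res_b.clusters)
        assert sets_a == sets_b
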