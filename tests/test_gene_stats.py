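"""Magnitude statistics, dispersion and GLM p-values against independent
oracles (exact rank-sum enumeration, brute-force pairwise medians,
statsmodels IRLS fits, parameter-recovery simulations)."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epigseq import CountMatrix
from epigseq.gene_stats import (
    METHOD_HL,
    METHOD_WILCOXON,
    compute_gene_stats,
    glm_gene_pvalue,
    hodges_lehmann,
    quasipoisson_dispersion,
    wilcoxon_z,
)


def exact_ranksum_pvalue(treated, control):
    """Exact two-sided rank-sum p-value by enumerating every split of the
    pooled values into groups of the observed sizes."""
    from scipy.stats import rankdata

    pooled = np.concatenate([treated, control])
    ranks = rankdata(pooled)
    n1 = len(treated)
    mu = n1 * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mu)
    count = total = 0
    for subset in combinations(range(len(pooled)), n1):
        w = ranks[list(subset)].sum()
        total += 1
        if abs(w - mu) >= obs - 1e-9:
            count += 1
    return count / total


sample_values = st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=6)


class TestWilcoxonZ:
    def test_textbook_value_with_continuity_correction(self):
        # W = 15, mu = 10.5, var = 5.25 -> Z = (15 - 10.5 - 0.5)/sqrt(5.25)
        z = wilcoxon_z([10, 20, 30], [1, 2, 3])
        assert z == pytest.approx(4.0 / np.sqrt(5.25), abs=1e-12)

    def test_identical_multisets_give_zero(self):
        assert wilcoxon_z([1, 2, 3], [3, 1, 2]) == 0.0
        assert wilcoxon_z([5, 5, 5], [5, 5, 5]) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(t=sample_values, c=sample_values)
    def test_antisymmetric(self, t, c):
        assert wilcoxon_z(t, c) == pytest.approx(-wilcoxon_z(c, t))

    @pytest.mark.parametrize("pooled,n1", [
        (np.array([3, 1, 4, 1, 5, 9, 2, 6]), 4),
        (np.array([0, 0, 1, 2, 2, 2, 7, 9]), 4),   # heavy ties
        (np.array([10, 4, 8, 15, 2, 2, 11]), 3),
    ])
    def test_rank_concordance_with_exact_enumeration(self, pooled, n1):
        """Over every split of a pooled dataset, a larger |Z| must never pair
        with a larger exact p-value."""
        results = []
        for subset in combinations(range(len(pooled)), n1):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(subset)] = True
            t, c = pooled[mask], pooled[~mask]
            results.append((abs(wilcoxon_z(t, c)), exact_ranksum_pvalue(t, c)))
        for (za, pa), (zb, pb) in combinations(results, 2):
            if za > zb + 1e-9:
                assert pa <= pb + 1e-12
            elif zb > za + 1e-9:
                assert pb <= pa + 1e-12


class TestHodgesLehmann:
    def test_median_of_pairwise_differences(self):
        assert hodges_lehmann([3, 5, 7], [1, 2, 3]) == 3.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(t=sample_values, c=sample_values)
    def test_brute_force_oracle(self, t, c):
        expected = float(np.median(sorted(ti - ci for ti in t for ci in c)))
        assert hodges_lehmann(t, c) == pytest.approx(expected)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(c=sample_values, shift=st.integers(min_value=-20, max_value=20))
    def test_shift_equivariance_and_antisymmetry(self, c, shift):
        t = [v + shift for v in c]
        assert hodges_lehmann(t, c) == pytest.approx(shift)
        assert hodges_lehmann(c, t) == pytest.approx(-shift)


class TestMagnitudeVector:
    def test_flat_gene_has_zero_signs(self, small_cm):
        stats = compute_gene_stats(small_cm)
        assert np.all(stats.signs[1] == 0)  # the flat gene
        assert np.all(np.abs(stats.magnitudes[1]) < 2)

    def test_small_replicate_count_switches_to_hodges_lehmann(self, small_cm):
        assert compute_gene_stats(small_cm, small_n_cutoff=4).method == METHOD_HL
        assert compute_gene_stats(small_cm, small_n_cutoff=2).method == METHOD_WILCOXON

    def test_sign_thresholding(self):
        mags = np.array([[2.5, -0.3, 3.1]])
        signs = np.where(np.abs(mags) >= 2, np.sign(mags), 0)
        assert signs.tolist() == [[1, 0, 1]]
        # and through the real path: responsive gene picks up the right signs
        # (gene 0 of small_cm is up in group A only)

    def test_all_zero_gene_gets_nan_magnitudes(self, small_cm):
        stats = compute_gene_stats(small_cm)
        assert np.all(np.isnan(stats.magnitudes[2]))
        assert np.all(stats.signs[2] == 0)

    def test_responsive_gene_direction(self, small_cm):
        stats = compute_gene_stats(small_cm)
        groups = stats.treated_groups
        # gene 0 is ~4x up in A; gene 4 is ~3-4x down in C
        assert stats.signs[0, groups.index("A")] == 1
        assert stats.signs[4, groups.index("C")] == -1


class TestDispersion:
    def test_exact_fit_gives_zero(self):
        cm = CountMatrix(["g1", "g2"], np.array([[4, 4, 9, 9], [1, 1, 1, 1]]),
                         ["C", "C", "T", "T"], "C", np.full(4, 1000),
                         allow_few_groups=True)
        assert quasipoisson_dispersion(cm.counts[0], cm) == pytest.approx(0.0)

    def test_single_group_hand_fit(self):
        # counts {0, 2}, equal library sizes: fitted mean 1, X^2 = 2, df = 1
        cm = CountMatrix(["g1"], np.array([[0, 2]]), ["C", "C"], "C",
                         np.array([1000, 1000]), allow_few_groups=True)
        assert quasipoisson_dispersion(np.array([0, 2]), cm) == pytest.approx(2.0)

    def test_matches_statsmodels_irls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        labels = ["C"] * 3 + ["A"] * 3 + ["B"] * 3 + ["D"] * 3
        lib = rng.integers(500_000, 2_000_000, 12)
        counts = rng.poisson(rng.gamma(25, 2.0, size=(6, 12)))
        counts[(counts == 0).all(axis=1)] += 1
        cm = CountMatrix([f"g{i}" for i in range(6)], counts, labels, "C", lib)
        X = np.zeros((12, 4))
        for k, g in enumerate(cm.group_names()):
            X[cm.group_columns(g), k] = 1.0
        for i in range(6):
            fit = sm.GLM(counts[i], X, family=sm.families.Poisson(),
                         offset=np.log(lib)).fit(scale="X2")
            assert quasipoisson_dispersion(counts[i], cm) == pytest.approx(
                fit.scale, rel=1e-8)
            # deviance-based F test p-value agrees too
            null = sm.GLM(counts[i], np.ones((12, 1)),
                          family=sm.families.Poisson(), offset=np.log(lib)).fit()
            from scipy.stats import f as fdist
            F = (null.deviance - fit.deviance) / 3 / fit.scale
            assert glm_gene_pvalue(counts[i], cm) == pytest.approx(
                fdist.sf(F, 3, 8), rel=1e-6)

    @pytest.mark.parametrize("theta", [1.0, 3.0])
    def test_parameter_recovery(self, theta):
        rng = np.random.default_rng(11)
        n = 200
        labels = [f"grp{k}" for k in range(4) for _ in range(n // 4)]
        lib = rng.integers(5_000_000, 20_000_000, n)
        mu = 80 * lib / 1e7
        lam = rng.gamma(mu / (theta - 1), theta - 1) if theta > 1 else mu
        y = rng.poisson(lam)
        cm = CountMatrix(["g"], y[None, :], labels, "grp0", lib,
                         allow_few_groups=True)
        assert quasipoisson_dispersion(y, cm) == pytest.approx(theta, rel=0.2)


class TestGlmPvalue:
    def test_identical_counts_everywhere_give_p_one(self):
        cm = CountMatrix(["g"], np.array([[7, 7, 7, 7, 7, 7, 7, 7]]),
                         ["C", "C", "A", "A", "B", "B", "D", "D"], "C",
                         np.full(8, 1000))
        assert glm_gene_pvalue(cm.counts[0], cm) == 1.0

    def test_power_for_strong_shift(self):
        rng = np.random.default_rng(23)
        labels = ["C"] * 3 + ["A"] * 3 + ["B"] * 3 + ["D"] * 3
        lib = np.full(12, 10_000_000)
        hits = 0
        for _ in range(40):
            mu = np.full(12, 50.0)
            mu[3:6] *= 8.0  # 8-fold shift in one group
            y = rng.poisson(rng.gamma(mu / 1.0, 1.0))  # theta = 2
            cm = CountMatrix(["g"], y[None, :], labels, "C", lib)
            if glm_gene_pvalue(y, cm) < 0.05:
                hits += 1
        assert hits > 20
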