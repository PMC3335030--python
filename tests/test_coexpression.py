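import numpy as np
import pandas as pd
import pytest

from melnet.coexpression import (
    bootstrap_stability,
    conserved_pair_check,
    filter_clusters,
    random_set_rho_null,
    spearman_matrix,
    ward_cluster,
    ward_linkage,
)
from melnet.dataio import DataFormatError
from melnet.synthetic import (
    GeneratorConfig,
    generate_truth,
    simulate_perturbation_dataset,
)

from conftest import make_expr


def _noiseless_two_module_expr(n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=n_samples), rng.normal(size=n_samples)
    rows = [a, 2 * a, -a, 0.5 * a, b, 3 * b, -0.5 * b, b + 0.0]
    genes = [f"m1_{i}" for i in range(4)] + [f"m2_{i}" for i in range(4)]
    return make_expr(np.array(rows), genes=genes)


class TestSpearman:
    def test_hand_rank_formula_example(self):
        # ranks of y against x: d = (0, 2, -2)... rho = 1 - 6*sum(d^2)/(n(n^2-1))
        expr = make_expr([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        corr = spearman_matrix(expr)
        assert corr.rho[0, 1] == pytest.approx(-0.5)

    def test_invariant_to_monotone_transform(self):
        x = np.array([0.3, 1.7, 0.9, 2.5, -1.0])
        expr = make_expr([x, np.exp(x)])
        corr = spearman_matrix(expr)
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        expr = make_expr([[1.0, 5.0, 2.0, 4.0]])
        assert spearman_matrix(expr).rho[0, 0] == 1.0

    def test_constant_gene_zeroed_and_flagged(self):
        expr = make_expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            corr = spearman_matrix(expr)
        assert corr.rho[0, 1] == 0.0
        assert corr.constant_genes == ["g0"]
        assert corr.rho[0, 0] == 1.0  # unit diagonal preserved

    def test_requires_three_samples(self):
        with pytest.raises(DataFormatError):
            spearman_matrix(make_expr([[1.0, 2.0]]))

    def test_matches_scipy_on_random_data(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 25))
        corr = spearman_matrix(make_expr(X))
        expected = spearmanr(X, axis=1).statistic
        assert np.allclose(corr.rho, expected, atol=1e-12)


class TestWard:
    def test_noiseless_modules_recovered_at_k2(self):
        expr = _noiseless_two_module_expr()
        corr = spearman_matrix(expr)
        clusters = ward_cluster(corr, 2)
        parts = {frozenset(c.members) for c in clusters.clusters}
        assert parts == {
            frozenset(f"m1_{i}" for i in range(4)),
            frozenset(f"m2_{i}" for i in range(4)),
        }

    def test_k_equals_n_gives_singletons(self):
        expr = _noiseless_two_module_expr()
        clusters = ward_cluster(spearman_matrix(expr), expr.n_genes)
        assert all(c.size == 1 for c in clusters.clusters)

    def test_gene_and_its_negation_co_cluster(self):
        expr = _noiseless_two_module_expr()
        corr = spearman_matrix(expr)
        clusters = ward_cluster(corr, 2)
        member_of = clusters.membership()
        assert member_of["m1_0"] == member_of["m1_2"]  # -a clusters with a

    def test_invalid_k_rejected(self):
        corr = spearman_matrix(_noiseless_two_module_expr())
        with pytest.raises(DataFormatError):
            ward_cluster(corr, 0)
        with pytest.raises(DataFormatError):
            ward_cluster(corr, 999)

    def test_merge_heights_non_decreasing(self, scaled):
        corr = spearman_matrix(scaled)
        Z = ward_linkage(corr)
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)


class TestFilterClusters:
    def _corr_of(self, expr):
        return spearman_matrix(expr)

    def test_five_member_perfect_cluster_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        expr = make_expr([a * w for w in (1, 2, 3, 4, 5)])
        corr = self._corr_of(expr)
        clusters = ward_cluster(corr, 1)
        assert len(filter_clusters(clusters, corr)) == 0  # size must exceed 5

    def test_six_identical_genes_retained_with_unit_stats(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        expr = make_expr([a] * 6)
        corr = self._corr_of(expr)
        retained = filter_clusters(ward_cluster(corr, 1), corr)
        assert len(retained) == 1
        c = retained.clusters[0]
        assert c.min_abs_rho == pytest.approx(1.0)
        assert c.median_abs_rho == pytest.approx(1.0)

    def test_single_weak_pair_fails_min_rule(self):
        # six genes, five perfectly correlated, one nearly independent:
        # the cluster's min pairwise |rho| falls below 0.4
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        weak = 0.2 * a + rng.normal(size=40)
        expr = make_expr([a, 2 * a, 3 * a, -a, 0.5 * a, weak])
        corr = self._corr_of(expr)
        retained = filter_clusters(ward_cluster(corr, 1), corr)
        assert len(retained) == 0

    def test_invariant_to_gene_ordering(self, scaled):
        corr = spearman_matrix(scaled)
        retained = filter_clusters(ward_cluster(corr, 10), corr)
        perm = np.random.default_rng(0).permutation(scaled.n_genes)
        shuffled = make_expr(
            scaled.values.to_numpy()[perm],
            genes=[scaled.gene_ids[i] for i in perm],
            samples=scaled.sample_ids,
        )
        corr2 = spearman_matrix(shuffled)
        retained2 = filter_clusters(ward_cluster(corr2, 10), corr2)
        assert {frozenset(c.members) for c in retained.clusters} == {
            frozenset(c.members) for c in retained2.clusters
        }

    def test_recorded_stats_reproducible_from_correlations(self, scaled):
        corr = spearman_matrix(scaled)
        retained = filter_clusters(ward_cluster(corr, 10), corr)
        frame = corr.to_frame()
        for c in retained.clusters:
            sub = frame.loc[c.members, c.members].abs().to_numpy()
            vals = sub[np.triu_indices(len(c.members), k=1)]
            assert c.min_abs_rho == pytest.approx(vals.min())
            assert c.median_abs_rho == pytest.approx(np.median(vals))
            assert c.size > 5
            assert c.min_abs_rho >= 0.4
            assert c.median_abs_rho >= 0.5


class TestBootstrapStability:
    def test_clear_modules_stable_and_noise_unstable(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=40)
        module_rows = [w * a + 0.01 * rng.normal(size=40) for w in
                       (1, 1.2, -0.8, 0.9, 1.1, -1.0, 0.7)]
        noise_rows = [rng.normal(size=40) for _ in range(13)]
        expr = make_expr(np.array(module_rows + noise_rows))
        corr = spearman_matrix(expr)
        retained = filter_clusters(ward_cluster(corr, 5), corr)
        assert len(retained) == 1
        stab = bootstrap_stability(expr, k=5, n_boot=20, seed=1, clusters=retained)
        assert list(stab.values())[0] == pytest.approx(1.0)

    def test_deterministic_given_seed(self, scaled):
        s1 = bootstrap_stability(scaled, k=10, n_boot=10, seed=5)
        s2 = bootstrap_stability(scaled, k=10, n_boot=10, seed=5)
        assert s1 == s2


class TestRandomSetNull:
    def test_null_centred_at_zero_on_independent_noise(self):
        rng = np.random.default_rng(11)
        expr = make_expr(rng.normal(size=(40, 40)))
        samples = random_set_rho_null(expr, set_size=8, n_random=10, seed=2)
        pooled = np.concatenate(samples)
        assert abs(pooled.mean()) < 0.05

    def test_true_module_dominates_null(self, scaled, truth):
        members = truth.genes_in_module(0)
        corr = spearman_matrix(scaled.subset_genes(members))
        module_rho = np.abs(corr.rho[np.triu_indices(len(members), k=1)])
        null = np.abs(
            np.concatenate(
                random_set_rho_null(scaled, len(members), n_random=10, seed=3)
            )
        )
        assert np.median(module_rho) > np.quantile(null, 0.95)

    def test_zero_random_sets_empty(self, scaled):
        assert random_set_rho_null(scaled, 5, n_random=0, seed=0) == []


class TestConservedPairs:
    def test_identical_datasets_fully_conserved(self, scaled):
        _pairs, frac = conserved_pair_check(scaled, scaled, rho_threshold=0.8)
        assert frac == 1.0

    def test_per_gene_permutation_destroys_conservation(self, scaled):
        rng = np.random.default_rng(13)
        permuted = scaled.values.apply(
            lambda row: pd.Series(
                rng.permutation(row.to_numpy()), index=row.index
            ),
            axis=1,
        )
        other = make_expr(
            permuted.to_numpy(), genes=scaled.gene_ids, samples=scaled.sample_ids
        )
        _pairs, frac = conserved_pair_check(scaled, other, rho_threshold=0.8)
        assert frac < 0.2

    def test_impossible_threshold_selects_nothing(self, scaled):
        pairs, frac = conserved_pair_check(scaled, scaled, rho_threshold=1.0 + 1e-9)
        assert len(pairs) == 0 and np.isnan(frac)

    def test_disjoint_gene_sets_rejected(self, scaled):
        other = make_expr(
            scaled.values.to_numpy(),
            genes=[f"other_{g}" for g in scaled.gene_ids],
            samples=scaled.sample_ids,
        )
        with pytest.raises(DataFormatError):
            conserved_pair_check(scaled, other)
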