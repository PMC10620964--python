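import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from multiplexdiff import (
    EmbeddingConfig,
    MultiplexNetwork,
    NullDistribution,
    PhenotypeTable,
    SimulationSpec,
    adjust_p,
    build_null,
    empirical_p,
    fisher_combine,
    generate_cohort,
    generate_multiplex,
    kendall_test,
    permute_network,
    scenario1,
    scenario2,
    wilcoxon_test,
)

from conftest import random_symmetric_weights, small_config


# ---------------------------------------------------------------------------
# permutation null models
# ---------------------------------------------------------------------------


class TestPermuteNetwork:
    def test_weight_shuffle_preserves_weight_multiset(self):
        W = random_symmetric_weights(12, 0.5, seed=0)
        P = permute_network(W, "weight_shuffle", seed=1)
        iu = np.triu_indices(12, k=1)
        np.testing.assert_array_equal(np.sort(W[iu]), np.sort(P[iu]))
        np.testing.assert_array_equal(P, P.T)
        assert np.all(np.diag(P) == 0)

    def test_degree_preserving_keeps_degree_sequence(self):
        W = random_symmetric_weights(20, 0.3, seed=2)
        P = permute_network(W, "degree_preserving", seed=3)
        np.testing.assert_array_equal(
            np.sort((W > 0).sum(axis=1)), np.sort((P > 0).sum(axis=1))
        )
        # per-node degrees are preserved exactly, not just as a multiset
        np.testing.assert_array_equal((W > 0).sum(axis=1), (P > 0).sum(axis=1))
        iu = np.triu_indices(20, k=1)
        np.testing.assert_array_equal(
            np.sort(W[iu][W[iu] > 0]), np.sort(P[iu][P[iu] > 0])
        )

    @pytest.mark.parametrize("method", ["weight_shuffle", "degree_preserving"])
    def test_seeded_determinism(self, method):
        W = random_symmetric_weights(15, 0.3, seed=4)
        a = permute_network(W, method, seed=5)
        b = permute_network(W, method, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_degree_preserving_on_complete_graph_errors(self):
        n = 8
        W = np.full((n, n), 0.5)
        np.fill_diagonal(W, 0.0)
        with pytest.raises(ValueError, match="weight_shuffle"):
            permute_network(W, "degree_preserving", seed=0)


# ---------------------------------------------------------------------------
# p-value machinery
# ---------------------------------------------------------------------------


class TestEmpiricalP:
    def test_extreme_with_add_one_correction(self):
        null = NullDistribution(np.linspace(0.0, 1.0, 99))
        assert empirical_p(2.0, null) == pytest.approx(1 / 100)

    def test_smaller_than_all_null(self):
        null = NullDistribution(np.linspace(0.5, 1.0, 10))
        assert empirical_p(0.1, null) == 1.0

    def test_tie_counted_as_geq(self):
        null = NullDistribution(np.array([1.0, 2.0, 3.0]))
        assert empirical_p(2.0, null) == pytest.approx(3 / 4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        d1=st.floats(0.0, 2.0),
        d2=st.floats(0.0, 2.0),
    )
    def test_monotone_nonincreasing_in_d(self, seed, d1, d2):
        rng = np.random.default_rng(seed)
        null = NullDistribution(rng.uniform(0, 2, size=37))
        lo, hi = min(d1, d2), max(d1, d2)
        assert empirical_p(lo, null) >= empirical_p(hi, null)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            NullDistribution(np.array([]))


class TestFisherCombine:
    def test_no_evidence(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        # with df=2, Fisher's method returns the input exactly
        assert fisher_combine([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_two_halves_oracle(self):
        # X = -2(ln .5 + ln .5) = 2.7726; chi2.sf(X, 4)
        expected = stats.chi2.sf(-2 * 2 * np.log(0.5), df=4)
        assert expected == pytest.approx(0.5966, abs=5e-5)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        pvals=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8),
        idx=st.integers(0, 7),
        factor=st.floats(0.1, 1.0),
    )
    def test_permutation_invariant_and_monotone(self, pvals, idx, factor):
        combined = fisher_combine(pvals)
        assert fisher_combine(list(reversed(pvals))) == pytest.approx(combined)
        lowered = list(pvals)
        lowered[idx % len(pvals)] *= factor
        assert fisher_combine(lowered) <= combined + 1e-12


class TestAdjustP:
    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_p([0.01, 0.02], "bonferroni"), [0.02, 0.04]
        )

    def test_none_is_identity(self):
        p = np.array([0.5, 0.01, 1.0])
        np.testing.assert_array_equal(adjust_p(p, "none"), p)

    def test_bh_step_up_oracle(self):
        # hand computation: p_(i) * n / i, then cumulative min from the right
        np.testing.assert_allclose(
            adjust_p([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            adjust_p([0.01, 0.04, 0.03, 0.005], "bh"),
            [0.02, 0.04, 0.04, 0.02],
        )

    def test_holm_oracle(self):
        # sorted: .005*4=.02, .01*3=.03, .03*2=.06, .04*1 -> max-running .06
        np.testing.assert_allclose(
            adjust_p([0.01, 0.04, 0.03, 0.005], "holm"), [0.03, 0.06, 0.06, 0.02]
        )

    def test_equal_inputs_fixed_point_of_bh(self):
        p = np.full(6, 0.2)
        np.testing.assert_allclose(adjust_p(p, "bh"), p)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        pvals=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10),
        idx=st.integers(0, 9),
        bump=st.floats(1.0, 10.0),
    )
    def test_bh_componentwise_monotone(self, pvals, idx, bump):
        p = np.asarray(pvals)
        q0 = adjust_p(p, "bh")
        p2 = p.copy()
        i = idx % len(p)
        p2[i] = min(1.0, p2[i] * bump)
        q1 = adjust_p(p2, "bh")
        assert np.all(q1 >= q0 - 1e-12)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_p([0.5], "tukey")


# ---------------------------------------------------------------------------
# association tests vs exhaustive oracles
# ---------------------------------------------------------------------------


def _exact_ranksum_p(x, y):
    """Enumerate all assignments of the pooled ranks to group x."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    stats_all = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    stats_all = np.array(stats_all)
    return float(np.mean(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-12))


class TestWilcoxon:
    def test_exact_small_case(self):
        assert wilcoxon_test([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(2 / 6)

    def test_no_separation(self):
        assert wilcoxon_test([5, 5, 5, 5], [0, 0, 1, 1]) == 1.0

    def test_label_swap_symmetry(self):
        d = [1.0, 3.0, 2.0, 7.0, 5.0]
        g = [0, 1, 0, 1, 0]
        swapped = [1 - x for x in g]
        assert wilcoxon_test(d, g) == pytest.approx(wilcoxon_test(d, swapped))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, size=2)
        d = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct, no ties
        g = np.array([0] * n1 + [1] * n2)
        expected = _exact_ranksum_p(d[g == 0], d[g == 1])
        assert wilcoxon_test(d, g) == pytest.approx(expected, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_test([1, 2, 3], [0, 1, 1])


def _exact_kendall(d, ph):
    """tau by pair counting; exact p by permuting the phenotype order."""
    n = len(d)
    def tau_stat(a, b):
        conc = disc = 0
        for i, j in itertools.combinations(range(n), 2):
            s = np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
            conc += s > 0
            disc += s < 0
        return (conc - disc) / (n * (n - 1) / 2)
    obs = tau_stat(d, ph)
    taus = [tau_stat(d, np.asarray(perm)) for perm in itertools.permutations(ph)]
    p = np.mean([abs(t) >= abs(obs) - 1e-12 for t in taus])
    return obs, float(p)


class TestKendall:
    def test_perfect_concordance(self):
        tau, _ = kendall_test([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_test([1, 2, 3, 4], [40, 30, 20, 10])
        assert tau == pytest.approx(-1.0)

    def test_matches_brute_force_enumeration(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ph = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        tau_exp, p_exp = _exact_kendall(d, ph)
        tau, p = kendall_test(d, ph)
        assert tau == pytest.approx(tau_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_test([1, 2, 3, 4], [5, 5, 5, 5])

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            kendall_test([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# scenario I
# ---------------------------------------------------------------------------


class TestScenario1:
    def _identical_net(self, n=20, seed=0):
        W = random_symmetric_weights(n, 0.3, seed=seed)
        return MultiplexNetwork(
            [f"n{i:02d}" for i in range(n)], {"a": W.copy(), "b": W.copy()}
        )

    def test_null_identity_all_p_one(self):
        net = self._identical_net()
        tab = scenario1(net, small_config(seed=1), n_perm=5, repeats=2, seed=1)
        assert np.all(tab.mean_distance == 0.0)
        assert np.all(tab.p_per_repeat == 1.0)
        assert np.all(tab.p_combined == 1.0)

    def test_single_repeat_equals_its_empirical_p(self):
        spec = SimulationSpec(n=20, n_planted=2, perturbation_strength=0.9, seed=2)
        net, _ = generate_multiplex(spec)
        tab = scenario1(net, small_config(seed=2), n_perm=5, repeats=1, seed=2)
        np.testing.assert_allclose(tab.p_combined, tab.p_per_repeat[0], atol=1e-12)

    def test_null_count_contract(self):
        spec = SimulationSpec(n=10, n_planted=1, seed=3)
        net, _ = generate_multiplex(spec)
        null = build_null(net, n_perm=2, config=small_config(seed=3, k=2), seed=3)
        assert null.m == 2 * 10
        assert np.all(null.distances >= 0) and np.isfinite(null.distances).all()

    def test_rows_sorted_by_significance(self):
        spec = SimulationSpec(n=15, n_planted=3, perturbation_strength=0.9, seed=4)
        net, _ = generate_multiplex(spec)
        tab = scenario1(net, small_config(seed=4), n_perm=5, repeats=2, seed=4)
        assert list(tab.p_combined) == sorted(tab.p_combined)

    def test_planted_nodes_rank_first(self):
        """Planted nodes beat unperturbed nodes in median significance rank."""
        for seed in range(3):
            spec = SimulationSpec(
                n=100, n_planted=10, perturbation_strength=0.8, seed=seed
            )
            net, truth = generate_multiplex(spec)
            cfg = EmbeddingConfig(seed=seed, k=8, epochs=40, batch_size=512)
            tab = scenario1(net, cfg, n_perm=20, repeats=5, seed=seed)
            ranks = np.arange(len(tab.node_ids))
            mask = truth.mask(tab.node_ids)
            assert np.median(ranks[mask]) < np.median(ranks[~mask])

    def test_per_node_null_scope(self):
        spec = SimulationSpec(n=12, n_planted=2, perturbation_strength=0.9, seed=5)
        net, _ = generate_multiplex(spec)
        tab = scenario1(
            net, small_config(seed=5), n_perm=6, repeats=1, seed=5,
            null_scope="per_node",
        )
        # with n_perm=6 per node, p-values live on the add-one grid {1/7..7/7}
        grid = np.arange(1, 8) / 7
        assert all(any(abs(p - g) < 1e-12 for g in grid) for p in tab.p_per_repeat[0])


# ---------------------------------------------------------------------------
# scenario II
# ---------------------------------------------------------------------------


class TestScenario2:
    def test_identical_multiplexes_give_p_one(self):
        W = random_symmetric_weights(10, 0.4, seed=6)
        net = MultiplexNetwork(
            [f"n{i}" for i in range(10)], {"a": W.copy(), "b": W.copy()}
        )
        nets = [net] * 6
        ids = [f"ind{i}" for i in range(6)]
        pheno = PhenotypeTable(ids, np.array([0, 0, 0, 1, 1, 1.0]), kind="binary")
        tab = scenario2(nets, pheno, individual_ids=ids,
                        config=small_config(seed=6), repeats=2, seed=6)
        assert np.all(tab.p_per_repeat == 1.0)
        assert np.all(tab.p_combined == 1.0)

    def test_planted_group_difference_detected(self):
        """Nodes perturbed only in one phenotype group rank at the top."""
        hits = 0
        for seed in range(3):
            spec = SimulationSpec(
                n=50, n_planted=5, perturbation_strength=0.9, seed=seed
            )
            nets, truth = generate_cohort(spec, 20, perturbed_individuals=range(10, 20))
            ids = [f"ind{i}" for i in range(20)]
            pheno = PhenotypeTable(
                ids, np.array([0.0] * 10 + [1.0] * 10), kind="binary"
            )
            cfg = EmbeddingConfig(seed=seed, k=8, epochs=40, batch_size=512)
            tab = scenario2(nets, pheno, individual_ids=ids, config=cfg,
                            repeats=3, seed=seed)
            top10 = set(tab.node_ids[:10])
            if truth.planted_node_ids <= top10:
                hits += 1
        assert hits >= 2

    def test_shuffled_labels_are_calibrated(self):
        """Phenotype independent of structure: few combined p fall below 0.05."""
        fracs = []
        for seed in range(3):
            spec = SimulationSpec(
                n=50, n_planted=5, perturbation_strength=0.9, seed=seed
            )
            nets, _ = generate_cohort(spec, 40, perturbed_individuals=range(20, 40))
            ids = [f"ind{i}" for i in range(40)]
            rng = np.random.default_rng(100 + seed)
            labels = rng.permutation(np.array([0.0] * 20 + [1.0] * 20))
            pheno = PhenotypeTable(ids, labels, kind="binary")
            cfg = EmbeddingConfig(seed=seed, k=8, epochs=30, batch_size=512)
            tab = scenario2(nets, pheno, individual_ids=ids, config=cfg,
                            repeats=3, adjust_method="none", seed=seed)
            fracs.append(float((tab.p_combined < 0.05).mean()))
        assert 0.0 <= np.mean(fracs) <= 0.12

    def test_node_set_mismatch_reported(self):
        W = random_symmetric_weights(5, 0.5, seed=7)
        net1 = MultiplexNetwork([f"n{i}" for i in range(5)], {"a": W, "b": W})
        net2 = MultiplexNetwork([f"m{i}" for i in range(5)], {"a": W, "b": W})
        ids = ["i0", "i1", "i2", "i3"]
        pheno = PhenotypeTable(ids, np.array([0, 0, 1, 1.0]), kind="binary")
        with pytest.raises(ValueError, match="node sets differ"):
            scenario2([net1, net1, net2, net1], pheno, individual_ids=ids,
                      config=small_config(seed=7, k=2), repeats=1, seed=7)

    def test_continuous_phenotype_uses_kendall(self):
        spec = SimulationSpec(n=20, n_planted=2, perturbation_strength=0.9, seed=8)
        nets, _ = generate_cohort(spec, 8, perturbed_individuals=range(4, 8))
        ids = [f"ind{i}" for i in range(8)]
        pheno = PhenotypeTable(
            ids, np.arange(8, dtype=float), kind="continuous"
        )
        tab = scenario2(nets, pheno, individual_ids=ids,
                        config=small_config(seed=8), repeats=2, seed=8)
        assert tab.metadata["phenotype_kind"] == "continuous"
        assert np.all((tab.p_combined > 0) & (tab.p_combined <= 1))
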