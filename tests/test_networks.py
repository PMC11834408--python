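import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibromics import (
    AbundanceTable,
    CohortDesign,
    PlantedSignal,
    clique_check,
    cooccurrence_network,
    integration_network,
    simulate_abundances,
    spearman,
)
from fibromics.errors import DesignError, DomainError, ParameterError
from fibromics.networks import _s_null_counts, _s_two_sided_table

from conftest import make_table


def enumerate_spearman_p(x, y):
    """Brute-force permutation two-sided p: Pearson on ranks over all n!
    orderings of one vector."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = sps.pearsonr(rx, ry).statistic
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        count += abs(sps.pearsonr(rx, np.asarray(perm)).statistic) >= abs(obs) - 1e-12
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [10, 20, 30, 40, 50]).rho == pytest.approx(1.0)
        assert spearman(x, [5, 4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert spearman(x, y) == spearman(y, x)

    def test_exact_p_matches_brute_force_n5(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.normal(size=5), rng.normal(size=5)
            r = spearman(x, y)
            assert r.exact
            assert r.p == pytest.approx(enumerate_spearman_p(x, y), abs=1e-12)

    def test_exact_p_with_ties_matches_brute_force(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 2.0, 5.0, 3.0]
        r = spearman(x, y)
        assert r.p == pytest.approx(enumerate_spearman_p(x, y), abs=1e-12)

    def test_tiefree_dp_null_matches_enumeration(self):
        """The subset-DP null of S = Σd² equals full enumeration for n ≤ 7."""
        for n in (5, 6, 7):
            from collections import Counter

            ref = Counter(
                sum((i - p[i]) ** 2 for i in range(n))
                for p in itertools.permutations(range(n))
            )
            counts = _s_null_counts(n)
            assert counts.sum() == math.factorial(n)
            for s, c in ref.items():
                assert counts[s] == c

    def test_exact_tiefree_path_at_n12_matches_scipy_rho(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.exact
        assert r.rho == pytest.approx(ref.statistic, abs=1e-12)
        # exact p and t-approximation agree to first order
        assert r.p == pytest.approx(ref.pvalue, rel=0.35, abs=0.02)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_length_preconditions(self):
        with pytest.raises(ParameterError):
            spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(ParameterError):
            spearman([1, 2, 3, 4], [1, 2, 3])


class TestCooccurrence:
    def make_null_table(self, seed, n_feat=30, n=14):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0, 1, size=(n_feat, n))
        breeds = ["MS"] * n
        diets = ["CON"] * (n // 2) + ["WB-10.5"] * (n - n // 2)
        return make_table(vals, breeds, diets)

    def test_identical_rank_profiles_give_positive_edge(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(0, 1, size=14)
        vals = np.vstack([base, base * 3.0, rng.lognormal(0, 1, size=14)])
        table = make_table(vals, ["MS"] * 14, ["CON"] * 7 + ["WB-10.5"] * 7)
        net = cooccurrence_network(table, "MS", prevalence_min=0.0)
        assert net.graph.has_edge("f0", "f1")
        assert net.graph.edges["f0", "f1"]["sign"] == "positive"
        assert net.graph.edges["f0", "f1"]["rho"] == pytest.approx(1.0)

    def test_every_edge_beats_alpha_and_sign_matches_rho(self):
        net = cooccurrence_network(self.make_null_table(5), "MS", alpha=0.3,
                                   prevalence_min=0.0)
        e = net.edges
        assert (e["p"] < 0.3).all()
        assert ((e["rho"] > 0) == (e["sign"] == "positive")).all()

    def test_node_size_is_mean_relative_abundance(self):
        table = self.make_null_table(6)
        net = cooccurrence_network(table, "MS", prevalence_min=0.0)
        sub = table.values[table.samples_of("MS")]
        for node, data in net.graph.nodes(data=True):
            assert data["size"] == pytest.approx(sub.loc[node].mean())

    def test_feature_order_does_not_change_network(self):
        table = self.make_null_table(7)
        shuffled = AbundanceTable(
            table.values.sample(frac=1.0, random_state=1), table.metadata.copy()
        )
        n1 = cooccurrence_network(table, "MS", prevalence_min=0.0)
        n2 = cooccurrence_network(shuffled, "MS", prevalence_min=0.0)
        edges1 = {frozenset(e) for e in n1.graph.edges}
        edges2 = {frozenset(e) for e in n2.graph.edges}
        assert edges1 == edges2

    def test_too_few_samples_is_design_error(self):
        vals = np.ones((3, 3)) + np.arange(3)[:, None]
        table = make_table(vals, ["MS"] * 3, ["CON"] * 3)
        with pytest.raises(DesignError):
            cooccurrence_network(table, "MS")


class TestIntegration:
    def layered_data(self, seed=8, n=14):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        butyrate = rng.lognormal(0, 0.5, size=n)
        gene_follow = np.exp(2.0 * np.log(butyrate)) * rng.lognormal(0, 0.05, size=n)
        genes = pd.DataFrame(
            {s: v for s, v in zip(samples, np.vstack([gene_follow, rng.lognormal(0, 1, n)]).T)},
            index=["geneA", "geneB"],
        )
        scfas = pd.DataFrame(
            {s: v for s, v in zip(samples, np.vstack([butyrate, rng.lognormal(0, 1, n)]).T)},
            index=["butyrate", "acetate"],
        )
        return genes, scfas

    def test_constructed_monotone_dependence_found(self):
        genes, scfas = self.layered_data()
        net = integration_network({"host_gene": genes, "scfa": scfas}, alpha=0.01)
        assert net.graph.has_edge("geneA", "butyrate")
        assert net.graph.edges["geneA", "butyrate"]["sign"] == "positive"

    def test_alpha_one_keeps_every_cross_layer_pair(self):
        genes, scfas = self.layered_data()
        net = integration_network({"host_gene": genes, "scfa": scfas}, alpha=1.0)
        assert net.graph.number_of_edges() == 4  # 2 genes × 2 acids

    def test_permuted_layer_collapses_edges(self):
        genes, scfas = self.layered_data()
        rng = np.random.default_rng(9)
        edge_counts = []
        for _ in range(20):
            perm = rng.permutation(scfas.columns)
            shuffled = pd.DataFrame(
                scfas.to_numpy(), index=scfas.index, columns=perm
            )
            net = integration_network({"host_gene": genes, "scfa": shuffled}, alpha=0.05)
            edge_counts.append(net.graph.number_of_edges())
        # 4 pairs at alpha 0.05 → ≈0.2 edges per replicate on average
        assert np.mean(edge_counts) < 1.0

    def test_empty_intersection_rejected(self):
        genes = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd"))
        scfas = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["x"], columns=list("efgh"))
        with pytest.raises(ParameterError):
            integration_network({"host_gene": genes, "scfa": scfas})


class TestCliqueCheck:
    def make_net(self, flip_one=False):
        rng = np.random.default_rng(10)
        base = rng.lognormal(0, 1, size=14)
        noise = rng.lognormal(0, 0.1, size=(3, 14))
        vals = np.vstack([base * noise[0], base * noise[1], base * noise[2]])
        if flip_one:
            vals[2] = 1.0 / vals[2]
        table = make_table(vals, ["MS"] * 14, ["CON"] * 7 + ["WB-10.5"] * 7)
        return cooccurrence_network(table, "MS", prevalence_min=0.0)

    def test_singleton_vacuously_true(self):
        ok, audit = clique_check(self.make_net(), ["f0"])
        assert ok and audit.empty

    def test_positive_triangle_then_flip(self):
        ok, audit = clique_check(self.make_net(), ["f0", "f1", "f2"])
        assert ok and len(audit) == 3
        ok_flip, audit_flip = clique_check(self.make_net(flip_one=True), ["f0", "f1", "f2"])
        assert not ok_flip
        assert not audit_flip["positive"].all()

    def test_unknown_node_rejected(self):
        with pytest.raises(ParameterError):
            clique_check(self.make_net(), ["f0", "nope"])

    def test_planted_latent_clique_recovered_and_destroyed_by_shuffling(self):
        sig = PlantedSignal(clique_size=4)
        table, truth = simulate_abundances(CohortDesign.screen_design(seed=3), sig)
        clique = list(truth.index[truth["clique"]])
        net = cooccurrence_network(table, "MS", prevalence_min=0.5)
        ok, _ = clique_check(net, clique)
        assert ok
        # independently shuffling each clique species breaks the co-occurrence
        rng = np.random.default_rng(0)
        ms = table.samples_of("MS")
        shuffled = table.values.copy()
        for sp in clique:
            shuffled.loc[sp, ms] = rng.permutation(shuffled.loc[sp, ms].to_numpy())
        net2 = cooccurrence_network(
            AbundanceTable(shuffled, table.metadata.copy()), "MS", prevalence_min=0.5
        )
        ok2, _ = clique_check(net2, clique)
        assert not ok2
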