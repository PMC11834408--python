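import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fibromics import (
    ScreenCriteria,
    bh_fdr,
    log2_fold_change,
    mann_whitney,
    screen_genes,
    screen_species,
)
from fibromics.errors import DesignError, DomainError, ParameterError

from conftest import make_table


# ----------------------------------------------------------------------
# Independent oracles
# ----------------------------------------------------------------------

def enumerate_mw_p(a, b, alternative):
    """Exhaustive relabeling null: every C(n1+n2, n1) assignment of the
    pooled values to group a, U computed from rank sums each time."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    if alternative == "less":
        return np.mean(us <= u_obs)
    if alternative == "greater":
        return np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


def stepup_fdr(p):
    """Hand-written BH step-up: q_(i) = min_{j≥i} p_(j)·m/j, via double loop."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


# ----------------------------------------------------------------------
# Mann-Whitney
# ----------------------------------------------------------------------

class TestMannWhitney:
    def test_all_ties_give_p_one(self):
        r = mann_whitney([3.0] * 5, [3.0] * 5)
        assert r.p == 1.0

    def test_fully_separated_seven_vs_seven(self):
        """Complete separation at n=7 per group: two-sided p = 2/C(14,7)."""
        a = np.arange(7.0)
        b = np.arange(7.0) + 100
        r = mann_whitney(a, b)
        assert r.exact
        assert r.p == pytest.approx(2 / 3432, abs=1e-15)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(size=8)
        assert mann_whitney(a, b).p == pytest.approx(mann_whitney(b, a).p)

    @pytest.mark.parametrize("n1", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("n2", [2, 3, 4, 5, 6])
    def test_exact_p_equals_enumeration(self, n1, n2):
        """Exact path must reproduce exhaustive relabeling for all n ≤ 6."""
        rng = np.random.default_rng(100 * n1 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2) + 0.5
        for alt in ("two-sided", "less", "greater"):
            r = mann_whitney(a, b, alt)
            assert r.exact
            assert r.p == pytest.approx(enumerate_mw_p(a, b, alt), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a, b = rng.normal(size=7), rng.normal(size=7) + 1
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.u == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tied_data_uses_corrected_approximation(self):
        rng = np.random.default_rng(2)
        a = np.round(rng.normal(size=10), 1)
        b = np.round(rng.normal(size=10) + 0.3, 1)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert not ours.exact
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_or_singleton_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0, 2.0])
        with pytest.raises(ParameterError):
            mann_whitney([1.0], [1.0, 2.0])


# ----------------------------------------------------------------------
# BH-FDR and fold change
# ----------------------------------------------------------------------

class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_stepup_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_matches_independent_stepup_and_dominates_p(self, p):
        q = bh_fdr(p)
        assert q == pytest.approx(stepup_fdr(p), abs=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_fdr(p) == pytest.approx(ref, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.5])


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change([2, 2], [2, 2]) == 0.0

    def test_fourfold_with_small_pseudocount(self):
        assert log2_fold_change([400.0], [100.0], pseudocount=1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_antisymmetry(self):
        a, b = [3.0, 5.0], [1.0, 2.0]
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))

    def test_zero_means_need_pseudocount(self):
        with pytest.raises(DomainError):
            log2_fold_change([0.0], [1.0], pseudocount=0.0)


# ----------------------------------------------------------------------
# Species screen
# ----------------------------------------------------------------------

def build_screen_table(rng, n_feat=20, n=7, depleted=(), zero_ms=()):
    """Exchangeable lognormal table with optional planted LW depletion or
    a forced zero in one MS sample."""
    vals = rng.lognormal(0, 0.4, size=(n_feat, 4 * n))
    for f in depleted:
        vals[f, 3 * n :] /= 16.0  # LW-WB-10.5 block
    for f in zero_ms:
        vals[f, 0] = 0.0  # first MS-CON sample
    breeds = ["MS"] * (2 * n) + ["LW"] * (2 * n)
    diets = (["CON"] * n + ["WB-10.5"] * n) * 2
    return make_table(vals, breeds, diets)


class TestSpeciesScreen:
    def test_prevalence_gate_blocks_absent_species(self):
        rng = np.random.default_rng(21)
        table = build_screen_table(rng, depleted=[0, 1], zero_ms=[1])
        out = screen_species(table)
        assert not out.table.iloc[1]["prevalent"]
        assert not out.table.iloc[1]["pass"]  # fails regardless of the tests
        assert out.table.iloc[0]["pass"]  # depleted + prevalent passes

    def test_audit_trail_consistency(self):
        rng = np.random.default_rng(22)
        out = screen_species(build_screen_table(rng, depleted=[0]))
        t = out.table
        expected = t["prevalent"] & t["ms_stable"] & t["lw_significant"]
        assert (t["pass"] == expected).all()
        assert t.loc[t["pass"], "direction_lw"].eq("down").all()

    def test_missing_group_is_design_error(self):
        rng = np.random.default_rng(23)
        vals = rng.lognormal(0, 0.3, size=(3, 6))
        table = make_table(vals, ["MS"] * 6, ["CON"] * 3 + ["WB-10.5"] * 3)
        with pytest.raises(DesignError):
            screen_species(table)

    def test_stricter_thresholds_never_enlarge_candidate_set(self):
        rng = np.random.default_rng(24)
        table = build_screen_table(rng, n_feat=60, depleted=range(10))
        base = set(screen_species(table, ScreenCriteria()).passed)
        stricter_lw = set(
            screen_species(table, ScreenCriteria(alpha_lw=0.001)).passed
        )
        stricter_ms = set(
            screen_species(table, ScreenCriteria(alpha_ms=0.2)).passed
        )
        assert stricter_lw <= base
        assert stricter_ms <= base

    def test_null_pass_rate_bounded_by_alpha_lw(self):
        """Exchangeable features: overall pass rate < alpha_lw over replicates."""
        rng = np.random.default_rng(25)
        crit = ScreenCriteria(require_prevalence=False)
        passes = total = 0
        for _ in range(25):
            out = screen_species(build_screen_table(rng, n_feat=40), crit)
            passes += out.table["pass"].sum()
            total += 40
        rate = passes / total
        assert rate <= 0.01 + 1.96 * math.sqrt(0.01 * 0.99 / total)


# ----------------------------------------------------------------------
# Gene screen
# ----------------------------------------------------------------------

class TestGeneScreen:
    def make_counts(self, rng, n_genes=40, n=7, shifted=()):
        mu = rng.lognormal(np.log(150), 0.3, size=n_genes)
        vals = rng.poisson(mu[:, None], size=(n_genes, 4 * n)).astype(float)
        for g in shifted:
            vals[g, 3 * n :] = rng.poisson(mu[g] * 8, size=n)  # LW high-fiber up
        breeds = ["MS"] * (2 * n) + ["LW"] * (2 * n)
        diets = (["CON"] * n + ["WB-10.5"] * n) * 2
        return make_table(vals, breeds, diets)

    def test_effect_size_gate(self):
        """A gene with tiny fold change fails even at minuscule FDR."""
        rng = np.random.default_rng(31)
        counts = self.make_counts(rng, shifted=[0])
        out = screen_genes(counts, ScreenCriteria(log2fc_threshold=5.0))
        assert not out.table.iloc[0]["pass"]
        relaxed = screen_genes(counts, ScreenCriteria(log2fc_threshold=1.0))
        assert relaxed.table.iloc[0]["pass"]

    def test_partition_union_is_candidate_set(self):
        rng = np.random.default_rng(32)
        out = screen_genes(self.make_counts(rng, shifted=[0, 1, 2]))
        assert len(out.up) + len(out.down) == len(out)
        assert set(out.up) | set(out.down) == set(out.passed)

    def test_up_down_signs_match_fold_change(self):
        rng = np.random.default_rng(33)
        out = screen_genes(self.make_counts(rng, shifted=[0, 1]))
        t = out.table
        assert (t.loc[out.up, "log2fc_lw"] > 0).all()
        assert (t.loc[out.down, "log2fc_lw"] < 0).all()

    def test_raising_fc_threshold_never_enlarges(self):
        rng = np.random.default_rng(34)
        counts = self.make_counts(rng, shifted=[0, 1, 2, 3])
        base = set(screen_genes(counts, ScreenCriteria(log2fc_threshold=1.0)).passed)
        strict = set(screen_genes(counts, ScreenCriteria(log2fc_threshold=2.5)).passed)
        assert strict <= base
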