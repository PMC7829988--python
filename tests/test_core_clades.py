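"""Clade abundance agglomeration, permutation null, and core calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coreclades.asv_table import AsvCountTable, rarefy
from coreclades.core_clades import (
    NullMoments,
    call_core,
    clade_abundance,
    clade_prevalence,
    find_core_clades,
    permutation_null,
)
from coreclades.phylo import enumerate_clades, parse_newick
from coreclades.synthetic_data import SimulationConfig, simulate_dataset, simulate_tree


def random_table(tips, n_samples, rng, sparsity=0.5, max_count=20):
    counts = rng.integers(0, max_count, size=(n_samples, len(tips)))
    counts[rng.random(counts.shape) < sparsity] = 0
    return AsvCountTable(
        counts=pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n_samples)], columns=tips
        )
    )


def bruteforce_clade_abundance(tree, table):
    """Naive per-clade tip-sum double loop (independent oracle)."""
    out = {}
    for clade in enumerate_clades(tree):
        sums = []
        for sid in table.sample_ids:
            total = 0
            for tip in clade.tip_set:
                total += int(table.counts.loc[sid, tip])
            sums.append(total)
        out[clade.clade_id] = sums
    return out


class TestCladeAbundance:
    def test_two_term_sum(self, four_tip_tree, small_table):
        mat = clade_abundance(four_tip_tree, small_table)
        ab = next(
            c.clade_id
            for c in enumerate_clades(four_tip_tree)
            if c.tip_set == frozenset("AB")
        )
        assert mat.abundance.loc[ab, "s1"] == 5
        assert mat.abundance.loc[ab, "s3"] == 2

    def test_root_equals_sample_totals_after_rarefaction(self, rng):
        phy = simulate_tree(12, seed=0)
        table = random_table(phy.tip_labels, 6, rng, sparsity=0.0, max_count=200)
        rare = rarefy(table, depth=300, seed=1)
        phy = phy.prune_to(rare.asv_ids, on_extra="warn")
        mat = clade_abundance(phy, rare)
        root_id = max(
            enumerate_clades(phy), key=lambda c: c.n_tips
        ).clade_id
        assert (mat.abundance.loc[root_id] == 300).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        phy = simulate_tree(int(rng.integers(5, 30)), seed=seed)
        table = random_table(phy.tip_labels, int(rng.integers(3, 12)), rng)
        mat = clade_abundance(phy, table)
        oracle = bruteforce_clade_abundance(phy, table)
        for cid, sums in oracle.items():
            assert list(mat.abundance.loc[cid]) == sums

    def test_nested_parent_dominates_child(self, rng):
        phy = simulate_tree(15, seed=3)
        table = random_table(phy.tip_labels, 8, rng)
        mat = clade_abundance(phy, table)
        clades = {c.clade_id: c.tip_set for c in enumerate_clades(phy)}
        for c1, c2 in itertools.combinations(clades, 2):
            if clades[c1] < clades[c2]:
                assert (
                    mat.abundance.loc[c2] >= mat.abundance.loc[c1]
                ).all()

    def test_missing_tip_raises(self, four_tip_tree):
        table = AsvCountTable(
            counts=pd.DataFrame([[1, 1]], index=["s1"], columns=["A", "B"])
        )
        with pytest.raises(KeyError):
            clade_abundance(four_tip_tree, table)


class TestCladePrevalence:
    def test_simple_fraction(self, four_tip_tree, small_table):
        mat = clade_abundance(four_tip_tree, small_table)
        prev = clade_prevalence(mat)
        cd = next(
            c.clade_id
            for c in enumerate_clades(four_tip_tree)
            if c.tip_set == frozenset("CD")
        )
        # C or D nonzero in s1, s3, s4
        assert prev[cd] == pytest.approx(0.75)

    def test_all_zero_clade(self, four_tip_tree):
        counts = pd.DataFrame(
            [[1, 1, 0, 0], [2, 0, 0, 0]], index=["s1", "s2"], columns=list("ABCD")
        )
        mat = clade_abundance(four_tip_tree, AsvCountTable(counts=counts))
        prev = clade_prevalence(mat)
        cd = next(
            c.clade_id
            for c in enumerate_clades(four_tip_tree)
            if c.tip_set == frozenset("CD")
        )
        assert prev[cd] == 0.0

    def test_empty_selection_raises(self, four_tip_tree, small_table):
        mat = clade_abundance(four_tip_tree, small_table)
        with pytest.raises(ValueError):
            clade_prevalence(mat, sample_filter=[])


def exhaustive_null_moments(tree, table):
    """Exact null moments over all tip-label permutations (oracle)."""
    tips = tree.tip_labels
    presence = (table.counts[tips].to_numpy() > 0).T
    clades = enumerate_clades(tree)
    prevs = {c.clade_id: [] for c in clades}
    pos = {t: i for i, t in enumerate(tips)}
    for perm in itertools.permutations(range(len(tips))):
        for c in clades:
            rows = [perm[pos[t]] for t in c.tip_set]
            prev = presence[rows].any(axis=0).mean()
            prevs[c.clade_id].append(prev)
    return {
        cid: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for cid, v in prevs.items()
    }


class TestPermutationNull:
    def test_full_clade_invariant_sd_zero(self, four_tip_tree, small_table):
        null = permutation_null(four_tip_tree, small_table, n_perm=50, seed=0)
        root_id = max(
            enumerate_clades(four_tip_tree), key=lambda c: c.n_tips
        ).clade_id
        assert null[root_id].null_sd == 0.0

    def test_everything_present_gives_prevalence_one(self, four_tip_tree):
        counts = pd.DataFrame(
            np.ones((3, 4), dtype=int), index=["s1", "s2", "s3"], columns=list("ABCD")
        )
        table = AsvCountTable(counts=counts)
        null = permutation_null(four_tip_tree, table, n_perm=20, seed=0)
        for nm in null.values():
            assert nm.null_mean == 1.0
            assert nm.null_sd == 0.0

    def test_montecarlo_matches_exhaustive_on_5_tips(self, rng):
        phy = simulate_tree(5, seed=11)
        table = random_table(phy.tip_labels, 4, rng, sparsity=0.4)
        exact = exhaustive_null_moments(phy, table)
        n_perm = 5000
        mc = permutation_null(phy, table, n_perm=n_perm, seed=5)
        for cid, (mean_exact, sd_exact) in exact.items():
            se_mean = sd_exact / np.sqrt(n_perm)
            assert abs(mc[cid].null_mean - mean_exact) <= 3 * se_mean + 1e-12
            se_sd = sd_exact / np.sqrt(2 * n_perm)
            assert abs(mc[cid].null_sd - sd_exact) <= 3 * se_sd + 1e-12

    def test_equal_size_clades_share_null(self, rng):
        # exchangeability: null depends only on clade tip count
        phy = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        table = random_table(phy.tip_labels, 30, rng, sparsity=0.6)
        null = permutation_null(phy, table, n_perm=4000, seed=9)
        cherries = [
            c.clade_id for c in enumerate_clades(phy) if c.n_tips == 2
        ]
        means = [null[c].null_mean for c in cherries]
        sds = [null[c].null_sd for c in cherries]
        mc_se = max(sds) / np.sqrt(4000)
        assert max(means) - min(means) <= 6 * mc_se

    def test_deterministic_for_seed(self, four_tip_tree, small_table):
        a = permutation_null(four_tip_tree, small_table, n_perm=99, seed=3)
        b = permutation_null(four_tip_tree, small_table, n_perm=99, seed=3)
        assert all(
            a[c].null_mean == b[c].null_mean and a[c].null_sd == b[c].null_sd
            for c in a
        )


class TestCallCore:
    def test_observed_at_null_mean_is_not_core(self):
        res = call_core(
            {"node1": 0.5}, {"node1": NullMoments(0.5, 0.1, n_perm=999)}
        )
        (r,) = res
        assert r.z == 0.0
        assert r.p == pytest.approx(0.5)
        assert not r.is_core

    def test_z_1645_gives_p_005(self):
        res = call_core(
            {"node1": 0.6645}, {"node1": NullMoments(0.5, 0.1, n_perm=999)}
        )
        assert res[0].p == pytest.approx(0.05, abs=5e-4)

    def test_sd_zero_conventions(self):
        res = call_core(
            {"node1": 0.9, "node2": 0.5},
            {
                "node1": NullMoments(0.5, 0.0, n_perm=999),
                "node2": NullMoments(0.5, 0.0, n_perm=999),
            },
        )
        by_id = {r.clade_id: r for r in res}
        assert by_id["node1"].p == pytest.approx(1 / 1000)
        assert by_id["node2"].p == 1.0

    def test_q_at_least_p_and_core_implies_elevated(self, rng):
        obs = {f"node{i}": float(rng.random()) for i in range(40)}
        null = {
            c: NullMoments(0.3, 0.15, n_perm=999) for c in obs
        }
        res = call_core(obs, null)
        for r in res:
            assert r.q >= r.p - 1e-12
            if r.is_core:
                assert r.observed_prevalence > r.null_mean

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError):
            call_core({"a": 0.5}, {"b": NullMoments(0.1, 0.1)})


class TestEndToEnd:
    def test_full_pipeline_on_tiny_tree_matches_exhaustive(self, rng):
        """z/p from Monte-Carlo moments agree with exhaustive-permutation
        moments on a 5-tip tree, and the same clades are called."""
        phy = simulate_tree(5, seed=21)
        table = random_table(phy.tip_labels, 6, rng, sparsity=0.5)
        observed = clade_prevalence(clade_abundance(phy, table))
        exact = exhaustive_null_moments(phy, table)
        exact_mom = {
            cid: NullMoments(m, s, n_perm=5000) for cid, (m, s) in exact.items()
        }
        mc = permutation_null(phy, table, n_perm=5000, seed=2)
        res_exact = {r.clade_id: r for r in call_core(observed, exact_mom)}
        res_mc = {r.clade_id: r for r in call_core(observed, mc)}
        for cid in res_exact:
            assert res_exact[cid].is_core == res_mc[cid].is_core

    def test_planted_core_is_recovered(self):
        # power requires planted-core members to be a small fraction of all
        # tips, as in real amplicon collections where most ASVs are rare
        cfg = SimulationConfig(
            n_tips=1500,
            n_studies=2,
            samples_per_study=(40, 40),
            depth_mean=5000.0,
            n_core_clades=3,
            seed=17,
        )
        tree, table, meta, truth = simulate_dataset(cfg)
        rare = rarefy(table, depth=1000, seed=17)
        pruned = tree.prune_to(rare.asv_ids, on_extra="warn")
        meta = meta.loc[rare.sample_ids]
        results, _ = find_core_clades(
            pruned, rare, meta, n_perm=499, seed=17
        )
        from coreclades.synthetic_data import score_core_recovery

        score = score_core_recovery(truth, tree, results, pruned)
        assert score["sensitivity"] >= 2 / 3
        assert score["fdp"] <= 0.1
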