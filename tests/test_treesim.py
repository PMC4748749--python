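"""Forward simulator: conditioning on n, fossilization, sampling, pruning."""

import numpy as np
import pytest
from scipy.stats import kstest

from fbdsky.simulate import (CompleteTree, FossilEvent, prune_to_fbd,
                             sample_extant, sample_fossils_at_horizon,
                             sample_fossils_poisson, simulate_complete_tree,
                             simulate_fbd_tree)
from fbdsky.tree import FBDNode


class TestCompleteTreeSimulation:
    def test_exact_extant_count(self, rng):
        for n in (2, 10, 100):
            tree = simulate_complete_tree(0.3, 0.2, n, rng)
            assert len(tree.extant_tips()) == n

    def test_determinism_under_fixed_seed(self):
        t1 = simulate_complete_tree(0.3, 0.2, 20, np.random.default_rng(99))
        t2 = simulate_complete_tree(0.3, 0.2, 20, np.random.default_rng(99))
        a1 = sorted(n.age for n in t1.preorder())
        a2 = sorted(n.age for n in t2.preorder())
        assert a1 == a2
        assert t1.origin_age == t2.origin_age

    def test_yule_two_tip_crown_age_distribution(self, rng):
        """Under pure birth with n = 2, the stopping time is uniform within
        the single two-lineage epoch, so the crown age is U * W with
        W ~ Exp(2 lambda) and U uniform:
        F(x) = 1 - exp(-2 lam x) + 2 lam x E1(2 lam x)."""
        from scipy.special import exp1
        lam = 0.5
        ages = np.array([
            simulate_complete_tree(lam, 0.0, 2, np.random.default_rng(s),
                                   ).root.age
            for s in range(3000)])

        def cdf_fn(x):
            x = np.asarray(x, float)
            z = 2 * lam * x
            return np.where(z > 0, 1 - np.exp(-z) + z * exp1(np.maximum(z, 1e-300)),
                            0.0)

        res = kstest(ages, cdf_fn)
        assert res.pvalue > 0.01

    def test_lineage_counts_consistent_through_time(self):
        """Crossing counts equal the extant count near the present, never
        exceed it anywhere above the crown for a pure-birth tree, and extinct
        tips sit strictly above the present for death > 0."""
        tree = simulate_complete_tree(0.5, 0.0, 40, np.random.default_rng(3))
        near_present = sum(1 for node, top in tree.segments()
                           if node.age < 1e-12 < top)
        assert near_present + sum(
            1 for n in tree.preorder() if n.is_tip and n.age == 0.0
            and n.parent.age <= 1e-12) == 40
        # pure birth: the count is monotone toward the present
        probes = np.linspace(1e-9, tree.root.age, 25)
        counts = [sum(1 for node, top in tree.segments()
                      if node.age < p < top) for p in probes]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        tree_bd = simulate_complete_tree(0.3, 0.2, 20,
                                         np.random.default_rng(4))
        extinct = [n for n in tree_bd.preorder() if n.is_tip and n.age > 0]
        assert all(n.age > 0 for n in extinct)

    def test_rejects_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            simulate_complete_tree(0.3, 0.2, 1, rng)
        with pytest.raises(ValueError):
            simulate_complete_tree(0.0, 0.2, 5, rng)


class TestFossilization:
    def test_zero_rate_yields_no_fossils(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 20, rng)
        assert sample_fossils_poisson(tree, 0.0, rng) == []

    def test_poisson_mean_matches_total_branch_length(self):
        psi = 0.1
        counts, lengths = [], []
        for s in range(300):
            rng = np.random.default_rng(s)
            tree = simulate_complete_tree(0.3, 0.2, 30, rng)
            events = sample_fossils_poisson(tree, psi, rng)
            counts.append(len(events))
            lengths.append(tree.total_branch_length())
        counts = np.array(counts, float)
        expected = psi * np.mean(lengths)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_skyline_rate_respects_zero_interval(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 30, rng)
        x_cut = tree.root.age / 3
        events = sample_fossils_poisson(tree, [0.1, 0.0], rng,
                                        shift_ages=[x_cut, 0.0])
        assert all(ev.age >= x_cut for ev in events)

    def test_horizon_sampling_binomial_mean(self):
        prob = 0.5
        frac = []
        for s in range(200):
            rng = np.random.default_rng(s)
            tree = simulate_complete_tree(0.3, 0.2, 40, rng)
            t_h = tree.root.age / 2
            crossing = sum(1 for node, top in tree.segments()
                           if node.age < t_h < top)
            events = sample_fossils_at_horizon(tree, t_h, prob, rng)
            if crossing:
                frac.append(len(events) / crossing)
        frac = np.array(frac)
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - prob) < 3 * se

    def test_horizon_above_root_samples_nothing(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 10, rng)
        events = sample_fossils_at_horizon(tree, tree.origin_age + 5.0, 1.0,
                                           rng)
        assert events == []


class TestExtantSampling:
    def test_full_fraction_keeps_everything(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 25, rng)
        for mode in ("random", "diversified"):
            kept, _ = sample_extant(tree, mode, 1.0, rng)
            assert len(kept) == 25

    def test_random_mode_is_binomial(self):
        kept_counts = [
            len(sample_extant(simulate_complete_tree(
                0.3, 0.2, 100, np.random.default_rng(s)),
                "random", 0.5, np.random.default_rng(s + 1))[0])
            for s in range(200)]
        kept_counts = np.array(kept_counts, float)
        se = kept_counts.std(ddof=1) / np.sqrt(len(kept_counts))
        assert abs(kept_counts.mean() - 50.0) < 3 * se

    def test_diversified_exact_count_and_mrca_depth(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 100, rng)
        kept, x_cut = sample_extant(tree, "diversified", 0.5, rng)
        assert len(kept) == 50
        assert x_cut is not None and x_cut > 0
        # every retained pair's MRCA must be older than the cutoff
        parent_of = {}
        for node in tree.preorder():
            for c in node.children:
                parent_of[id(c)] = node
        kept_ids = {id(k) for k in kept}

        def path_to_root(tip):
            out = [tip]
            while id(out[-1]) in parent_of:
                out.append(parent_of[id(out[-1])])
            return out

        paths = [path_to_root(k) for k in kept[:10]]
        for i in range(len(paths)):
            for j in range(i + 1, len(paths)):
                shared = {id(n) for n in paths[i]} & {id(n) for n in paths[j]}
                mrca_age = min(n.age for n in paths[i] if id(n) in shared)
                assert mrca_age > x_cut

    def test_too_small_fraction_raises(self, rng):
        tree = simulate_complete_tree(0.3, 0.2, 10, rng)
        with pytest.raises(ValueError):
            sample_extant(tree, "diversified", 0.1, rng)


class TestPruning:
    @staticmethod
    def _three_lineage_complete():
        """Origin at 10; crown at 8; one side goes extinct at 3."""
        a = FBDNode(0.0, "a")
        b = FBDNode(0.0, "b")
        dead = FBDNode(3.0)            # extinct tip
        inner = FBDNode(6.0, children=[a, b])
        root = FBDNode(8.0, children=[inner, dead])
        return CompleteTree(root, origin_age=10.0)

    def test_identity_when_everything_sampled_and_no_fossils(self):
        ct = self._three_lineage_complete()
        tips = [n for n in ct.extant_tips()]
        fbd = prune_to_fbd(ct, [], tips)
        assert len(fbd.extant_tips()) == 2
        assert fbd.root.age == 6.0     # the extinct side is pruned away
        assert fbd.fossils() == []

    def test_fossil_on_extinct_branch_becomes_tip(self):
        ct = self._three_lineage_complete()
        dead = next(n for n in ct.preorder() if n.is_tip and n.age == 3.0)
        ev = FossilEvent(dead, 5.0)
        fbd = prune_to_fbd(ct, [ev], ct.extant_tips())
        fossils = fbd.fossils()
        assert len(fossils) == 1
        f = fossils[0]
        assert not f.is_sampled_ancestor
        assert f.age == 5.0
        assert f.parent.age == 8.0     # attaches at the true branching

    def test_fossil_above_sampled_tip_becomes_sampled_ancestor(self):
        ct = self._three_lineage_complete()
        a = next(n for n in ct.extant_tips() if n.label == "a")
        ev = FossilEvent(a, 2.0)
        fbd = prune_to_fbd(ct, [ev], ct.extant_tips())
        f = fbd.fossils()[0]
        assert f.is_sampled_ancestor
        assert f.age == 2.0 and f.parent.age == 2.0

    def test_fewer_than_two_samples_raises(self):
        ct = self._three_lineage_complete()
        with pytest.raises(ValueError):
            prune_to_fbd(ct, [], ct.extant_tips()[:1])


class TestStrategySimulations:
    @pytest.mark.parametrize("strategy", [1, 2, 3, 4])
    def test_each_strategy_produces_consistent_output(self, strategy):
        res = simulate_fbd_tree(strategy, np.random.default_rng(5 + strategy),
                                n_extant=40)
        tree = res.tree
        assert res.shift_ages[-1] == 0.0
        assert tree.root.sa_child is None
        if strategy in (3, 4):
            assert res.x_cut is not None
            assert res.eta_l == 40 - len(tree.extant_tips())
            assert all(f.age > res.x_cut for f in tree.fossils())
            assert all(n.age > res.x_cut for n in tree.true_branchings())
        if strategy in (2, 4):
            horizon = [f for f in tree.fossils()
                       if f.fossil.kind == "horizon"]
            assert all(f.age == 10.0 for f in horizon)

    def test_strategy_determinism(self):
        r1 = simulate_fbd_tree(2, np.random.default_rng(77), n_extant=30)
        r2 = simulate_fbd_tree(2, np.random.default_rng(77), n_extant=30)
        from fbdsky.io import write_newick
        assert write_newick(r1.tree) == write_newick(r2.tree)
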