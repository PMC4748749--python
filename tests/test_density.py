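"""FBD tree densities: conditioning, fossils, diversified correction, counts."""

import numpy as np
import pytest

from fbdsky.density import (compute_tree_statistics, log_density_crown,
                            log_density_diversified, log_density_stem,
                            oriented_to_labeled)
from fbdsky.simulate import simulate_fbd_tree
from fbdsky.skyline import RateSkyline, diversified_F
from fbdsky.tree import FBDNode, FBDTree, FossilInfo

from conftest import (classic_crown_log_density, four_tip_mixed_tree,
                      tree_with_fossil_tip, two_tip_tree)


class TestCrownDensity:
    def test_two_tip_yule_hand_derivation(self):
        # probability that neither crown lineage speciates before the present
        lam, x1 = 0.37, 3.2
        sky = RateSkyline.constant(lam, 0.0, 0.0, 1.0)
        assert log_density_crown(two_tip_tree(x1), sky) == pytest.approx(
            -2 * lam * x1, rel=1e-12)

    def test_classic_crown_conditioned_reduction(self, rng):
        """With one interval, no fossils and complete sampling the density
        equals the classic crown-conditioned birth-death formula."""
        for lam, mu in [(0.3, 0.0), (0.3, 0.2), (1.0, 0.7), (0.5, 0.45)]:
            sky = RateSkyline.constant(lam, mu, 0.0, 1.0)
            for x1 in (2.0, 7.5, 20.0):
                inner = np.sort(rng.uniform(0, x1, size=4))
                tips = [FBDNode(0.0, f"T{i}") for i in range(6)]
                node = FBDNode(inner[0], children=[tips[0], tips[1]])
                for j, age in enumerate(inner[1:], start=2):
                    node = FBDNode(age, children=[node, tips[j]])
                tree = FBDTree(FBDNode(x1, children=[node, tips[5]]))
                expected = classic_crown_log_density(inner, x1, lam, mu)
                assert log_density_crown(tree, sky) == pytest.approx(
                    expected, abs=1e-10)

    def test_fossil_in_zero_psi_interval_is_impossible(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.0, 0.5)
        tree = tree_with_fossil_tip(9.0, 5.0, 2.0)
        assert log_density_crown(tree, sky) == -np.inf

    def test_four_sample_tree_term_by_term_oracle(self):
        """Independent scalar evaluation of every density factor."""
        lam, mu, psi, rho = 0.3, 0.2, 0.1, 0.5
        sky = RateSkyline.constant(lam, mu, psi, rho)
        tree = four_tip_mixed_tree()   # root 9, n1 at 6, SA at 4, tip at 2.5
        A = np.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
        B = ((1 - 2 * (1 - rho)) * lam + mu + psi) / A

        def q(t):
            e = np.exp(-A * t)
            return 4 * e / ((1 + B) + (1 - B) * e) ** 2

        def p(t):
            e = np.exp(-A * t)
            frac = ((1 + B) - (1 - B) * e) / ((1 + B) + (1 - B) * e)
            return (lam + mu + psi - A * frac) / (2 * lam)

        # term list: crown conditioning, the sampled ancestor's psi, the one
        # non-root branching (n1 at age 6; the attachment at age 4 is not a
        # speciation event), the fossil tip's psi p/q, and rho per extant tip
        expected = (2 * np.log(q(9.0)) - 2 * np.log(1 - p(9.0))
                    + np.log(psi)
                    + np.log(lam * q(6.0))
                    + np.log(psi) + np.log(p(2.5)) - np.log(q(2.5))
                    + 2 * np.log(rho))        # the two extant tips C, D
        assert log_density_crown(tree, sky) == pytest.approx(
            expected, rel=1e-12)

    def test_node_older_than_condition_age_raises(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5, condition_age=5.0)
        with pytest.raises(ValueError):
            log_density_crown(two_tip_tree(9.0), sky)


class TestStemDensity:
    def test_single_tip_yule_survival(self):
        lam, x0 = 0.37, 5.0
        sky = RateSkyline.constant(lam, 0.0, 0.0, 1.0)
        tree = FBDTree(FBDNode(0.0, "A"), origin_age=x0)
        assert log_density_stem(tree, sky) == pytest.approx(-lam * x0,
                                                            rel=1e-12)

    def test_crown_stem_consistency_in_the_short_stem_limit(self):
        """As the stem shrinks, stem density -> crown density times the
        root-branching and conditioning bookkeeping factors."""
        lam, mu, psi, rho = 0.3, 0.2, 0.1, 0.5
        sky = RateSkyline.constant(lam, mu, psi, rho)
        x1 = 6.0
        tree = two_tip_tree(x1)
        crown = log_density_crown(tree, sky)
        tree_stem = two_tip_tree(x1)
        tree_stem.origin_age = x1 + 1e-9
        stem = log_density_stem(tree_stem, sky)
        # stem - crown = log lambda + log(1 - p(x1)): one conditioning factor
        # is traded for the root's lambda q(x1) term while q(x1) cancels
        p1, _ = sky.pq_at(np.array([x1]))
        bridge = np.log(lam) + np.log1p(-float(p1[0]))
        assert stem == pytest.approx(crown + bridge, abs=1e-6)

    def test_origin_not_older_than_root_raises(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5)
        tree = two_tip_tree(6.0)
        tree.origin_age = 6.0
        with pytest.raises(ValueError):
            log_density_stem(tree, sky)

    def test_stem_older_than_condition_age_raises(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5, condition_age=7.0)
        tree = two_tip_tree(6.0)
        tree.origin_age = 8.0
        with pytest.raises(ValueError):
            log_density_stem(tree, sky)


class TestOrientedToLabeled:
    @pytest.mark.parametrize("tips,ancestors,expected", [
        (2, 0, 2.0 / 2),          # 2^1 / 2!
        (3, 0, 4.0 / 6),          # 2^2 / 3!
        (4, 2, 8.0 / 720),        # 2^3 / 6!
    ])
    def test_conversion_factor(self, tips, ancestors, expected):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5)
        # build statistics with the requested counts directly
        st = compute_tree_statistics(two_tip_tree(5.0), sky)
        st.M_i = np.array([tips])
        st.k_i = np.array([ancestors])
        st.m_i = np.array([0])
        st.K_i = np.array([0])
        assert np.exp(oriented_to_labeled(st)) == pytest.approx(expected)


class TestDiversified:
    def _sky(self, x_cut, lam=0.3, mu=0.2, psi=0.1):
        return RateSkyline([lam, lam], [mu, mu], [psi, 0.0], [0.0, 1.0],
                           [x_cut, 0.0])

    def test_no_pruned_taxa_equals_complete_sampling(self):
        sky = self._sky(2.0)
        tree = two_tip_tree(6.0)
        assert log_density_diversified(tree, sky, 2.0, 0) == pytest.approx(
            log_density_crown(tree, sky.with_extant_sampling(1.0)))

    def test_constant_rate_closed_form_identity(self):
        """The single-shift closed form equals the general F-based correction
        over a grid of rates."""
        for lam, mu in [(0.3, 0.2), (0.5, 0.1), (0.4, 0.39), (1.2, 0.6)]:
            for x_cut in (1.0, 4.0, 9.0):
                sky = self._sky(x_cut, lam, mu, 0.1)
                F = diversified_F(sky, x_cut)
                general = np.log1p(-1.0 / F)
                net = lam - mu
                e = np.exp(-net * x_cut)
                closed = np.log(lam * (1 - e) / (lam - mu * e))
                assert general == pytest.approx(closed, abs=1e-12)

    def test_correction_factor_value(self):
        lam, mu, x_cut, eta = 0.3, 0.2, 10.0, 50
        sky = self._sky(x_cut, lam, mu, 0.1)
        tree = FBDTree(FBDNode(
            20.0, children=[FBDNode(15.0, children=[FBDNode(0.0, "A"),
                                                    FBDNode(0.0, "B")]),
                            FBDNode(0.0, "C")]))
        base = log_density_crown(tree, sky.with_extant_sampling(1.0))
        F = 1 + 0.3 * (np.e - 1) / 0.1
        assert log_density_diversified(tree, sky, x_cut, eta) == \
            pytest.approx(base + eta * np.log(1 - 1 / F), rel=1e-10)

    def test_structure_violations_raise(self):
        sky = self._sky(4.0)
        young_split = FBDTree(FBDNode(
            9.0, children=[FBDNode(2.0, children=[FBDNode(0.0, "A"),
                                                  FBDNode(0.0, "B")]),
                           FBDNode(0.0, "C")]))
        with pytest.raises(ValueError):
            log_density_diversified(young_split, sky, 4.0, 10)


class TestTreeStatistics:
    def test_published_worked_example_counts(self):
        """Three intervals; one horizon ancestor at t1, one horizon tip at
        t2, three extant tips: K1 = M2 = n1 = 1, M3 = n2 = 3, n3 = 0."""
        sky = RateSkyline([0.3] * 3, [0.2] * 3, [0.1] * 3, [0.5, 0.5, 0.5],
                          [10.0, 5.0, 0.0])
        x1_ = FBDNode(0.0, "X1")
        x2 = FBDNode(5.0, "X2", fossil=FossilInfo("horizon", horizon=2))
        y1 = FBDNode(0.0, "Y1")
        y2 = FBDNode(0.0, "Y2")
        k1 = FBDNode(10.0, "K1f", fossil=FossilInfo("horizon", horizon=1))
        x_split = FBDNode(8.0, children=[x1_, x2])
        att = FBDNode(10.0, children=[x_split, k1])
        y_split = FBDNode(7.0, children=[y1, y2])
        tree = FBDTree(FBDNode(12.0, children=[att, y_split]))
        st = compute_tree_statistics(tree, sky)
        assert st.K_i.tolist() == [1, 0, 0]
        assert st.M_i.tolist() == [0, 1, 3]
        assert st.n_i.tolist() == [1, 3, 0]
        assert st.m == 0 and st.k == 0

    def test_tree_without_fossils(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5)
        st = compute_tree_statistics(two_tip_tree(4.0), sky)
        assert st.m == st.k == st.K == 0
        assert st.M == 2

    def test_crossing_counts_match_brute_force(self, rng):
        sky = RateSkyline([0.3, 0.3, 0.3], [0.2] * 3, [0.1] * 3,
                          [0.0, 0.0, 0.5], [12.0, 6.0, 0.0])
        for seed in range(5):
            res = simulate_fbd_tree(1, np.random.default_rng(seed),
                                    n_extant=25)
            tree = res.tree
            st = compute_tree_statistics(tree, sky)
            for j, tb in enumerate([12.0, 6.0]):
                brute = sum(
                    1 for n in tree.preorder()
                    if n.parent is not None and n.age < tb < n.parent.age)
                # horizon samples would be excluded, but strategy 1 has none
                assert st.n_i[j] == brute

    def test_sampled_ancestor_roles(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5)
        tree = four_tip_mixed_tree()
        st = compute_tree_statistics(tree, sky)
        assert st.k == 1 and st.m == 1 and st.M == 2
        assert tree.n_sampled_ancestors() == 1
        assert tree.n_fossil_tips() == 1

    def test_mislabelled_horizon_fossil_raises(self):
        sky = RateSkyline([0.3, 0.3], [0.2, 0.2], [0.1, 0.1], [0.5, 0.5],
                          [10.0, 0.0])
        bad = FBDNode(7.0, "F", fossil=FossilInfo("horizon", horizon=1))
        tree = FBDTree(FBDNode(9.0, children=[
            FBDNode(8.0, children=[FBDNode(0.0, "A"), bad]),
            FBDNode(0.0, "B")]))
        with pytest.raises(ValueError):
            compute_tree_statistics(tree, sky)


class TestFastEvaluator:
    @pytest.mark.parametrize("strategy", [1, 2, 3, 4])
    def test_matches_general_density_path(self, strategy, rng):
        """The frozen fixed-tree kernel agrees with the general evaluation
        (density + conversion factor) for random rates on every sampling
        strategy."""
        from fbdsky.experiments import _sim1_model
        from fbdsky.mcmc import FBDChain, ChainConfig
        from fbdsky.priors import PriorSpec
        from fbdsky.skyline import CanonicalParams
        res = simulate_fbd_tree(strategy, np.random.default_rng(strategy),
                                n_extant=30)
        chain = FBDChain(_sim1_model(res), PriorSpec(), res.tree,
                         CanonicalParams([0.1], [0.5], [0.5]),
                         np.random.default_rng(1), fixed_tree=True,
                         config=ChainConfig())
        for _ in range(4):
            p = CanonicalParams([rng.uniform(0.02, 0.3)],
                                [rng.uniform(0.1, 0.9)],
                                [rng.uniform(0.1, 0.9)])
            fast = chain._tree_prior(p)
            ev, chain._evaluator = chain._evaluator, None
            slow = chain._tree_prior(p)
            chain._evaluator = ev
            assert fast == pytest.approx(slow, abs=1e-8)


class TestSeamInvisibility:
    def test_inserting_silent_boundary_leaves_density_unchanged(self):
        sky = RateSkyline.constant(0.3, 0.2, 0.1, 0.5)
        tree = four_tip_mixed_tree()
        base = log_density_crown(tree, sky)
        for cut in (0.5, 2.5 - 1e-6, 3.7, 8.9):
            sky2 = sky.insert_boundary(cut, sampling=0.0)
            assert log_density_crown(tree, sky2) == pytest.approx(
                base, abs=1e-10)
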