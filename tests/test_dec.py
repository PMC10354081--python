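import numpy as np
import pytest

from biogeodyn import (AreaScheme, DECModel, DECParams, anagenetic_rate_matrix,
                       build_state_space, cladogenesis_distribution, dec_loglik,
                       simulate_ranges, simulate_tree)
from biogeodyn.dec import StateSpace
from biogeodyn.treeio import TreeValidationError

from conftest import brute_dec, coding, write_newick


class TestStateSpace:
    @pytest.mark.parametrize("n_areas,max_range,expected", [
        (2, 2, 3),          # A, B, AB
        (3, 3, 7),          # 2^3 - 1
        (13, 2, 91),        # C(13,1) + C(13,2), checked by enumeration below
    ])
    def test_observable_range_count(self, n_areas, max_range, expected):
        areas = tuple("ABCDEFGHIJKLM"[:n_areas])
        scheme = AreaScheme(areas=areas, focal_area="A", max_range_size=max_range)
        ranges = build_state_space(scheme)
        assert len(ranges) == expected
        # independent enumeration of non-empty subsets within the cap
        brute = [s for s in range(1, 2 ** n_areas)
                 if bin(s).count("1") <= max_range]
        assert len(ranges) == len(brute)

    def test_order_and_first_states(self, three_area_scheme):
        assert build_state_space(three_area_scheme) == \
            ["A", "B", "C", "AB", "AC", "BC", "ABC"]

    def test_cap_above_area_count_rejected(self):
        with pytest.raises(ValueError):
            AreaScheme(areas=("A", "B"), focal_area="A", max_range_size=3)


class TestRateMatrix:
    def test_expansion_extirpation_entries(self, two_area_scheme):
        Q = anagenetic_rate_matrix(two_area_scheme, DECParams(0.1, 0.05))
        assert Q.loc["A", "AB"] == pytest.approx(0.1)
        assert Q.loc["AB", "A"] == pytest.approx(0.05)
        assert Q.loc["A", ""] == pytest.approx(0.05)   # singleton decays to null
        np.testing.assert_allclose(Q.to_numpy().sum(axis=1), 0.0, atol=1e-12)

    def test_zero_rates_zero_matrix(self, two_area_scheme):
        Q = anagenetic_rate_matrix(two_area_scheme, DECParams(0.0, 0.0))
        assert (Q.to_numpy() == 0).all()

    def test_multiplier_blocks_one_direction(self):
        m = np.array([[1.0, 0.0], [1.0, 1.0]])  # A->B blocked, B->A open
        scheme = AreaScheme(areas=("A", "B"), focal_area="A", max_range_size=2,
                            multipliers=[m])
        Q = anagenetic_rate_matrix(scheme, DECParams(0.2, 0.0))
        assert Q.loc["A", "AB"] == 0.0
        assert Q.loc["B", "AB"] == pytest.approx(0.2)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            DECParams(-0.1, 0.0)


class TestCladogenesis:
    def test_singleton_sympatry(self, two_area_scheme):
        assert cladogenesis_distribution("A", two_area_scheme) == \
            {("A", "A"): 1.0}

    def test_widespread_six_ordered_scenarios(self, two_area_scheme):
        dist = cladogenesis_distribution("AB", two_area_scheme)
        assert len(dist) == 6
        assert all(p == pytest.approx(1 / 6) for p in dist.values())
        # unordered vicariance A|B carries 2/6 = 1/3
        assert dist[("A", "B")] + dist[("B", "A")] == pytest.approx(1 / 3)

    def test_distributions_sum_to_one_for_every_parent(self, three_area_scheme):
        for parent in build_state_space(three_area_scheme):
            dist = cladogenesis_distribution(parent, three_area_scheme)
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_null_parent_rejected(self, two_area_scheme):
        space = StateSpace(two_area_scheme)
        with pytest.raises(ValueError):
            space.cladogenesis(0)


class TestLikelihood:
    def test_cherry_vicariance_third(self, cherry, two_area_scheme):
        cod = coding({"a": "A", "b": "B"}, "AB")
        ll, cond = dec_loglik(cherry, cod, two_area_scheme, DECParams(0.0, 0.0))
        assert cond["AB"] == pytest.approx(1 / 3, abs=1e-12)
        assert cond["A"] == 0.0 and cond["B"] == 0.0
        assert ll == pytest.approx(np.log(1 / 9))  # flat prior over 3 states

    def test_cherry_identical_tips_sympatry_one(self, cherry, two_area_scheme):
        cod = coding({"a": "A", "b": "A"}, "AB")
        _, cond = dec_loglik(cherry, cod, two_area_scheme, DECParams(0.0, 0.0))
        assert cond["A"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed, three_area_scheme):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(0.8, 0.1, 5, seed=seed)
        sim = simulate_ranges(tree, three_area_scheme, DECParams(0.4, 0.1),
                              "AB", seed=seed, on_death="retry")
        params = DECParams(float(rng.uniform(0.05, 0.5)),
                           float(rng.uniform(0.01, 0.2)))
        model = DECModel(sim.tree, sim.tip_coding, three_area_scheme)
        ll, _ = model.loglik(params)
        brute_ll, brute_marg = brute_dec(sim.tree, sim.tip_coding,
                                         three_area_scheme, params)
        assert ll == pytest.approx(brute_ll, abs=1e-8)
        anc = model.ancestral_ranges(params)
        for r, v in enumerate(anc.node_ids):
            np.testing.assert_allclose(anc.probs[r], brute_marg[v], atol=1e-8)

    def test_time_slices_match_brute_force(self):
        scheme = AreaScheme(
            areas=("A", "B", "C"), focal_area="A", max_range_size=2,
            slice_boundaries=(1.0,),
            multipliers=[np.ones((3, 3)),
                         np.array([[1, .2, .1], [.2, 1, 1], [.1, 1, 1.]])])
        tree = simulate_tree(0.9, 0.0, 4, seed=11)
        sim = simulate_ranges(tree, scheme, DECParams(0.3, 0.05), "AB",
                              seed=5, on_death="retry")
        params = DECParams(0.25, 0.04)
        ll, _ = DECModel(sim.tree, sim.tip_coding, scheme).loglik(params)
        brute_ll, _ = brute_dec(sim.tree, sim.tip_coding, scheme, params)
        assert ll == pytest.approx(brute_ll, abs=1e-8)

    def test_missing_tip_coding_names_tip(self, cherry, two_area_scheme):
        with pytest.raises(TreeValidationError, match="b"):
            DECModel(cherry, coding({"a": "A"}, "AB"), two_area_scheme)

    def test_area_relabelling_invariance(self, cherry):
        """Permuting area labels (focal fixed appropriately) leaves the
        likelihood unchanged."""
        params = DECParams(0.3, 0.1)
        s1 = AreaScheme(areas=("A", "B", "C"), focal_area="A", max_range_size=2)
        s2 = AreaScheme(areas=("A", "C", "B"), focal_area="A", max_range_size=2)
        c1 = coding({"a": "B", "b": "AC"}, "ABC")
        c2 = coding({"a": "C", "b": "AB"}, "ABC")  # B<->C swapped
        ll1, _ = dec_loglik(cherry, c1, s1, params)
        ll2, _ = dec_loglik(cherry, c2, s2, params)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_redundant_slice_boundary_is_neutral(self, cherry):
        params = DECParams(0.3, 0.1)
        cod = coding({"a": "A", "b": "AB"}, "AB")
        plain = AreaScheme(areas=("A", "B"), focal_area="A", max_range_size=2)
        sliced = AreaScheme(areas=("A", "B"), focal_area="A", max_range_size=2,
                            slice_boundaries=(0.4,),
                            multipliers=[np.ones((2, 2)), np.ones((2, 2))])
        ll1, _ = dec_loglik(cherry, cod, plain, params)
        ll2, _ = dec_loglik(cherry, cod, sliced, params)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_transition_matrices_stochastic(self, two_area_scheme):
        from scipy.linalg import expm
        space = StateSpace(two_area_scheme)
        P = expm(space.rate_matrix(DECParams(0.3, 0.2)) * 2.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P >= -1e-12).all()


class TestFit:
    def test_uniform_singleton_tips_drive_d_to_zero(self, tmp_path,
                                                    two_area_scheme):
        from biogeodyn import read_tree
        t = read_tree(write_newick(tmp_path, "((a:1,b:1):1,(c:1.5,d:1.5):0.5);"))
        cod = coding({x: "A" for x in "abcd"}, "AB")
        res = DECModel(t, cod, two_area_scheme).fit()
        assert res.params.d < 1e-4

    def test_fitted_loglik_beats_coarse_grid(self, two_area_scheme):
        tree = simulate_tree(0.4, 0.0, 20, seed=2)
        sim = simulate_ranges(tree, two_area_scheme, DECParams(0.2, 0.02),
                              "B", seed=2)
        model = DECModel(sim.tree, sim.tip_coding, two_area_scheme)
        res = model.fit()
        for d in (0.01, 0.1, 0.3, 1.0):
            for e in (0.01, 0.1, 0.3, 1.0):
                ll, _ = model.loglik(DECParams(d, e))
                assert res.llf >= ll - 1e-6

    def test_d_recovery_within_factor_two(self, two_area_scheme):
        """Expansion-rate recovery on 200-tip forward simulations."""
        hits = 0
        n = 20
        for rep in range(n):
            tree = simulate_tree(0.3, 0.05, 200, seed=rep)
            sim = simulate_ranges(tree, two_area_scheme,
                                  DECParams(0.2, 0.02), "B", seed=rep)
            res = DECModel(sim.tree, sim.tip_coding, two_area_scheme).fit()
            hits += 0.1 <= res.params.d <= 0.4
        assert hits >= 0.8 * n

    def test_summary_mentions_rates(self, two_area_scheme):
        tree = simulate_tree(0.4, 0.0, 10, seed=4)
        sim = simulate_ranges(tree, two_area_scheme, DECParams(0.2, 0.02),
                              "B", seed=4)
        res = DECModel(sim.tree, sim.tip_coding, two_area_scheme).fit()
        out = res.summary()
        assert "log-likelihood" in out and "d (expansion/Ma)" in out


class TestAncestral:
    def test_cherry_vicariant_root_map(self, cherry, two_area_scheme):
        cod = coding({"a": "A", "b": "B"}, "AB")
        anc = DECModel(cherry, cod, two_area_scheme).ancestral_ranges(
            DECParams(0.0, 0.0))
        assert anc.map_range(cherry.root) == "AB"
        assert anc.probability(cherry.root, "AB") == pytest.approx(1.0)

    def test_all_focal_tips_reconstruct_focal(self, tmp_path, two_area_scheme):
        from biogeodyn import read_tree
        t = read_tree(write_newick(tmp_path, "((a:1,b:1):1,(c:1.5,d:1.5):0.5);"))
        cod = coding({x: "A" for x in "abcd"}, "AB")
        anc = DECModel(t, cod, two_area_scheme).ancestral_ranges(
            DECParams(0.05, 0.001))
        assert set(anc.map_ranges().values()) == {"A"}

    def test_map_tie_break_is_first_state(self):
        from biogeodyn.dec import AncestralRangeTable
        table = AncestralRangeTable(node_ids=[0], range_labels=["A", "B", "AB"],
                                    probs=np.array([[0.5, 0.5, 0.0]]))
        assert table.map_range(0) == "A"
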