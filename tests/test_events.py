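import math

import numpy as np
import pytest

from biogeodyn import (AreaScheme, DECParams, EventRecord, EventTable,
                       classify_events, read_tree, simulate_ranges,
                       simulate_tree, tally)
from biogeodyn.dec import AncestralRangeTable
from biogeodyn.events import EventTally, assign_source, assign_sources, attach_timing

from conftest import coding, write_newick


def one_hot(node_ids, labels, assignments):
    probs = np.zeros((len(node_ids), len(labels)))
    for r, v in enumerate(node_ids):
        probs[r, labels.index(assignments[v])] = 1.0
    return AncestralRangeTable(node_ids=node_ids, range_labels=labels,
                               probs=probs)


@pytest.fixture
def balanced(tmp_path):
    return read_tree(write_newick(tmp_path, "((a:1,b:1):1,(c:1,d:1):1);"),
                     clade_id="demo")


class TestClassify:
    def test_single_gain_and_single_radiation(self, balanced, two_area_scheme):
        t = balanced
        internal = [v for v in range(t.n_nodes) if not t.is_tip(v)]
        tipsets = {v: frozenset(t.labels[c] for c in range(t.n_nodes)
                                if t.is_tip(c) and _under(t, c, v))
                   for v in internal}
        anc_ab = next(v for v in internal if tipsets[v] == frozenset("ab"))
        anc_cd = next(v for v in internal if tipsets[v] == frozenset("cd"))
        assign = {t.root: "B", anc_ab: "A", anc_cd: "B"}
        anc = one_hot(internal, ["A", "B", "AB"], assign)
        cod = coding({"a": "A", "b": "A", "c": "B", "d": "B"}, "AB")
        events = classify_events(t, anc, cod, two_area_scheme)
        kinds = sorted((e.event_type, e.node_id) for e in events)
        assert kinds == [("dispersal_in", anc_ab), ("in_situ", anc_ab)]

    def test_no_focal_anywhere_gives_empty_table(self, balanced, two_area_scheme):
        internal = [v for v in range(balanced.n_nodes) if not balanced.is_tip(v)]
        anc = one_hot(internal, ["A", "B", "AB"], {v: "B" for v in internal})
        cod = coding({x: "B" for x in "abcd"}, "AB")
        assert len(classify_events(balanced, anc, cod, two_area_scheme)) == 0

    def test_events_sorted_old_to_young(self, two_area_scheme):
        tree = simulate_tree(0.4, 0.0, 30, seed=9, clade_id="s")
        sim = simulate_ranges(tree, two_area_scheme, DECParams(0.3, 0.02),
                              "B", seed=9)
        ev = classify_events(sim.tree, sim.true_range_table(two_area_scheme),
                             sim.tip_coding, two_area_scheme)
        ages = [e.point_age for e in ev]
        assert ages == sorted(ages, reverse=True)

    @pytest.mark.parametrize("seed", range(15))
    def test_oracle_equivalence_on_true_histories(self, seed, two_area_scheme):
        """Classification on the simulator's true node ranges reproduces its
        event log exactly (type and node id), with dead lineages pruned."""
        tree = simulate_tree(0.3, 0.05, 15, seed=seed, clade_id=f"c{seed}")
        sim = simulate_ranges(tree, two_area_scheme, DECParams(0.3, 0.05),
                              "B", seed=seed)
        anc = sim.true_range_table(two_area_scheme)
        got = {(e.event_type, e.node_id)
               for e in classify_events(sim.tree, anc, sim.tip_coding,
                                        two_area_scheme)}
        true = {(e.event_type, e.node_id) for e in sim.true_events}
        assert got == true

    def test_counts_invariant_to_area_permutation_fixing_focal(self):
        s1 = AreaScheme(areas=("A", "B", "C"), focal_area="A", max_range_size=2)
        s2 = AreaScheme(areas=("A", "C", "B"), focal_area="A", max_range_size=2)
        tree = simulate_tree(0.4, 0.0, 20, seed=12, clade_id="p")
        sim = simulate_ranges(tree, s1, DECParams(0.3, 0.02), "B", seed=12)
        swap = str.maketrans("BC", "CB")
        cod2 = coding({sp: c.translate(swap)
                       for sp, c in sim.tip_coding.codes.items()}, "ABC")
        anc1 = sim.true_range_table(s1)
        labels = anc1.range_labels
        anc2 = one_hot(anc1.node_ids, labels,
                       {v: "".join(sorted(lbl.translate(swap)))
                        for v, lbl in
                        ((v, labels[int(np.argmax(anc1.probs[r]))])
                         for r, v in enumerate(anc1.node_ids))})
        e1 = classify_events(sim.tree, anc1, sim.tip_coding, s1)
        e2 = classify_events(sim.tree, anc2, cod2, s2)
        assert {(e.event_type, e.node_id) for e in e1} == \
            {(e.event_type, e.node_id) for e in e2}

    def test_in_situ_intervals_inside_tree_span(self, two_area_scheme):
        tree = simulate_tree(0.4, 0.0, 25, seed=3, clade_id="span")
        for v in range(tree.n_nodes):
            if not tree.is_tip(v):
                age = float(tree.ages[v])
                tree.hpd[v] = (age * 1.05, age * 0.95)
        sim = simulate_ranges(tree, two_area_scheme, DECParams(0.4, 0.0),
                              "A", seed=3)
        ev = classify_events(sim.tree, sim.true_range_table(two_area_scheme),
                             sim.tip_coding, two_area_scheme)
        root_age = float(sim.tree.ages[sim.tree.root])
        for e in ev:
            if e.event_type == "in_situ":
                assert root_age * 1.05 + 1e-9 >= e.older_bound >= \
                    e.younger_bound >= 0.0


def _under(tree, tip, anc):
    v = tip
    while v >= 0:
        if v == anc:
            return True
        v = tree.parent[v]
    return False


class TestTiming:
    def test_dispersal_window_spans_parent_and_child_hpds(self, balanced):
        t = balanced
        child = next(v for v in range(t.n_nodes) if not t.is_tip(v)
                     and t.parent[v] >= 0)
        parent = int(t.parent[child])
        t.hpd[parent] = (10.50, 8.00)
        t.hpd[child] = (9.80, 9.10)
        t.ages[parent] = 9.9
        t.ages[child] = 9.0
        age, interval = attach_timing(t, "dispersal_in", child)
        assert age == pytest.approx(9.0)
        assert interval == (10.50, 9.10)

    def test_fallback_to_node_ages_without_hpds(self, balanced):
        t = balanced
        child = next(v for v in range(t.n_nodes) if not t.is_tip(v)
                     and t.parent[v] >= 0)
        age, interval = attach_timing(t, "dispersal_in", child)
        assert interval == (float(t.ages[t.parent[child]]), float(t.ages[child]))

    def test_in_situ_uses_node_hpd(self, balanced):
        t = balanced
        node = next(v for v in range(t.n_nodes) if not t.is_tip(v))
        t.hpd[node] = (10.10, 6.00)
        age, interval = attach_timing(t, "in_situ", node)
        assert interval == (10.10, 6.00)


class TestSources:
    @pytest.fixture
    def regional(self, tmp_path):
        scheme = AreaScheme(areas=tuple("ABCDEFGHIJKLM"), focal_area="A",
                            max_range_size=2)
        tree = read_tree(write_newick(tmp_path, "((a:1,b:1):1,c:2);"),
                         clade_id="reg")
        return scheme, tree

    def test_singleton_parent_names_source(self, regional):
        scheme, tree = regional
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        labels = [s for s in __import__("biogeodyn").build_state_space(scheme)]
        tipmap = tree.tip_label_map()
        anc_ab = next(v for v in internal if v != tree.root)
        anc = one_hot(internal, labels, {tree.root: "G", anc_ab: "G"})
        cod = coding({"a": "AG", "b": "G", "c": "G"}, "ABCDEFGHIJKLM")
        ev = classify_events(tree, anc, cod, scheme)
        disp = [e for e in ev if e.event_type == "dispersal_in"]
        assert len(disp) == 1
        src = assign_source(disp[0], tree, anc, cod, scheme)
        assert src == "G"

    def test_widespread_parent_is_ambiguous(self, regional):
        scheme, tree = regional
        internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
        labels = __import__("biogeodyn").build_state_space(scheme)
        anc_ab = next(v for v in internal if v != tree.root)
        anc = one_hot(internal, labels, {tree.root: "DF", anc_ab: "DF"})
        cod = coding({"a": "AD", "b": "D", "c": "F"}, "ABCDEFGHIJKLM")
        ev = classify_events(tree, anc, cod, scheme)
        disp = [e for e in ev if e.event_type == "dispersal_in"]
        assert assign_source(disp[0], tree, anc, cod, scheme) == ""
        # assign_sources drops ambiguous events from per-source tallies
        tl = tally(assign_sources(EventTable(list(ev)), tree, anc, cod, scheme))
        assert tl.by_source == {}


class TestTally:
    def test_study_scale_counts_and_ratio(self):
        tl = EventTally.from_counts(105, 26, {"G": 14, "B": 2, "C": 2, "D": 2,
                                              "E": 2, "F": 2, "H": 2})
        assert tl.n_total == 131
        assert tl.ratio == pytest.approx(105 / 26)
        assert round(tl.ratio) == 4
        assert tl.pct_by_source["G"] == pytest.approx(100 * 14 / 26)
        assert round(tl.pct_by_source["G"]) == 54

    def test_empty_table_flags_undefined_ratio(self):
        tl = tally(EventTable([]))
        assert tl.n_total == 0
        assert not tl.ratio_defined and math.isnan(tl.ratio)

    def test_dispersals_without_insitu_is_infinite_ratio(self):
        ev = EventTable([EventRecord("c", "dispersal_in", 0, 1.0, 1.5, 0.5)])
        tl = tally(ev)
        assert math.isinf(tl.ratio) and not tl.ratio_defined

    def test_tally_matches_table_contents(self):
        recs = [EventRecord("c", "dispersal_in", i, 2.0, 2.5, 1.5,
                            "G" if i % 2 else "")
                for i in range(4)]
        recs += [EventRecord("c", "in_situ", 10 + i, 1.0, 1.2, 0.8)
                 for i in range(2)]
        tl = tally(EventTable(recs))
        assert (tl.n_dispersal, tl.n_insitu, tl.n_total) == (4, 2, 6)
        assert tl.by_source == {"G": 2}
        assert tl.pct_by_source["G"] == pytest.approx(100.0)
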